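import numpy as np
import pytest

from fluxquant import synthcells as sc


@pytest.fixture(scope="session")
def base_params() -> sc.SimFieldParams:
    """Noise-off oracle settings: every spot individually resolvable."""
    return sc.SimFieldParams(seed=0)


@pytest.fixture(scope="session")
def noisy_params(base_params) -> sc.SimFieldParams:
    """Moderate camera noise: shot noise plus read noise at 5% of spot peak."""
    return base_params.replace(
        poisson_noise=True,
        gaussian_noise_sd=0.05 * base_params.punctum_peak_intensity,
    )


@pytest.fixture(scope="session")
def oracle_field(base_params):
    """One rendered noise-off field with its ground truth."""
    return sc.generate_field(base_params.replace(seed=42))


def render_exact_field(n_ap: int, n_al: int, n_nuclei: int = 4,
                       shape=(256, 256)) -> tuple[sc.FieldImage, sc.GroundTruth]:
    """Deterministic field with exact class counts on a regular grid.

    Bypasses the Poisson draw so tests can assert fixed per-cell values.
    """
    from fluxquant.synthcells import _render_disk, _render_spot

    nuclei = np.zeros(shape)
    green = np.zeros(shape)
    red = np.zeros(shape)
    params = sc.SimFieldParams(image_size=shape, seed=0)
    centers = [(60.0 + 120.0 * (i // 2), 60.0 + 120.0 * (i % 2)) for i in range(n_nuclei)]
    for c in centers:
        _render_disk(nuclei, c, 9.0, params.nucleus_peak_intensity)
    # spots on a separate coarse grid, away from the nuclei
    positions = [
        (20.0 + 12.0 * (k % 18), 24.0 + 12.0 * (k // 18)) for k in range(n_ap + n_al)
    ]
    puncta = []
    for k, pos in enumerate(positions):
        cls = sc.AP if k < n_ap else sc.AL
        _render_spot(red, pos, params.punctum_sigma_px, params.punctum_peak_intensity)
        amp = params.punctum_peak_intensity * (
            1.0 if cls == sc.AP else params.green_quench_factor
        )
        _render_spot(green, pos, params.punctum_sigma_px, amp)
        puncta.append((pos[0], pos[1], cls))
    bg = params.background_level
    image = sc.FieldImage(nuclei + bg, green + bg, red + bg, source_id="exact")
    truth = sc.GroundTruth(
        nuclei_centroids=centers, nuclei_radii=[9.0] * n_nuclei, puncta=puncta
    )
    return image, truth
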