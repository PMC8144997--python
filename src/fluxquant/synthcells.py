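"""Synthetic data generators with known ground truth.

Emulates the three kinds of raw data the analysis pipeline consumes:

* fluorescence-microscopy fields of view carrying a tandem mCherry-EGFP-LC3B
  reporter — DAPI-stained nuclei plus two classes of LC3 vesicles:
  autophagosomes (AP, red and green) and autolysosomes (AL, red only,
  EGFP quenched in the acidic lumen);
* long-format qPCR Ct tables with configurable true fold changes and
  reference genes held constant;
* zebrafish-xenograft tumor-volume tables (baseline and follow-up per fish).

Every generator is deterministic given its seed and records the complete
ground truth, so detector and statistics stages can be benchmarked exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimFieldParams",
    "GroundTruth",
    "CohortEffectSpec",
    "FieldImage",
    "generate_field",
    "generate_cohort",
    "simulate_cohort_counts",
    "write_cohort",
    "generate_ct_table",
    "generate_xeno_cohort",
]

# Classes of LC3 vesicle in the tandem reporter.
AP = "AP"  # autophagosome: mCherry + EGFP
AL = "AL"  # autolysosome: mCherry only, EGFP quenched

_MAX_PLACEMENT_ATTEMPTS = 200


class FieldTooCrowdedError(ValueError):
    """Non-overlapping nucleus placement failed within the attempt budget."""


@dataclass(frozen=True)
class SimFieldParams:
    """Generative parameters for one synthetic field of view.

    Intensities are arbitrary camera units on a 16-bit scale; distances are
    pixels. ``green_quench_factor`` is the fraction of full EGFP intensity
    retained by an autolysosome; it must stay below the detector's contrast
    threshold for ground-truth classes to be recoverable at zero noise.
    """

    image_size: tuple[int, int] = (256, 256)
    n_cells: int = 6
    nucleus_radius_px: tuple[float, float] = (9.0, 1.0)  # (mean, sd)
    puncta_per_cell_ap: float = 3.0  # Poisson mean
    puncta_per_cell_al: float = 3.0  # Poisson mean
    punctum_sigma_px: float = 1.5
    punctum_peak_intensity: float = 150.0
    nucleus_peak_intensity: float = 120.0
    green_quench_factor: float = 0.15
    background_level: float = 20.0
    poisson_noise: bool = False
    gaussian_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image_size must be at least 64x64")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.green_quench_factor <= 1.0:
            raise ValueError("green_quench_factor must lie in [0, 1]")
        for name in ("punctum_peak_intensity", "nucleus_peak_intensity",
                     "background_level", "gaussian_noise_sd",
                     "puncta_per_cell_ap", "puncta_per_cell_al"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.punctum_sigma_px <= 0:
            raise ValueError("punctum_sigma_px must be positive")

    def replace(self, **kwargs) -> "SimFieldParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FieldImage:
    """One field of view: three registered 2-D channels (nuclei, green, red)."""

    nuclei: np.ndarray
    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (self.nuclei.shape == self.green.shape == self.red.shape):
            raise ValueError("all three channels must share identical dimensions")
        for name in ("nuclei", "green", "red"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise ValueError(f"channel {name!r} must be finite and nonnegative")
            setattr(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei.shape


@dataclass
class GroundTruth:
    """Everything placed in a simulated field, for use as a test oracle."""

    nuclei_centroids: list[tuple[float, float]] = field(default_factory=list)
    nuclei_radii: list[float] = field(default_factory=list)
    puncta: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei_centroids)

    @property
    def n_ap(self) -> int:
        return sum(1 for *_, c in self.puncta if c == AP)

    @property
    def n_al(self) -> int:
        return sum(1 for *_, c in self.puncta if c == AL)

    def puncta_of(self, cls: str) -> np.ndarray:
        pts = [(r, c) for r, c, k in self.puncta if k == cls]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nuclei_centroids": self.nuclei_centroids,
                "nuclei_radii": self.nuclei_radii,
                "puncta": self.puncta,
                "n_AP": self.n_ap,
                "n_AL": self.n_al,
            }
        )


@dataclass(frozen=True)
class CohortEffectSpec:
    """Per-condition multipliers on the two vesicle-class Poisson means.

    Emulates a drug/bafilomycin factorial design: each condition scales the
    expected autophagosome and autolysosome counts per cell of a shared
    baseline parameter set.
    """

    conditions: tuple[str, ...]
    ap_multipliers: tuple[float, ...]
    al_multipliers: tuple[float, ...]
    n_fields: int = 10
    timepoint: str = "48h"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition labels")
        if not (len(self.conditions) == len(self.ap_multipliers) == len(self.al_multipliers)):
            raise ValueError("conditions and multipliers must have equal length")
        if any(m <= 0 for m in self.ap_multipliers + self.al_multipliers):
            raise ValueError("multipliers must be > 0")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")

    @classmethod
    def flux_induced(cls, n_fields: int = 10, seed: int = 0) -> "CohortEffectSpec":
        """Drug raises autolysosomes; with late-stage blockade it raises
        autophagosomes relative to blockade alone — the induced-flux signature."""
        return cls(
            conditions=("control", "drug", "baf", "drug_baf"),
            ap_multipliers=(1.0, 0.5, 3.0, 9.0),
            al_multipliers=(1.0, 3.0, 0.3, 0.3),
            n_fields=n_fields,
            seed=seed,
        )

    @classmethod
    def flux_blocked(cls, n_fields: int = 10, seed: int = 0) -> "CohortEffectSpec":
        """Drug accumulates autophagosomes without autolysosome gain — the
        blocked-fusion signature."""
        return cls(
            conditions=("control", "drug", "baf", "drug_baf"),
            ap_multipliers=(1.0, 3.0, 3.0, 3.0),
            al_multipliers=(1.0, 0.3, 0.3, 0.3),
            n_fields=n_fields,
            seed=seed,
        )

    @classmethod
    def null(cls, n_fields: int = 10, seed: int = 0) -> "CohortEffectSpec":
        """All conditions identical to baseline."""
        return cls(
            conditions=("control", "drug", "baf", "drug_baf"),
            ap_multipliers=(1.0, 1.0, 1.0, 1.0),
            al_multipliers=(1.0, 1.0, 1.0, 1.0),
            n_fields=n_fields,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------

def _place_nuclei(params: SimFieldParams, rng: np.random.Generator,
                  margin: float) -> tuple[list[tuple[float, float]], list[float]]:
    """Rejection-sample non-overlapping nucleus centers with a border margin."""
    h, w = params.image_size
    mean_r, sd_r = params.nucleus_radius_px
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(params.n_cells):
        placed = False
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            r = max(3.0, rng.normal(mean_r, sd_r))
            row = rng.uniform(margin, h - margin)
            col = rng.uniform(margin, w - margin)
            ok = all(
                np.hypot(row - cr, col - cc) >= r + rr + 2.0
                for (cr, cc), rr in zip(centers, radii)
            )
            if ok:
                centers.append((row, col))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise FieldTooCrowdedError(
                f"could not place {params.n_cells} non-overlapping nuclei in "
                f"a {h}x{w} field: field too crowded"
            )
    return centers, radii


def _place_puncta(params: SimFieldParams, rng: np.random.Generator,
                  centers: Sequence[tuple[float, float]], radii: Sequence[float],
                  ap_mean: float, al_mean: float) -> list[tuple[float, float, str]]:
    """Place puncta uniformly in a cytoplasmic annulus around each nucleus.

    A minimum center separation of 4x the spot sigma is enforced between all
    puncta (bounded retries) so that at noise-off oracle settings every spot
    is individually resolvable; on the rare exhausted retry the point is
    placed anyway (overlap allowed). Two equal Gaussians closer than ~2.4
    sigma sum to a unimodal profile, so a 2-sigma floor would leave counts
    ambiguous for any detector; 4 sigma keeps distinct spots distinct.
    """
    h, w = params.image_size
    min_sep = 4.0 * params.punctum_sigma_px
    annulus_width = 12.0
    placed: list[tuple[float, float, str]] = []

    def try_place(nuc_idx: int, cls: str) -> None:
        (cr, cc), nr = centers[nuc_idx], radii[nuc_idx]
        best = None
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            rad = rng.uniform(nr + 1.5, nr + annulus_width)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            row = float(np.clip(cr + rad * np.sin(ang), 3.0, h - 4.0))
            col = float(np.clip(cc + rad * np.cos(ang), 3.0, w - 4.0))
            best = (row, col)
            if all(np.hypot(row - pr, col - pc) >= min_sep for pr, pc, _ in placed):
                break
        placed.append((best[0], best[1], cls))

    for i in range(len(centers)):
        for _ in range(rng.poisson(ap_mean)):
            try_place(i, AP)
        for _ in range(rng.poisson(al_mean)):
            try_place(i, AL)
    return placed


def _render_disk(img: np.ndarray, center: tuple[float, float], radius: float,
                 peak: float) -> None:
    """Filled disk with a mild radial intensity falloff (brighter center)."""
    h, w = img.shape
    cr, cc = center
    r0, r1 = int(max(0, cr - radius - 2)), int(min(h, cr + radius + 3))
    c0, c1 = int(max(0, cc - radius - 2)), int(min(w, cc + radius + 3))
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - cr, cc_ - cc)
    inside = d <= radius
    profile = peak * (1.0 - 0.3 * (d / radius) ** 2)
    img[r0:r1, c0:c1][inside] += profile[inside]


def _render_spot(img: np.ndarray, center: tuple[float, float], sigma: float,
                 amplitude: float) -> None:
    if amplitude <= 0:
        return
    h, w = img.shape
    cr, cc = center
    ext = int(np.ceil(4 * sigma))
    r0, r1 = int(max(0, cr - ext)), int(min(h, cr + ext + 1))
    c0, c1 = int(max(0, cc - ext)), int(min(w, cc + ext + 1))
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - cr) ** 2 + (cc_ - cc) ** 2) / (2.0 * sigma**2)
    )


def generate_field(
    params: SimFieldParams,
    *,
    ap_multiplier: float = 1.0,
    al_multiplier: float = 1.0,
    source_id: str = "field",
) -> tuple[FieldImage, GroundTruth]:
    """Render one three-channel field and its ground truth.

    Autophagosome spots appear at identical positions in red and green at
    full intensity; autolysosome spots appear in red at full intensity and in
    green at ``green_quench_factor`` of it. Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    mean_r, _ = params.nucleus_radius_px
    margin = mean_r + 16.0  # keep the cytoplasmic annulus inside the frame

    centers, radii = _place_nuclei(params, rng, margin)
    puncta = _place_puncta(
        params, rng, centers, radii,
        params.puncta_per_cell_ap * ap_multiplier,
        params.puncta_per_cell_al * al_multiplier,
    )

    nuclei = np.zeros((h, w), dtype=float)
    green = np.zeros((h, w), dtype=float)
    red = np.zeros((h, w), dtype=float)
    for center, radius in zip(centers, radii):
        _render_disk(nuclei, center, radius, params.nucleus_peak_intensity)
    peak = params.punctum_peak_intensity
    for row, col, cls in puncta:
        _render_spot(red, (row, col), params.punctum_sigma_px, peak)
        g_amp = peak if cls == AP else peak * params.green_quench_factor
        _render_spot(green, (row, col), params.punctum_sigma_px, g_amp)

    channels = []
    for chan in (nuclei, green, red):
        img = chan + params.background_level
        if params.poisson_noise:
            img = rng.poisson(img).astype(float)
        if params.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, params.gaussian_noise_sd, size=img.shape)
        channels.append(np.clip(img, 0.0, 65535.0))

    image = FieldImage(*channels, source_id=source_id)
    truth = GroundTruth(
        nuclei_centroids=[(float(r), float(c)) for r, c in centers],
        nuclei_radii=[float(r) for r in radii],
        puncta=[(float(r), float(c), k) for r, c, k in puncta],
    )
    return image, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    spec: CohortEffectSpec, base: SimFieldParams
) -> tuple[list[tuple[FieldImage, GroundTruth, str]], pd.DataFrame]:
    """Generate ``spec.n_fields`` fields per condition plus a sample sheet.

    Field seeds are derived deterministically from ``spec.seed`` via a
    seed sequence, so cohorts are reproducible end to end.
    """
    ss = np.random.SeedSequence(spec.seed)
    field_seeds = ss.generate_state(len(spec.conditions) * spec.n_fields) % (2**31)
    fields: list[tuple[FieldImage, GroundTruth, str]] = []
    rows = []
    k = 0
    for cond, ap_m, al_m in zip(spec.conditions, spec.ap_multipliers, spec.al_multipliers):
        for i in range(spec.n_fields):
            source_id = f"{cond}_{spec.timepoint}_f{i:03d}"
            params = base.replace(seed=int(field_seeds[k]))
            image, truth = generate_field(
                params, ap_multiplier=ap_m, al_multiplier=al_m, source_id=source_id
            )
            fields.append((image, truth, cond))
            rows.append(
                {
                    "file": f"{source_id}.tif",
                    "condition": cond,
                    "timepoint": spec.timepoint,
                    "seed": int(field_seeds[k]),
                }
            )
            k += 1
    return fields, pd.DataFrame(rows)


def simulate_cohort_counts(spec: CohortEffectSpec, base: SimFieldParams) -> pd.DataFrame:
    """Draw only the ground-truth per-field counts of a cohort (no rendering).

    Uses the same Poisson generative model as :func:`generate_cohort` for the
    per-cell vesicle counts; intended for fast statistical simulations where
    pixel data are not needed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows = []
    for cond, ap_m, al_m in zip(spec.conditions, spec.ap_multipliers, spec.al_multipliers):
        for i in range(spec.n_fields):
            n_cells = base.n_cells
            n_ap = int(rng.poisson(base.puncta_per_cell_ap * ap_m * n_cells))
            n_al = int(rng.poisson(base.puncta_per_cell_al * al_m * n_cells))
            rows.append(
                {
                    "source_id": f"{cond}_{spec.timepoint}_f{i:03d}",
                    "condition": cond,
                    "timepoint": spec.timepoint,
                    "n_nuclei": n_cells,
                    "n_AP": n_ap,
                    "n_AL": n_al,
                    "per_cell_AP": n_ap / n_cells if n_cells else np.nan,
                    "per_cell_AL": n_al / n_cells if n_cells else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(
    fields: Sequence[tuple[FieldImage, GroundTruth, str]],
    sheet: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write per-field multi-channel TIFFs, ground-truth JSON, and the sheet.

    TIFF channel order is (nuclei, green, red), declared in the image
    description metadata; pixel data are stored as 16-bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for image, truth, _cond in fields:
        stack = np.stack(
            [np.round(c).astype(np.uint16) for c in (image.nuclei, image.green, image.red)]
        )
        tifffile.imwrite(
            out_dir / f"{image.source_id}.tif",
            stack,
            photometric="minisblack",
            planarconfig="separate",
            description=json.dumps({"channel_order": ["nuclei", "green", "red"]}),
        )
        (out_dir / f"{image.source_id}.truth.json").write_text(truth.to_json())
    sheet_path = out_dir / "sample_sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    return sheet_path


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_log2_fold_changes: Mapping[str, float | Mapping[str, float]],
    ref_genes: Sequence[str] = ("SDHA", "HPRT"),
    *,
    control_condition: str | None = None,
    baseline_ct: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    n_samples: int = 3,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format Ct table with known expression fold changes.

    Each measured Ct is drawn as ``baseline_Ct - log2(relative expression)
    + N(0, noise_sd)``: one extra doubling of template shifts the threshold
    cycle one cycle earlier. ``true_log2_fold_changes`` maps each target gene
    to either a scalar log2 fold change (applied in every non-control
    condition) or a per-condition mapping. Reference genes must have true
    fold change 1 (log2 FC 0) everywhere.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 for downstream testing use")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    control = control_condition if control_condition is not None else conditions[0]
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not in conditions")
    for g in ref_genes:
        spec_fc = true_log2_fold_changes.get(g, 0.0)
        vals = spec_fc.values() if isinstance(spec_fc, Mapping) else [spec_fc]
        if any(v != 0.0 for v in vals):
            raise ValueError(f"reference gene {g!r} must have true fold change 1")

    all_genes = list(dict.fromkeys(list(genes) + list(ref_genes)))
    base_ct = dict(baseline_ct or {})
    for g in all_genes:
        base_ct.setdefault(g, 20.0 if g in ref_genes else 24.0)

    def log2fc(gene: str, condition: str) -> float:
        if gene in ref_genes or condition == control:
            return 0.0
        spec_fc = true_log2_fold_changes.get(gene, 0.0)
        if isinstance(spec_fc, Mapping):
            return float(spec_fc.get(condition, 0.0))
        return float(spec_fc)

    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for s in range(n_samples):
            sample_id = f"{cond}_s{s + 1}"
            for gene in all_genes:
                true_ct = base_ct[gene] - log2fc(gene, cond)
                for rep in range(n_replicates):
                    ct = true_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "condition": cond,
                            "gene": gene,
                            "replicate": rep + 1,
                            "Ct": float(ct),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Xenograft volume tables
# ---------------------------------------------------------------------------

def generate_xeno_cohort(
    arms: Sequence[tuple[str, int, float, float]],
    seed: int = 0,
    *,
    baseline_mean: float = 1.0e5,
    baseline_cv: float = 0.25,
) -> pd.DataFrame:
    """Simulate per-fish tumor volumes at baseline (day 1) and follow-up (day 3).

    ``arms`` is a list of ``(label, n_fish, mean_pct_change, sd_pct_change)``.
    Baseline volumes are log-normal around ``baseline_mean`` (arbitrary volume
    units); follow-up volumes realize the drawn percent change, floored so
    volumes stay nonnegative.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, n_fish, mean_pct, sd_pct in arms:
        if n_fish < 1:
            raise ValueError(f"arm {label!r}: n_fish must be >= 1")
        if sd_pct < 0:
            raise ValueError(f"arm {label!r}: sd must be nonnegative")
        for i in range(n_fish):
            baseline = baseline_mean * rng.lognormal(0.0, baseline_cv)
            pct = mean_pct if sd_pct == 0 else rng.normal(mean_pct, sd_pct)
            pct = max(pct, -100.0)
            rows.append(
                {
                    "fish_id": f"{label}_{i + 1:02d}",
                    "arm": label,
                    "volume_baseline": float(baseline),
                    "volume_followup": float(baseline * (1.0 + pct / 100.0)),
                }
            )
    return pd.DataFrame(rows)
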