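"""Quantification of tandem-reporter fluorescence fields.

Implements the semi-automated image-analysis pipeline: count DAPI-stained
nuclei to assess cell number, detect red and green fluorescent vesicles
(LC3 puncta), classify red vesicles into autophagosomes (red AND green) and
autolysosomes (red only, EGFP quenched) by object-based colocalization, and
normalize class counts per cell.

Detection is Laplacian-of-Gaussian blob detection on a background-subtracted
channel with a contrast filter relative to local background; a red punctum is
"green-positive" only via one-to-one centroid matching to an independently
detected green punctum, never via green intensity sampled under the red spot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
from skimage import feature, filters, measure, morphology, segmentation

from .synthcells import FieldImage

__all__ = [
    "NucleiParams",
    "SpotParams",
    "QuantParams",
    "Punctum",
    "FieldQuantification",
    "count_nuclei",
    "detect_puncta",
    "classify_vesicles",
    "greedy_match_points",
    "quantify_field",
    "quantify_batch",
    "read_field_tiff",
]

log = logging.getLogger("fluxquant")


@dataclass(frozen=True)
class NucleiParams:
    """Nucleus segmentation settings (smooth, threshold, fill, split)."""

    smooth_sigma: float = 2.0
    min_area_px: int = 30
    split_min_distance_px: int = 7


@dataclass(frozen=True)
class SpotParams:
    """Blob-detection settings for one fluorescence channel.

    ``min_contrast`` is the minimum smoothed peak height above local
    background; it is the double-positive detection threshold in intensity
    units — quenched-EGFP autolysosome spots must fall below it.
    """

    expected_sigma_px: float = 1.5
    min_contrast: float = 50.0
    background_filter_px: int = 15
    min_area_px: int = 3
    max_area_px: int = 200


@dataclass(frozen=True)
class QuantParams:
    """All thresholds for one quantification run, serialized with results."""

    nuclei: NucleiParams = field(default_factory=NucleiParams)
    spots: SpotParams = field(default_factory=SpotParams)
    coloc_radius_px: float = 2.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass(frozen=True)
class Punctum:
    """A detected fluorescent vesicle."""

    centroid: tuple[float, float]  # 0-based (row, col)
    area_px: int
    mean_intensity: float
    channel: str  # "green" or "red"


@dataclass
class FieldQuantification:
    """Per-field counts and per-cell normalized values."""

    source_id: str
    n_nuclei: int
    n_red_total: int
    n_ap: int
    n_al: int
    n_green_only: int
    per_cell_ap: float  # NaN when n_nuclei == 0
    per_cell_al: float
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_ap + self.n_al != self.n_red_total:
            raise AssertionError(
                "conservation violated: n_AP + n_AL != n_red_total"
            )


def _validate_channel(channel: np.ndarray) -> np.ndarray:
    arr = np.asarray(channel, dtype=float)
    if arr.ndim != 2:
        raise ValueError("channel must be a 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("channel contains non-finite values")
    if arr.min() < 0:
        raise ValueError("channel intensities must be nonnegative")
    return arr


# ---------------------------------------------------------------------------
# Nuclei
# ---------------------------------------------------------------------------

def count_nuclei(
    nuclei_channel: np.ndarray, params: NucleiParams = NucleiParams()
) -> tuple[int, np.ndarray, np.ndarray]:
    """Count nuclear objects in the DAPI channel.

    Pipeline: Gaussian smoothing, Otsu global threshold, hole filling, size
    filtering, and distance-transform watershed to split touching nuclei.

    Returns ``(count, centroids, label_mask)`` with 0-based centroids sorted
    by (row, col). A blank or constant channel yields count 0 (callers add
    the "no nuclei" QC flag).
    """
    arr = _validate_channel(nuclei_channel)
    if arr.max() == arr.min():
        return 0, np.empty((0, 2)), np.zeros(arr.shape, dtype=np.int32)

    smoothed = filters.gaussian(arr, sigma=params.smooth_sigma, preserve_range=True)
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=params.min_area_px - 1)
    if not mask.any():
        return 0, np.empty((0, 2)), np.zeros(arr.shape, dtype=np.int32)

    # Split touching nuclei: peaks of the (slightly smoothed) distance
    # transform seed a watershed.
    distance = ndi.distance_transform_edt(mask)
    distance_s = filters.gaussian(distance, sigma=1.0, preserve_range=True)
    peak_coords = feature.peak_local_max(
        distance_s,
        min_distance=params.split_min_distance_px,
        labels=measure.label(mask),
        exclude_border=False,
    )
    if len(peak_coords) == 0:
        labels = measure.label(mask).astype(np.int32)
    else:
        markers = np.zeros(arr.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peak_coords, start=1):
            markers[r, c] = i
        labels = segmentation.watershed(-distance_s, markers, mask=mask).astype(np.int32)

    regions = measure.regionprops(labels)
    regions = [r for r in regions if r.area >= params.min_area_px]
    centroids = sorted(r.centroid for r in regions)
    return len(regions), np.asarray(centroids).reshape(-1, 2), labels


# ---------------------------------------------------------------------------
# Spot detection
# ---------------------------------------------------------------------------

def detect_puncta(
    channel: np.ndarray, params: SpotParams = SpotParams(), *, channel_name: str = "red"
) -> list[Punctum]:
    """Detect fluorescent vesicles as LoG blobs above local background.

    Background is estimated by a median filter much wider than a spot and
    subtracted; candidate blobs then pass a contrast filter (smoothed peak
    height above background >= ``min_contrast``) and an area filter. The
    returned list is sorted by (row, col); zero detections is a valid result.
    """
    arr = _validate_channel(channel)
    if arr.max() == arr.min():
        return []  # blank or uniform channel: no contrast, no spots

    background = ndi.median_filter(arr, size=params.background_filter_px)
    signal = np.clip(arr - background, 0.0, None)
    # Mild smoothing stabilizes the peak-height measurement under shot noise.
    signal_s = filters.gaussian(signal, sigma=1.0, preserve_range=True)

    # Scale-normalized LoG at the expected spot scale: a Gaussian spot of
    # amplitude A and width sigma gives a center response of ~A/2, and the
    # LoG kernel is more compact than the spot, so neighbors at twice the
    # spot sigma remain separable.
    sigma = params.expected_sigma_px
    response = -(sigma**2) * ndi.gaussian_laplace(signal, sigma)
    peaks = feature.peak_local_max(
        response,
        min_distance=1,
        threshold_abs=0.25 * params.min_contrast,
        exclude_border=False,
    ).astype(float)
    # Merge peaks closer than the resolvable spot separation, keeping the
    # stronger response (guards against plateau ties on symmetric spots).
    order_idx = np.argsort(-response[peaks[:, 0].astype(int), peaks[:, 1].astype(int)])
    blobs: list[np.ndarray] = []
    for idx in order_idx:
        p = peaks[idx]
        if all(np.hypot(*(p - q)) >= 2.0 for q in blobs):
            blobs.append(p)

    # Smoothing a Gaussian spot of width sigma with a sigma=1 kernel scales
    # its amplitude by sigma^2/(sigma^2+1); correct the contrast threshold
    # so min_contrast keeps its meaning on the unsmoothed signal.
    atten = sigma**2 / (sigma**2 + 1.0)
    h, w = arr.shape
    puncta: list[Punctum] = []
    for br, bc in blobs:
        r, c = int(round(br)), int(round(bc))
        peak = signal_s[r, c]
        if peak < params.min_contrast * atten:
            continue
        # Subpixel centroid: weighted by the compact LoG response in a 3x3
        # window, which is insensitive to the flanks of nearby spots.
        r0, r1 = max(0, r - 1), min(h, r + 2)
        c0, c1 = max(0, c - 1), min(w, c + 2)
        win = np.clip(response[r0:r1, c0:c1], 0.0, None)
        total = win.sum()
        if total > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            cen = (float((rr * win).sum() / total), float((cc * win).sum() / total))
        else:
            cen = (float(r), float(c))
        # Area: pixels above half the measured peak within a spot-sized window.
        ext = int(np.ceil(3 * sigma))
        ar0, ar1 = max(0, r - ext), min(h, r + ext + 1)
        ac0, ac1 = max(0, c - ext), min(w, c + ext + 1)
        region = signal[ar0:ar1, ac0:ac1]
        above = region >= 0.5 * peak / atten
        area = int(above.sum())
        if not params.min_area_px <= area <= params.max_area_px:
            continue
        mean_int = float(arr[ar0:ar1, ac0:ac1][above].mean()) if area else 0.0
        puncta.append(Punctum(cen, area, mean_int, channel_name))

    puncta.sort(key=lambda p: p.centroid)
    return puncta


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------

def greedy_match_points(
    a: np.ndarray, b: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """One-to-one greedy matching of two point sets by ascending distance.

    Candidate pairs with distance <= ``radius`` are processed in ascending
    distance order, ties broken by (index in a, index in b); each point is
    used at most once. Returns matched index pairs.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    ia, ib = np.nonzero(d <= radius)
    order = sorted(zip(d[ia, ib], ia, ib), key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _dist, i, j in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((int(i), int(j)))
    return matches


def classify_vesicles(
    red: Sequence[Punctum], green: Sequence[Punctum], coloc_radius_px: float = 2.0
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Classify red vesicles by object-based colocalization with green.

    Red puncta matched one-to-one to a green punctum within
    ``coloc_radius_px`` are autophagosomes (AP); unmatched red puncta are
    autolysosomes (AL, quenched EGFP); unmatched green puncta are reported
    but excluded from the flux classes.

    Returns ``(n_AP, n_AL, n_green_only, matching)``.
    """
    if coloc_radius_px <= 0:
        raise ValueError("coloc_radius_px must be positive")
    red_pts = np.asarray([p.centroid for p in red], dtype=float).reshape(-1, 2)
    green_pts = np.asarray([p.centroid for p in green], dtype=float).reshape(-1, 2)
    matching = greedy_match_points(red_pts, green_pts, coloc_radius_px)
    n_ap = len(matching)
    n_al = len(red) - n_ap
    n_green_only = len(green) - n_ap
    return n_ap, n_al, n_green_only, matching


# ---------------------------------------------------------------------------
# Field and batch quantification
# ---------------------------------------------------------------------------

def quantify_field(
    image: FieldImage, params: QuantParams = QuantParams()
) -> FieldQuantification:
    """Full per-field quantification: nuclei, puncta, classes, per-cell rates.

    Fields without nuclei get NaN per-cell values and a QC flag; they are
    excluded from group statistics downstream.
    """
    qc: list[str] = []
    n_nuclei, _centroids, _labels = count_nuclei(image.nuclei, params.nuclei)
    if n_nuclei == 0:
        qc.append("no nuclei")
    red = detect_puncta(image.red, params.spots, channel_name="red")
    green = detect_puncta(image.green, params.spots, channel_name="green")
    n_ap, n_al, n_green_only, _ = classify_vesicles(red, green, params.coloc_radius_px)
    if n_nuclei > 0:
        per_ap, per_al = n_ap / n_nuclei, n_al / n_nuclei
    else:
        per_ap = per_al = float("nan")
    return FieldQuantification(
        source_id=image.source_id,
        n_nuclei=n_nuclei,
        n_red_total=len(red),
        n_ap=n_ap,
        n_al=n_al,
        n_green_only=n_green_only,
        per_cell_ap=per_ap,
        per_cell_al=per_al,
        qc_flags=qc,
    )


def benchmark_classification(
    truth, red: Sequence[Punctum], matching: Sequence[tuple[int, int]],
    match_radius_px: float = 3.0,
) -> dict[str, dict[str, int]]:
    """Score classified detections against simulator ground truth.

    Matches detected autophagosome (matched red) and autolysosome (unmatched
    red) centroids to the true spot positions of each class within
    ``match_radius_px``; returns per-class true/false positive and false
    negative counts for precision/recall/F1 benchmarking.
    """
    ap_idx = {i for i, _ in matching}
    det = {
        "AP": np.asarray([red[i].centroid for i in sorted(ap_idx)]).reshape(-1, 2),
        "AL": np.asarray(
            [red[i].centroid for i in range(len(red)) if i not in ap_idx]
        ).reshape(-1, 2),
    }
    out = {}
    for cls in ("AP", "AL"):
        true_pts = truth.puncta_of(cls)
        tp = len(greedy_match_points(true_pts, det[cls], match_radius_px))
        out[cls] = {"tp": tp, "fp": len(det[cls]) - tp, "fn": len(true_pts) - tp}
    return out


def read_field_tiff(path: str | Path, channel_order: Sequence[str] | None = None) -> FieldImage:
    """Read a multi-channel TIFF as a FieldImage.

    Channel order is taken from the JSON image description written by the
    simulator when present, else from ``channel_order``, else assumed
    (nuclei, green, red).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray().astype(float)
        order = None
        desc = tf.pages[0].description
        if desc:
            try:
                order = json.loads(desc).get("channel_order")
            except (ValueError, AttributeError):
                order = None
    if channel_order is not None:
        order = list(channel_order)
    if order is None:
        order = ["nuclei", "green", "red"]
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path.name}: expected a 3-channel TIFF stack")
    chans = {name: stack[i] for i, name in enumerate(order)}
    return FieldImage(
        chans["nuclei"], chans["green"], chans["red"], source_id=path.stem
    )


def quantify_batch(
    sample_sheet: pd.DataFrame | str | Path,
    image_dir: str | Path,
    params: QuantParams = QuantParams(),
    *,
    channel_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify every field in a sample sheet; errors are recorded, not fatal.

    Rows are processed in sample-sheet order (never filesystem order). Returns
    the long-format results table and a list of per-row error records.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = pd.read_csv(sample_sheet)
    image_dir = Path(image_dir)
    rows = []
    errors: list[dict] = []
    for _, sheet_row in sample_sheet.iterrows():
        fname = sheet_row["file"]
        try:
            image = read_field_tiff(image_dir / fname, channel_order)
            q = quantify_field(image, params)
        except (OSError, ValueError) as exc:
            log.warning("skipping %s: %s", fname, exc)
            errors.append({"file": fname, "error": str(exc)})
            continue
        rows.append(
            {
                "source_id": q.source_id,
                "condition": sheet_row.get("condition", ""),
                "timepoint": sheet_row.get("timepoint", ""),
                "n_nuclei": q.n_nuclei,
                "n_red_total": q.n_red_total,
                "n_AP": q.n_ap,
                "n_AL": q.n_al,
                "n_green_only": q.n_green_only,
                "per_cell_AP": q.per_cell_ap,
                "per_cell_AL": q.per_cell_al,
                "qc_flags": ";".join(q.qc_flags),
            }
        )
    columns = [
        "source_id", "condition", "timepoint", "n_nuclei", "n_red_total",
        "n_AP", "n_AL", "n_green_only", "per_cell_AP", "per_cell_AL", "qc_flags",
    ]
    return pd.DataFrame(rows, columns=columns), errors
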