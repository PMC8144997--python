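# Methods

## Scope and rationale

`fluxquant` quantifies autophagic flux from tandem mCherry-EGFP-LC3B
fluorescence microscopy and complements that readout with 2^−ΔΔCt qPCR
quantification and RECIST-adapted xenograft response scoring. The tandem
reporter exploits the pH sensitivity of EGFP: LC3B on an autophagosome (AP)
fluoresces in both the red (mCherry) and green (EGFP) channels, while fusion
with a lysosome acidifies the lumen and quenches EGFP, so an autolysosome
(AL) is red-only. Counting the two classes per cell, with and without a
late-stage flux inhibitor such as bafilomycin A1, separates increased
autophagosome *production* from blocked autophagosome *clearance*.

All validation is against synthetic data with exact ground truth; the
simulators are first-class, tested modules, not test fixtures.

## Image simulation (`synthcells`)

One field of view is three registered 2-D channels: nuclei (DAPI), green
(EGFP), red (mCherry). Nuclei are rendered as filled disks (radius ~
N(9, 1) px by default) with a mild radial intensity falloff; centers are
rejection-sampled so disks never touch. Puncta are isotropic 2-D Gaussian
spots (σ = 1.5 px, peak 150 intensity units over a background of 20),
placed uniformly in a cytoplasmic annulus around a parent nucleus; per-cell
counts are Poisson with configurable means (default 3 AP + 3 AL per cell,
6 cells in a 256×256 field). AP spots are rendered at full intensity in red
and green; AL spots at full intensity in red and at `green_quench_factor`
(default 0.15) of it in green. Noise is the standard fluorescence-camera
model: Poisson shot noise on total signal plus additive Gaussian read
noise, both optional. Images are written as 16-bit TIFF (headroom for
intensity ratios), channel order declared in the image description.

**Minimum spot separation.** The generator enforces a minimum center
separation of 4σ between all puncta (bounded rejection sampling). The sum
of two equal-width Gaussians becomes unimodal below ≈2.4σ separation, so
spots closer than that are not countable by *any* detector and a tighter
floor would make "exact recovery at zero noise" an ill-posed target; at 4σ
every rendered spot is an unambiguous local structure. Overlap of spot
tails is still permitted and exercised.

**What the simulator does not emulate:** transfection mosaicism (every
simulated cell carries the reporter; the real assay analyzes transfected
cells only), uneven illumination, chromatic offset between channels,
out-of-focus light, z-structure, photobleaching and stage drift. Passing
the recovery benchmarks therefore demonstrates correctness of the counting
and classification logic under the stated camera model — not robustness to
every real-microscope artifact. Magnification and pixel size are free
parameters, not calibrated to any instrument.

## Image quantification (`puncta`)

*Nuclei*: Gaussian smoothing (σ = 2 px) → Otsu global threshold → hole
filling → removal of objects under 30 px → distance-transform watershed
(peaks of the smoothed distance map, minimum peak distance 7 px) to split
touching nuclei. The nucleus count is the cell-number denominator; vesicles
are *not* assigned to individual cells (per-cell values are field totals
divided by the field nucleus count).

*Puncta*: local background is a 15-px median filter, subtracted and clipped
at zero. Detection is scale-normalized Laplacian-of-Gaussian filtering at
the expected spot scale; candidate peaks (3×3 local maxima over a low
response floor, deduplicated below 2 px) pass a contrast filter — smoothed
peak height above background ≥ `min_contrast` (default 50 intensity units,
corrected for the smoothing attenuation σ²/(σ²+1)) — and an area filter
(3–200 px above half-maximum). Centroids are refined to subpixel precision
by weighting the compact positive LoG response in a 3×3 window, which is
insensitive to the flanks of neighboring spots. `min_contrast` doubles as
the double-positive detection threshold: the quenched-EGFP residue of an
autolysosome (0.15 × 150 = 22.5 units) sits well below it, full-intensity
spots (150) well above, with ≥ 3σ margins under the default noise model.

*Classification* is object-based: red and green puncta are detected
independently, then matched one-to-one greedily in ascending centroid
distance within `coloc_radius_px` (default 2 px ≈ the spot radius), ties
broken by red then green index. Matched red = AP, unmatched red = AL,
unmatched green is reported but excluded from the flux classes. Green
intensity sampled under a red spot is deliberately *not* used — the
symmetric object-level criterion avoids a second ad-hoc intensity threshold
and tolerates small chromatic offsets. Greedy matching is deterministic and
order-invariant but not guaranteed assignment-optimal; the test suite
documents a two-point instance where it strands a match. Conservation
(n_AP + n_AL = n_red) holds structurally and is asserted on every field.

## Group statistics and the flux verdict (`fluxstats`)

The unit of replication is the field of view. Comparisons are one-way ANOVA
with Tukey HSD post hoc tests (α = 0.05); fold changes are tested with a
two-sided one-sample t-test on the log scale against log 1. Degenerate
inputs (zero pooled variance; constant fold changes off the null) raise
explicit errors instead of returning NaN.

For a four-condition design (control, drug, bafilomycin, drug+bafilomycin)
the verdict rule is:

* **flux induced** iff per-cell AL is significantly increased in drug vs
  control *and* per-cell AP is significantly increased in drug+baf vs baf
  (both Tukey-adjusted, in the stated direction);
* **flux blocked** iff per-cell AP is significantly increased in drug vs
  control while AL is not significantly increased;
* **indeterminate** otherwise.

The induced verdict requires two independent significant contrasts rather
than an interaction test, mirroring how such designs are usually argued;
under the null its false-positive rate is bounded near α² (measured 0/50
in the acceptance run).

## qPCR (`qpcr`)

ΔCt = mean Ct(target) − arithmetic mean Ct of the reference genes (SDHA and
HPRT by default; the arithmetic Ct mean equals the geometric mean of their
expression levels). ΔΔCt = per-condition mean ΔCt − mean control ΔCt; fold
change = 2^−ΔΔCt, exactly, with per-sample fold changes retained. Technical
replicates are averaged at the Ct level first. A target Ct missing or above
40 cycles is "not detectable": the condition is flagged and excluded rather
than raising; an undetectable *reference* gene is a hard error. No
amplification-efficiency (Pfaffl) correction is applied.

## Xenograft response (`xeno`)

Percent change = 100 × (V_followup − V_baseline)/V_baseline. Calls: PD
(progressive disease) iff change ≥ +20%, PR (partial response) iff change
≤ −30%, both boundaries inclusive; everything between is SD (stable
disease), the residual category. Thresholds are applied to volumes directly
— no diameter conversion — since the assay measures volumes. Cohort
summaries keep exact percentages alongside integer display rounding, and
the waterfall ordering is percent change descending within arm.

## Problem sizes and numerical choices

Default benchmark sizes: 256×256 px fields with 6 cells (≈36 spots); 20
fields for the recovery benchmarks; 100 randomized 128×128 fields for the
conservation fuzz; 50 replicates of 10-fields-per-condition cohorts
(ground-truth counts only, no rendering) for verdict-recovery rates; 2000
simulations for ANOVA calibration. These sizes give Monte-Carlo standard
errors comfortably below the tolerances being checked while keeping a full
run in minutes on one core. All randomness flows from explicit seeds
(NumPy `default_rng`; per-field seeds derived via `SeedSequence`), so every
output — including rendered TIFF bytes — is reproducible.

## Known limitations

* Per-cell normalization divides field totals by nucleus count; it cannot
  detect cell-to-cell heterogeneity, and untransfected cells would inflate
  the denominator on real data.
* Greedy colocalization can differ from the assignment-optimal matching in
  dense scenes (it is maximal, not maximum).
* The flux rule is qualitative: it reports direction and significance, not
  effect size, and an interaction ANOVA is out of scope.
* The detector's defaults are tuned to the simulated point-spread scale
  (σ ≈ 1.5 px); real data at other magnifications need `expected_sigma_px`
  and `min_contrast` adjusted.
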