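"""Group statistics and autophagic-flux interpretation.

The unit of replication is the field of view. Group comparisons follow the
standard assay workflow: one-way ANOVA with Tukey HSD post hoc tests on
per-cell vesicle counts (alpha = 0.05), a one-sample t-test on log fold
changes against 1, and a decision rule for drug +/- bafilomycin designs:

* flux induced — the drug raises autolysosomes versus control AND, when
  late-stage fusion is blocked with bafilomycin, the drug raises
  autophagosomes versus bafilomycin alone (de novo autophagosomes pile up);
* flux blocked — the drug raises autophagosomes versus control without an
  autolysosome increase (impaired autophagosome-lysosome fusion);
* indeterminate otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DegenerateDataError",
    "ComparisonResult",
    "ConditionSummary",
    "FluxDesign",
    "FluxVerdict",
    "anova_tukey",
    "one_sample_fc_test",
    "summarize_conditions",
    "interpret_flux",
    "interpret_flux_table",
]

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined (e.g. zero pooled variance)."""


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # "anova" | "tukey" | "t" | "one_sample_t"
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    mean_diff: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    timepoint: str
    n_fields: int
    mean_per_cell_ap: float
    mean_per_cell_al: float
    sd_per_cell_ap: float
    sd_per_cell_al: float


@dataclass(frozen=True)
class FluxDesign:
    """Labels of the four conditions of a drug +/- bafilomycin experiment."""

    control: str = "control"
    drug: str = "drug"
    baf: str = "baf"
    drug_baf: str = "drug_baf"

    @property
    def conditions(self) -> tuple[str, str, str, str]:
        return (self.control, self.drug, self.baf, self.drug_baf)


@dataclass
class FluxVerdict:
    verdict: str  # "flux_induced" | "flux_blocked" | "indeterminate"
    supporting: list[ComparisonResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = ALPHA
) -> list[ComparisonResult]:
    """One-way ANOVA plus all pairwise Tukey HSD comparisons.

    Returns the omnibus result first, then one result per pair (group labels
    in sorted order). Raises :class:`DegenerateDataError` when the pooled
    within-group variance is zero.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(groups[k], dtype=float) for k in labels}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {k!r} contains non-finite values")
    if all(np.ptp(a) == 0 for a in arrays.values()):
        raise DegenerateDataError("zero pooled within-group variance")

    f_stat, p = stats.f_oneway(*(arrays[k] for k in labels))
    results = [ComparisonResult("anova", float(f_stat), float(p), tuple(labels),
                                alpha=alpha)]

    values = np.concatenate([arrays[k] for k in labels])
    keys = np.concatenate([[k] * len(arrays[k]) for k in labels])
    tk = pairwise_tukeyhsd(values, keys, alpha=alpha)
    summary = tk.summary().data[1:]  # rows: g1, g2, meandiff, p-adj, lo, hi, reject
    qstats = np.atleast_1d(tk.meandiffs) / np.atleast_1d(tk.std_pairs)
    for row, q, padj, (lo, hi) in zip(
        summary, qstats, np.atleast_1d(tk.pvalues), tk.confint
    ):
        g1, g2 = str(row[0]), str(row[1])
        mean_diff = float(arrays[g2].mean() - arrays[g1].mean())
        results.append(
            ComparisonResult(
                "tukey",
                float(q),
                float(min(max(padj, 0.0), 1.0)),
                (g1, g2),
                mean_diff=mean_diff,
                ci_lower=float(lo),
                ci_upper=float(hi),
                alpha=alpha,
            )
        )
    return results


def one_sample_fc_test(
    fold_changes: Sequence[float], null_value: float = 1.0, alpha: float = ALPHA
) -> ComparisonResult:
    """Two-sided one-sample t-test of fold changes against a null ratio.

    Performed on log-transformed values against log(null_value), as befits
    ratio data. A constant sample equal to the null gives statistic 0 and
    p = 1; a constant sample elsewhere has an undefined statistic and raises
    :class:`DegenerateDataError`.
    """
    x = np.asarray(fold_changes, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 fold changes")
    if np.any(x <= 0):
        raise ValueError("fold changes must be positive")
    logx = np.log(x)
    log0 = np.log(null_value)
    if np.ptp(logx) == 0:
        if np.isclose(logx[0], log0):
            return ComparisonResult("one_sample_t", 0.0, 1.0, alpha=alpha)
        raise DegenerateDataError(
            "constant fold changes differing from the null: t undefined"
        )
    t_stat, p = stats.ttest_1samp(logx, log0)
    return ComparisonResult("one_sample_t", float(t_stat), float(p), alpha=alpha)


# ---------------------------------------------------------------------------
# Flux interpretation
# ---------------------------------------------------------------------------

def summarize_conditions(results: pd.DataFrame) -> list[ConditionSummary]:
    """Per-condition means and dispersions of the per-cell class counts.

    QC-flagged fields (no nuclei) are excluded: their per-cell values are NaN.
    """
    out = []
    for (cond, tp), grp in results.groupby(["condition", "timepoint"], sort=True):
        ap = grp["per_cell_AP"].dropna()
        al = grp["per_cell_AL"].dropna()
        out.append(
            ConditionSummary(
                condition=str(cond),
                timepoint=str(tp),
                n_fields=int(len(grp)),
                mean_per_cell_ap=float(ap.mean()),
                mean_per_cell_al=float(al.mean()),
                sd_per_cell_ap=float(ap.std(ddof=1)) if len(ap) > 1 else 0.0,
                sd_per_cell_al=float(al.std(ddof=1)) if len(al) > 1 else 0.0,
            )
        )
    return out


def _tukey_lookup(
    comparisons: Sequence[ComparisonResult], a: str, b: str
) -> tuple[ComparisonResult, float]:
    """Find the Tukey pair (a, b); returns (result, signed mean b - a)."""
    for r in comparisons:
        if r.test != "tukey":
            continue
        if r.groups == (a, b):
            return r, r.mean_diff
        if r.groups == (b, a):
            return r, -r.mean_diff
    raise KeyError(f"no Tukey comparison for pair ({a}, {b})")


def interpret_flux(
    ap_groups: Mapping[str, Sequence[float]],
    al_groups: Mapping[str, Sequence[float]],
    design: FluxDesign = FluxDesign(),
    alpha: float = ALPHA,
) -> FluxVerdict:
    """Apply the drug/bafilomycin decision rule to per-field per-cell counts.

    ``ap_groups`` and ``al_groups`` map each condition label to the per-field
    per-cell autophagosome and autolysosome counts. Significance means a
    Tukey-adjusted p < alpha in the stated direction; the verdict is invariant
    to the order in which conditions are supplied.
    """
    for cond in design.conditions:
        if cond not in ap_groups or cond not in al_groups:
            raise ValueError(f"missing condition {cond!r}")

    ap_comp = anova_tukey({k: ap_groups[k] for k in design.conditions}, alpha)
    al_comp = anova_tukey({k: al_groups[k] for k in design.conditions}, alpha)

    al_dc, al_dc_diff = _tukey_lookup(al_comp, design.control, design.drug)
    ap_dc, ap_dc_diff = _tukey_lookup(ap_comp, design.control, design.drug)
    ap_bb, ap_bb_diff = _tukey_lookup(ap_comp, design.baf, design.drug_baf)

    al_up_drug = al_dc.significant and al_dc_diff > 0
    ap_up_drug = ap_dc.significant and ap_dc_diff > 0
    ap_up_baf_combo = ap_bb.significant and ap_bb_diff > 0

    supporting = [al_dc, ap_dc, ap_bb]
    if al_up_drug and ap_up_baf_combo:
        return FluxVerdict("flux_induced", supporting)
    if ap_up_drug and not al_up_drug:
        return FluxVerdict("flux_blocked", supporting)
    return FluxVerdict("indeterminate", supporting)


def interpret_flux_table(
    results: pd.DataFrame, design: FluxDesign = FluxDesign(), alpha: float = ALPHA
) -> FluxVerdict:
    """Convenience wrapper taking a per-field results table.

    Expects columns ``condition``, ``per_cell_AP``, ``per_cell_AL``;
    QC-excluded fields (NaN per-cell values) are dropped.
    """
    ap_groups = {}
    al_groups = {}
    for cond, grp in results.groupby("condition"):
        ap_groups[str(cond)] = grp["per_cell_AP"].dropna().to_numpy()
        al_groups[str(cond)] = grp["per_cell_AL"].dropna().to_numpy()
    return interpret_flux(ap_groups, al_groups, design, alpha)
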