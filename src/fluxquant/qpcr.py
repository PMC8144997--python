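"""Relative gene-expression quantification by the 2^-ddCt method.

Normalizes each target gene to the arithmetic mean Ct of two reference
genes (default SDHA and HPRT — equivalent to the geometric mean of their
expression levels) and to a control condition:

    dCt(sample)        = mean Ct(target) - mean Ct(references)
    ddCt(condition)    = mean dCt(condition) - mean dCt(control)
    fold change        = 2^(-ddCt)

Technical replicates are averaged at the Ct level before dCt. A target with
no usable Ct in a sample (missing, or above the detectability cutoff,
default 40 cycles) is flagged "not detectable" rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fluxstats import DegenerateDataError, one_sample_fc_test

__all__ = [
    "DEFAULT_REF_GENES",
    "DETECT_CUTOFF_CT",
    "FoldChangeResult",
    "delta_delta_ct",
    "fc_report",
]

DEFAULT_REF_GENES = ("SDHA", "HPRT")
DETECT_CUTOFF_CT = 40.0

_REQUIRED_COLUMNS = {"sample_id", "condition", "gene", "replicate", "Ct"}


@dataclass
class FoldChangeResult:
    gene: str
    condition: str
    fold_change: float  # 2^(-ddCt), NaN when not detectable
    delta_ct: float
    delta_delta_ct: float
    per_sample_fold_changes: dict[str, float] = field(default_factory=dict)
    detectable: bool = True


def _validate_table(table: pd.DataFrame, ref_genes: Sequence[str],
                    control_condition: str) -> pd.DataFrame:
    missing = _REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if control_condition not in set(table["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from table")
    present = set(table["gene"])
    for g in ref_genes:
        if g not in present:
            raise ValueError(f"reference gene {g!r} absent from table")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    target_genes: Sequence[str],
    ref_genes: Sequence[str] = DEFAULT_REF_GENES,
    control_condition: str = "control",
    detect_cutoff: float = DETECT_CUTOFF_CT,
) -> list[FoldChangeResult]:
    """Per-condition fold changes for each target gene.

    Returns one result per (gene, condition) pair, including the control
    condition (fold change 1 by construction). Conditions in which a target
    was never detected carry ``detectable=False`` and NaN fold change; a
    missing reference gene is a hard error.
    """
    table = _validate_table(table, ref_genes, control_condition)
    usable = table[table["Ct"] <= detect_cutoff]

    # Technical replicates averaged at Ct level, per (sample, gene).
    ct = (
        usable.groupby(["condition", "sample_id", "gene"], sort=True)["Ct"]
        .mean()
        .reset_index()
    )

    # Reference Ct per sample: arithmetic mean over the reference genes.
    ref = ct[ct["gene"].isin(ref_genes)]
    ref_per_sample = ref.groupby("sample_id")["Ct"].mean()
    n_refs_per_sample = ref.groupby("sample_id")["gene"].nunique()
    bad = n_refs_per_sample[n_refs_per_sample < len(ref_genes)]
    if len(bad) or set(ct["sample_id"]) - set(ref_per_sample.index):
        missing_in = sorted(set(ct["sample_id"]) - set(ref_per_sample.index)) + list(bad.index)
        raise ValueError(f"reference gene(s) undetectable in sample(s): {missing_in}")

    conditions = list(dict.fromkeys(table["condition"]))
    results: list[FoldChangeResult] = []
    for gene in target_genes:
        gct = ct[ct["gene"] == gene].set_index("sample_id")
        dct = gct["Ct"] - ref_per_sample.loc[gct.index]
        by_cond = gct["condition"]
        control_dct = dct[by_cond == control_condition]
        control_mean = control_dct.mean() if len(control_dct) else np.nan
        for cond in conditions:
            cond_dct = dct[by_cond == cond]
            if len(cond_dct) == 0 or np.isnan(control_mean):
                results.append(
                    FoldChangeResult(gene, cond, float("nan"), float("nan"),
                                     float("nan"), detectable=False)
                )
                continue
            ddct = float(cond_dct.mean() - control_mean)
            per_sample = {
                s: float(2.0 ** -(d - control_mean)) for s, d in cond_dct.items()
            }
            results.append(
                FoldChangeResult(
                    gene=gene,
                    condition=cond,
                    fold_change=float(2.0 ** -ddct),
                    delta_ct=float(cond_dct.mean()),
                    delta_delta_ct=ddct,
                    per_sample_fold_changes=per_sample,
                )
            )
    return results


def fc_report(
    experiments: Sequence[Sequence[FoldChangeResult]],
    control_condition: str = "control",
) -> pd.DataFrame:
    """Combine fold changes across independent experiments.

    Each element of ``experiments`` is the :func:`delta_delta_ct` output of
    one experiment. Per (gene, condition) the report carries the geometric
    mean fold change, its dispersion (sd of log2 fold changes), and a
    one-sample t-test against 1 on the log scale. With fewer than two
    experiments the p-value is omitted and flagged.
    """
    records: dict[tuple[str, str], list[float]] = {}
    detect: dict[tuple[str, str], bool] = {}
    for exp in experiments:
        for r in exp:
            key = (r.gene, r.condition)
            detect[key] = detect.get(key, False) or r.detectable
            if r.detectable and np.isfinite(r.fold_change):
                records.setdefault(key, []).append(r.fold_change)

    rows = []
    for (gene, cond), fcs in sorted(records.items()):
        log2fc = np.log2(fcs)
        n = len(fcs)
        p = np.nan
        flag = ""
        if cond == control_condition:
            flag = "control"
        elif n < 2:
            flag = "single experiment: p omitted"
        else:
            try:
                p = one_sample_fc_test(fcs).p_value
            except DegenerateDataError:
                flag = "degenerate: constant fold changes"
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "n_experiments": n,
                "fold_change": float(2.0 ** log2fc.mean()),
                "sd_log2_fc": float(log2fc.std(ddof=1)) if n > 1 else 0.0,
                "p_value": p,
                "flag": flag,
            }
        )
    for (gene, cond), seen in sorted(detect.items()):
        if not seen:
            rows.append(
                {
                    "gene": gene, "condition": cond, "n_experiments": 0,
                    "fold_change": np.nan, "sd_log2_fc": np.nan,
                    "p_value": np.nan, "flag": "not detectable",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "condition", "n_experiments", "fold_change",
                 "sd_log2_fc", "p_value", "flag"],
    ).sort_values(["gene", "condition"], ignore_index=True)
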