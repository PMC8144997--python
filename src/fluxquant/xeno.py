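"""Zebrafish-xenograft tumor response: percent volume change, RECIST-adapted
classification, and waterfall summaries.

Thresholds follow RECIST 1.1 adapted to zebrafish tumor volumes: progressive
disease (PD) is at least a 20% volume increase, partial response (PR) at
least a 30% decrease; both boundaries inclusive. Everything between is
labeled stable disease (SD) as the residual category. Thresholds are applied
to volumes directly (no diameter conversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PD_THRESHOLD_PCT",
    "PR_THRESHOLD_PCT",
    "XenoRecord",
    "volume_change",
    "classify_response",
    "records_from_table",
    "cohort_summary",
    "waterfall_plot",
]

PD_THRESHOLD_PCT = 20.0   # >= +20% volume increase
PR_THRESHOLD_PCT = -30.0  # <= -30% volume decrease


@dataclass(frozen=True)
class XenoRecord:
    """One xenograft: volumes at baseline (day 1) and follow-up (day 3)."""

    fish_id: str
    arm: str
    volume_baseline: float
    volume_followup: float

    def __post_init__(self) -> None:
        if self.volume_baseline <= 0:
            raise ValueError(
                f"fish {self.fish_id!r}: baseline volume must be positive"
            )
        if self.volume_followup < 0:
            raise ValueError(
                f"fish {self.fish_id!r}: follow-up volume must be nonnegative"
            )

    @property
    def pct_change(self) -> float:
        return volume_change(self)


def volume_change(record: XenoRecord) -> float:
    """Signed percent change in tumor volume from baseline to follow-up."""
    return 100.0 * (record.volume_followup - record.volume_baseline) / record.volume_baseline


def classify_response(pct_change: float) -> str:
    """RECIST-adapted call from the percent volume change.

    PD iff change >= +20%, PR iff change <= -30%, SD otherwise.
    """
    if not np.isfinite(pct_change):
        raise ValueError("pct_change must be finite")
    if pct_change >= PD_THRESHOLD_PCT:
        return "PD"
    if pct_change <= PR_THRESHOLD_PCT:
        return "PR"
    return "SD"


def records_from_table(table: pd.DataFrame) -> list[XenoRecord]:
    """Build records from a (fish_id, arm, volume_baseline, volume_followup) table."""
    return [
        XenoRecord(
            str(r.fish_id), str(r.arm),
            float(r.volume_baseline), float(r.volume_followup),
        )
        for r in table.itertuples(index=False)
    ]


def cohort_summary(
    records: Sequence[XenoRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fish response calls and per-arm response rates.

    Returns ``(calls, summary)``: ``calls`` holds one row per fish in
    waterfall order (percent change descending within arm); ``summary`` holds
    per-arm n and exact plus display-rounded PD/SD/PR percentages. Arms with
    no records are excluded with a warning.
    """
    if not records:
        warnings.warn("no xenograft records supplied: empty summary")
        calls = pd.DataFrame(
            columns=["fish_id", "arm", "pct_change", "category"]
        )
        summary = pd.DataFrame(
            columns=["arm", "n", "pct_PD", "pct_SD", "pct_PR",
                     "pct_PD_display", "pct_SD_display", "pct_PR_display"]
        )
        return calls, summary

    calls = pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in records],
            "arm": [r.arm for r in records],
            "pct_change": [r.pct_change for r in records],
        }
    )
    calls["category"] = calls["pct_change"].map(classify_response)
    calls = calls.sort_values(
        ["arm", "pct_change"], ascending=[True, False], ignore_index=True
    )

    rows = []
    for arm, grp in calls.groupby("arm", sort=True):
        n = len(grp)
        pct = {
            cat: 100.0 * (grp["category"] == cat).sum() / n
            for cat in ("PD", "SD", "PR")
        }
        rows.append(
            {
                "arm": arm,
                "n": n,
                "pct_PD": pct["PD"],
                "pct_SD": pct["SD"],
                "pct_PR": pct["PR"],
                "pct_PD_display": int(round(pct["PD"])),
                "pct_SD_display": int(round(pct["SD"])),
                "pct_PR_display": int(round(pct["PR"])),
            }
        )
    return calls, pd.DataFrame(rows)


def waterfall_plot(calls: pd.DataFrame, out_path: str | Path) -> Path:
    """Waterfall plot of per-fish volume changes with threshold guide lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arms = list(dict.fromkeys(calls["arm"]))
    fig, axes = plt.subplots(
        1, max(len(arms), 1), figsize=(4 * max(len(arms), 1), 4),
        sharey=True, squeeze=False,
    )
    colors = {"PD": "#c0392b", "SD": "#7f8c8d", "PR": "#2980b9"}
    for ax, arm in zip(axes[0], arms):
        grp = calls[calls["arm"] == arm]
        ax.bar(
            range(len(grp)),
            grp["pct_change"],
            color=[colors[c] for c in grp["category"]],
        )
        ax.axhline(PD_THRESHOLD_PCT, ls=":", color="black", lw=1)
        ax.axhline(PR_THRESHOLD_PCT, ls=":", color="black", lw=1)
        ax.axhline(0, color="black", lw=0.5)
        ax.set_title(arm)
        ax.set_xlabel("xenograft")
    axes[0][0].set_ylabel("tumor volume change from baseline (%)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
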