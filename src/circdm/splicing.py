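"""Exon-inclusion summaries and the percent-splicing-rescue statistic.

DM1 missplicing shifts the inclusion level of MBNL1-dependent alternative
exons (ATP2A1 exon 22, INSR exon 11, ...) away from the healthy pattern.  A
treatment's effect is summarised as the fraction of the disease-vs-control
gap it closes:

    %rescue = 100 * (%DM1_NTC - %DM1_treated) / (%DM1_NTC - %CTRL_NTC)

where NTC is the non-targeting control condition.  0% means no movement,
100% full restoration of the control inclusion level; values outside
[0, 100] are reported as computed (over- or anti-rescue) and flagged, never
clamped — clamping would hide genuine reversals such as a miRNA mimic
cancelling the rescue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "inclusion_percentage",
    "percent_rescue",
    "RescueResult",
    "rescue_table",
]


def inclusion_percentage(included_signal: float, skipped_signal: float) -> float:
    """Percent inclusion from band (or isoform) signals: 100*inc/(inc+skip)."""
    if included_signal < 0 or skipped_signal < 0:
        raise ValueError("signals must be nonnegative")
    total = included_signal + skipped_signal
    if total == 0:
        raise ValueError("both signals zero; inclusion percentage undefined")
    return 100.0 * included_signal / total


def percent_rescue(pct_dm1_ntc: float, pct_dm1_treated: float, pct_ctrl_ntc: float) -> float:
    """Percent of the DM1-vs-control splicing gap closed by the treatment.

    The statistic is invariant to exchanging inclusion for exclusion
    percentages (replacing every argument by 100 - value), so it can be fed
    either orientation consistently.  A zero denominator means the event is
    not misspliced in the disease condition and rescue is undefined.
    """
    denom = pct_dm1_ntc - pct_ctrl_ntc
    if denom == 0:
        raise ZeroDivisionError(
            "no DM1-vs-CTRL missplicing for this event; percent rescue undefined"
        )
    value = 100.0 * (pct_dm1_ntc - pct_dm1_treated) / denom + 0.0  # normalize -0.0
    if value < 0 or value > 100:
        warnings.warn(
            f"percent rescue {value:.1f}% outside [0, 100] (over-/anti-rescue)",
            stacklevel=2,
        )
    return value


@dataclass
class RescueResult:
    event: str
    percent_rescue: float
    sem: float | None
    per_replicate: list[float]
    n: int
    denominator_condition: str


def rescue_table(
    table: pd.DataFrame,
    dm1_ntc: str = "DM1_NTC",
    treated: str = "DM1_si",
    ctrl_ntc: str = "CTRL_NTC",
) -> list[RescueResult]:
    """Percent rescue per event from a long inclusion table.

    Expects columns ``event``, ``condition``, ``inclusion_pct`` and
    optionally ``replicate``.  When all three conditions share a replicate
    labelling, the statistic is evaluated per matched replicate and
    summarised as mean +/- SEM; otherwise it is evaluated once on condition
    means (no SEM).
    """
    required = {"event", "condition", "inclusion_pct"}
    if not required <= set(table.columns):
        raise ValueError(f"missing columns: {sorted(required - set(table.columns))}")
    out: list[RescueResult] = []
    for event, sub in table.groupby("event", sort=False):
        conds = {c: sub[sub["condition"] == c] for c in (dm1_ntc, treated, ctrl_ntc)}
        missing = [c for c, d in conds.items() if len(d) == 0]
        if missing:
            raise ValueError(f"event {event!r} lacks required conditions: {missing}")

        paired = False
        if "replicate" in sub.columns:
            reps = [set(d["replicate"]) for d in conds.values()]
            common = set.intersection(*reps)
            paired = len(common) >= 2 and all(r == reps[0] for r in reps)
        if paired:
            vals = []
            for rep in sorted(common):
                args = [
                    float(conds[c].loc[conds[c]["replicate"] == rep, "inclusion_pct"].mean())
                    for c in (dm1_ntc, treated, ctrl_ntc)
                ]
                vals.append(percent_rescue(*args))
            vals_arr = np.asarray(vals)
            out.append(
                RescueResult(
                    event=event,
                    percent_rescue=float(vals_arr.mean()),
                    sem=float(vals_arr.std(ddof=1) / np.sqrt(len(vals_arr))),
                    per_replicate=list(map(float, vals_arr)),
                    n=len(vals_arr),
                    denominator_condition=ctrl_ntc,
                )
            )
        else:
            means = [float(conds[c]["inclusion_pct"].mean()) for c in (dm1_ntc, treated, ctrl_ntc)]
            out.append(
                RescueResult(
                    event=event,
                    percent_rescue=percent_rescue(*means),
                    sem=None,
                    per_replicate=[],
                    n=int(len(conds[treated])),
                    denominator_condition=ctrl_ntc,
                )
            )
    return out
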