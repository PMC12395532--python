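"""qPCR cycle-threshold analytics: relative expression, circ/lin ratios,
RNase R resistance and nonparametric group comparison.

All quantities live on the log2 scale natural to qPCR: one cycle difference
corresponds to a twofold abundance difference at 100% amplification
efficiency (efficiency correction is deliberately not applied).  Relative
expression is -dCt against the mean of the UBC and RPL23 reference genes;
the circular-to-linear ratio of a target is derived from raw Cts of the two
amplicons of the same gene, with no reference normalization at all.

Input is a long-format table with columns ``sample``, ``group``, ``target``,
``amplicon_class`` (``circular`` | ``linear`` | ``reference``), ``ct`` and
optionally ``replicate`` and ``treatment`` (``+`` / ``-`` for RNase R).
Replicate Cts are averaged before any delta is formed.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_REFERENCES",
    "relative_expression",
    "circ_lin_ratio",
    "rnase_r_resistance",
    "mann_whitney_u",
    "group_comparison",
]

DEFAULT_REFERENCES = ("UBC", "RPL23")

_BASE_KEYS = ["sample", "group", "target", "amplicon_class"]


def _mean_ct(table: pd.DataFrame, extra_keys: tuple[str, ...] = ()) -> pd.DataFrame:
    """Average replicate Cts per sample/target/class (and extra keys)."""
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycles")
    keys = _BASE_KEYS + [k for k in extra_keys if k in table.columns]
    return table.groupby(keys, as_index=False, sort=False)["ct"].mean()


def _reference_means(mean_ct: pd.DataFrame, references: tuple[str, ...]) -> pd.Series:
    ref = mean_ct[mean_ct["target"].isin(references)]
    per_sample = ref.groupby("sample")["ct"].agg(["mean", "size"])
    complete = per_sample[per_sample["size"] >= len(references)]
    return complete["mean"]


def relative_expression(
    table: pd.DataFrame,
    references: tuple[str, ...] = DEFAULT_REFERENCES,
    case_label: str = "DM1",
    control_label: str = "CTRL",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample -dCt values and per-target group log2 fold changes.

    The normalized value of a target in a sample is
    ``-(Ct_target - mean(Ct_ref1, Ct_ref2))`` so that larger means more
    abundant.  The group log2 fold change is the difference of group means
    of those normalized values, case minus control.  Samples lacking a
    complete reference set are dropped with a warning.

    Returns ``(per_sample, per_group)`` data frames.
    """
    mean_ct = _mean_ct(table)
    ref_mean = _reference_means(mean_ct, references)
    targets = mean_ct[~mean_ct["target"].isin(references)].copy()

    missing_ref = set(targets["sample"]) - set(ref_mean.index)
    if missing_ref:
        warnings.warn(
            f"samples without complete reference Cts excluded: {sorted(missing_ref)}",
            stacklevel=2,
        )
        targets = targets[~targets["sample"].isin(missing_ref)]

    targets["normalized"] = -(targets["ct"] - targets["sample"].map(ref_mean))
    per_sample = targets[_BASE_KEYS + ["normalized"]]

    pivot = per_sample.groupby(["target", "amplicon_class", "group"])["normalized"].mean().unstack("group")
    rows = []
    for (target, cls), row in pivot.iterrows():
        if case_label in row.index and control_label in row.index:
            rows.append(
                {
                    "target": target,
                    "amplicon_class": cls,
                    "log2fc": row[case_label] - row[control_label],
                    "mean_case": row[case_label],
                    "mean_control": row[control_label],
                }
            )
    return per_sample.reset_index(drop=True), pd.DataFrame(rows)


def circ_lin_ratio(
    table: pd.DataFrame,
    literal_sign: bool = False,
) -> pd.DataFrame:
    """Per-sample log2(circ/lin) from raw Cts of the paired amplicons.

    At equal efficiency a lower Ct means exponentially more template, so the
    abundance-consistent ratio is ``Ct_linear - Ct_circular``: positive when
    the circular isoform dominates.  ``literal_sign=True`` instead reports
    the raw subtraction circular minus linear (the same number negated),
    matching protocols that tabulate dCt directly.  No reference
    normalization is involved.  Samples missing either member of the pair
    are excluded.
    """
    mean_ct = _mean_ct(table)
    pairs = mean_ct[mean_ct["amplicon_class"].isin(["circular", "linear"])]
    wide = pairs.pivot_table(
        index=["sample", "group", "target"],
        columns="amplicon_class",
        values="ct",
        aggfunc="mean",
    ).reset_index()
    if "circular" not in wide.columns and "linear" not in wide.columns:
        raise ValueError("table contains no circular/linear amplicon rows")
    for col in ("circular", "linear"):  # one class absent -> no complete pairs
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide.dropna(subset=["circular", "linear"])
    value = wide["linear"] - wide["circular"]
    wide["log2_circ_lin"] = -value if literal_sign else value
    return wide[["sample", "group", "target", "log2_circ_lin"]].reset_index(drop=True)


def rnase_r_resistance(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2 fraction retained after RNase R digestion, per target.

    RNase R is a 3'->5' exoribonuclease that degrades linear RNAs but spares
    covalently closed circles.  For paired treated (``+``) / untreated
    (``-``) measurements of the same sample and amplicon,
    ``log2_retained = -(Ct_treated - Ct_untreated)``: approximately 0 for a
    resistant circle, strongly negative for a degraded linear transcript.
    Unpaired records are excluded with a warning.

    Returns ``(per_sample, per_target)``; the per-target frame carries the
    mean log2 retained fraction and a ``resistant`` call at the
    conventional -1 threshold (at most twofold loss).
    """
    if "treatment" not in table.columns:
        raise ValueError("rnase_r_resistance requires a 'treatment' column with '+'/'-'")
    mean_ct = _mean_ct(table, extra_keys=("treatment",))
    wide = mean_ct.pivot_table(
        index=["sample", "target", "amplicon_class"],
        columns="treatment",
        values="ct",
        aggfunc="mean",
    ).reset_index()
    paired = wide.dropna(subset=["+", "-"]) if {"+", "-"} <= set(wide.columns) else wide.iloc[0:0]
    n_dropped = len(wide) - len(paired)
    if n_dropped:
        warnings.warn(f"{n_dropped} unpaired RNase R records excluded", stacklevel=2)
    if len(paired) == 0:
        raise ValueError("no paired +/- RNase R measurements found")
    paired = paired.copy()
    paired["log2_retained"] = -(paired["+"] - paired["-"])
    per_sample = paired[["sample", "target", "amplicon_class", "log2_retained"]]
    per_target = (
        per_sample.groupby(["target", "amplicon_class"], as_index=False)["log2_retained"].mean()
    )
    per_target["resistant"] = per_target["log2_retained"] > -1.0
    return per_sample.reset_index(drop=True), per_target


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with mid-rank ties.

    Returns ``(U, p)`` where U counts, over all pairs, the times an x-value
    exceeds a y-value (ties count one half).  For combined sample sizes up
    to 12 the p-value is computed by exact enumeration of the permutation
    distribution of U (valid under ties, unlike the classical tables);
    larger samples use the normal approximation with the tie-corrected
    variance.  If every pooled value is identical the test is vacuous and
    p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Mann-Whitney p set to 1", stacklevel=2)
        return u, 1.0

    mu = n1 * n2 / 2
    if n1 + n2 <= 12:
        # exact permutation distribution of U under the observed (tied) ranks
        obs_dev = abs(u - mu)
        base = n1 * (n1 + 1) / 2
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - base
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12 * (n + 1 - tie_term)
        z = (u - mu) / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
    return u, min(1.0, float(p))


def group_comparison(
    ratios: pd.DataFrame,
    value_col: str = "log2_circ_lin",
    case_label: str = "DM1",
    control_label: str = "CTRL",
    fdr_column: bool = False,
) -> pd.DataFrame:
    """Per-target Mann-Whitney comparison of a per-sample quantity.

    Works on the output of :func:`circ_lin_ratio` or on per-sample relative
    expression; reports the raw two-sided p per target (matching
    per-candidate reporting) with an optional Benjamini-Hochberg column.
    """
    rows = []
    for target, sub in ratios.groupby("target", sort=False):
        case = sub.loc[sub["group"] == case_label, value_col].to_numpy()
        ctrl = sub.loc[sub["group"] == control_label, value_col].to_numpy()
        if len(case) == 0 or len(ctrl) == 0:
            continue
        u, p = mann_whitney_u(case, ctrl)
        rows.append(
            {
                "target": target,
                "mean_case": case.mean(),
                "mean_control": ctrl.mean(),
                "difference": case.mean() - ctrl.mean(),
                "U": u,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if fdr_column and len(out):
        from statsmodels.stats.multitest import multipletests

        out["fdr_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
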