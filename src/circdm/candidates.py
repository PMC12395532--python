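"""Two-study intersection filter for DM1 circRNA candidates.

Candidate circRNAs are defined by intersecting two independent differential
analyses of the same disease: a circRNA qualifies when it shows a high
circular-to-linear ratio, is strongly and significantly upregulated in study
A (p-value based), and is significantly increased in study B (FDR based).
Applied with the thresholds ratio > 1, fold change >= 4, p < 0.02 and
FDR < 0.1 this is the filter that yields the published 21-candidate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterCriteria", "select_candidates", "validate_candidate_table"]

REQUIRED_COLUMNS = ("id", "ratio", "log2fc", "p", "fdr")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for the two-study candidate intersection.

    min_ratio is exclusive (ratio strictly greater), min_fold_change is a
    linear-scale factor applied inclusively on the log2 scale
    (log2fc >= log2(min_fold_change)), and the probability bounds are
    exclusive upper limits as printed (p < max_p_study_a, fdr < max_fdr_study_b).
    """

    min_ratio: float = 1.0
    min_fold_change: float = 4.0
    max_p_study_a: float = 0.02
    max_fdr_study_b: float = 0.1
    require_ratio_in_both: bool = False

    def __post_init__(self) -> None:
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        for name in ("max_p_study_a", "max_fdr_study_b"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def validate_candidate_table(table: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{name} is missing required columns: {missing}")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{name} has duplicated circRNA ids: {dupes}")
    bad = table[["p", "fdr"]].to_numpy(dtype=float)
    if np.any((bad < 0) | (bad > 1)):
        raise ValueError(f"{name}: p and fdr must lie in [0, 1]")
    return table.set_index("id", drop=False)


def select_candidates(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    criteria: FilterCriteria = FilterCriteria(),
) -> pd.DataFrame:
    """Intersect two candidate tables under the stated thresholds.

    A circRNA id is selected iff it is present in both tables and, in study
    A, ratio > min_ratio, log2fc >= log2(min_fold_change) and
    p < max_p_study_a, and, in study B, fdr < max_fdr_study_b with a
    positive direction (log2fc > 0, "increased").  With
    ``require_ratio_in_both`` the ratio threshold is also applied to study B.

    Returns the selected rows of study A joined with study B columns
    (suffixed ``_b``), ordered as in study A.
    """
    a = validate_candidate_table(table_a, "table_a")
    b = validate_candidate_table(table_b, "table_b")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        warnings.warn("candidate tables share no circRNA ids; empty selection", stacklevel=2)

    a = a.loc[shared]
    b = b.loc[shared]
    log2_min_fc = np.log2(criteria.min_fold_change)
    keep = (
        (a["ratio"] > criteria.min_ratio)
        & (a["log2fc"] >= log2_min_fc)
        & (a["p"] < criteria.max_p_study_a)
        & (b["fdr"] < criteria.max_fdr_study_b)
        & (b["log2fc"] > 0)
    )
    if criteria.require_ratio_in_both:
        keep &= b["ratio"] > criteria.min_ratio

    out = a.loc[keep].join(b.loc[keep].drop(columns="id"), rsuffix="_b")
    return out.reset_index(drop=True)
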