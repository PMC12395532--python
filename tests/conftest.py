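import numpy as np
import pandas as pd
import pytest

from circdm import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """2 features x 2 samples with library sizes 100 and 200."""
    counts = pd.DataFrame(
        [[1, 2], [3, 4]], index=["f1", "f2"], columns=["s1", "s2"], dtype=float
    )
    lib = pd.Series([100.0, 200.0], index=["s1", "s2"])
    groups = pd.Series(["DM1", "CTRL"], index=["s1", "s2"])
    return ExpressionMatrix(counts, lib, groups)


def make_ct_rows(sample, group, target, cls, cts, treatment=None):
    rows = []
    for rep, ct in enumerate(np.atleast_1d(cts), start=1):
        row = {
            "sample": sample,
            "group": group,
            "target": target,
            "amplicon_class": cls,
            "replicate": rep,
            "ct": float(ct),
        }
        if treatment is not None:
            row["treatment"] = treatment
        rows.append(row)
    return rows


@pytest.fixture
def ct_builder():
    return make_ct_rows
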