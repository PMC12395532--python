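"""qPCR delta-Ct analytics and the Mann-Whitney comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from circdm import (
    QpcrTarget,
    SimQpcrConfig,
    circ_lin_ratio,
    gen_ct_table,
    mann_whitney_u,
    relative_expression,
    rnase_r_resistance,
)
from circdm.qpcr import group_comparison


def frame(rows):
    return pd.DataFrame(rows)


class TestRelativeExpression:
    def test_reference_mean_cancels(self, ct_builder):
        rows = (
            ct_builder("s1", "DM1", "T", "circular", 20.0)
            + ct_builder("s1", "DM1", "UBC", "reference", 18.0)
            + ct_builder("s1", "DM1", "RPL23", "reference", 22.0)
        )
        per_sample, _ = relative_expression(frame(rows))
        assert per_sample["normalized"].iloc[0] == pytest.approx(0.0)

    def test_one_cycle_shift_gives_log2fc_one(self, ct_builder):
        rows = []
        for s, g, ct in [("c1", "DM1", 19.0), ("n1", "CTRL", 20.0)]:
            rows += ct_builder(s, g, "T", "circular", ct)
            rows += ct_builder(s, g, "UBC", "reference", 18.0)
            rows += ct_builder(s, g, "RPL23", "reference", 22.0)
        _, per_group = relative_expression(frame(rows))
        assert per_group["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_invariant_to_per_sample_ct_shift(self, ct_builder):
        rows = []
        for s, g, shift in [("a", "DM1", 0.0), ("b", "CTRL", 2.5)]:
            rows += ct_builder(s, g, "T", "circular", 21.0 + shift)
            rows += ct_builder(s, g, "UBC", "reference", 19.0 + shift)
            rows += ct_builder(s, g, "RPL23", "reference", 21.0 + shift)
        per_sample, _ = relative_expression(frame(rows))
        assert per_sample["normalized"].nunique() == 1

    def test_missing_reference_excludes_sample(self, ct_builder):
        rows = (
            ct_builder("s1", "DM1", "T", "circular", 20.0)
            + ct_builder("s1", "DM1", "UBC", "reference", 18.0)
        )
        with pytest.warns(UserWarning, match="reference"):
            per_sample, _ = relative_expression(frame(rows))
        assert len(per_sample) == 0

    def test_simulated_effect_recovery(self):
        """True circular effect +2 cycles is recovered by the group log2FC."""
        ests = []
        for seed in range(30):
            cfg = SimQpcrConfig(
                n_case=8,
                n_control=8,
                targets=(QpcrTarget("T", circ_effect=2.0),),
                noise_sd=0.2,
                seed=seed,
            )
            ct, _, _ = gen_ct_table(cfg)
            _, per_group = relative_expression(ct)
            circ = per_group[per_group["amplicon_class"] == "circular"]
            ests.append(circ["log2fc"].iloc[0])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 2.0) < 3 * se


class TestCircLinRatio:
    def test_equal_cts_give_zero(self, ct_builder):
        rows = ct_builder("s", "DM1", "T", "circular", 22.0) + ct_builder(
            "s", "DM1", "T", "linear", 22.0
        )
        assert circ_lin_ratio(frame(rows))["log2_circ_lin"].iloc[0] == 0.0

    def test_delta_ct_arithmetic_and_sign_flag(self, ct_builder):
        rows = ct_builder("s", "DM1", "T", "circular", 20.0) + ct_builder(
            "s", "DM1", "T", "linear", 25.0
        )
        assert circ_lin_ratio(frame(rows))["log2_circ_lin"].iloc[0] == 5.0
        assert (
            circ_lin_ratio(frame(rows), literal_sign=True)["log2_circ_lin"].iloc[0]
            == -5.0
        )

    def test_group_difference_hand_ddct(self, ct_builder):
        """Circular Ct one cycle lower in cases, linear unchanged -> diff +1."""
        rows = []
        for s, g, circ_ct in [("c", "DM1", 19.0), ("n", "CTRL", 20.0)]:
            rows += ct_builder(s, g, "T", "circular", circ_ct)
            rows += ct_builder(s, g, "T", "linear", 24.0)
        ratios = circ_lin_ratio(frame(rows))
        by_group = ratios.set_index("group")["log2_circ_lin"]
        assert by_group["DM1"] - by_group["CTRL"] == pytest.approx(1.0)

    def test_reference_free(self, ct_builder):
        """Reference-gene rows do not enter the ratio at all."""
        rows = (
            ct_builder("s", "DM1", "T", "circular", 20.0)
            + ct_builder("s", "DM1", "T", "linear", 25.0)
            + ct_builder("s", "DM1", "UBC", "reference", 99.0)
        )
        assert circ_lin_ratio(frame(rows))["log2_circ_lin"].iloc[0] == 5.0

    def test_unpaired_sample_excluded(self, ct_builder):
        rows = ct_builder("s", "DM1", "T", "circular", 20.0)
        assert len(circ_lin_ratio(frame(rows))) == 0


class TestRnaseR:
    def test_unchanged_and_degraded(self, ct_builder):
        rows = (
            ct_builder("s", "DM1", "C", "circular", 20.0, treatment="-")
            + ct_builder("s", "DM1", "C", "circular", 20.0, treatment="+")
            + ct_builder("s", "DM1", "L", "linear", 20.0, treatment="-")
            + ct_builder("s", "DM1", "L", "linear", 23.0, treatment="+")
        )
        per_sample, per_target = rnase_r_resistance(frame(rows))
        vals = per_target.set_index("target")["log2_retained"]
        assert vals["C"] == 0.0
        assert vals["L"] == -3.0
        assert per_target.set_index("target")["resistant"].to_dict() == {
            "C": True,
            "L": False,
        }

    def test_simulated_panel_classified(self, ct_builder):
        """20 targets: circular shift 0 +/- 0.2, linear +3 +/- 0.2 cycles."""
        rng = np.random.default_rng(7)
        rows = []
        truth = {}
        for i in range(20):
            circ = i % 2 == 0
            name = f"T{i}"
            truth[name] = circ
            shift = rng.normal(0.0, 0.2) if circ else rng.normal(3.0, 0.2)
            cls = "circular" if circ else "linear"
            rows += ct_builder("s", "DM1", name, cls, 22.0, treatment="-")
            rows += ct_builder("s", "DM1", name, cls, 22.0 + shift, treatment="+")
        _, per_target = rnase_r_resistance(frame(rows))
        calls = per_target.set_index("target")["resistant"].to_dict()
        assert calls == truth

    def test_unpaired_records_warn(self, ct_builder):
        rows = ct_builder("s", "DM1", "C", "circular", 20.0, treatment="-")
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning, match="unpaired"):
                rnase_r_resistance(frame(rows))


class TestMannWhitney:
    def test_no_overlap_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_midrank(self):
        x = [1.0, 2.0, 5.0]
        u, _ = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2

    def test_exact_matches_brute_force_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 6).astype(float)  # ties on purpose
        y = rng.integers(0, 5, 6).astype(float)
        u_obs, p_obs = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        n1 = len(x)
        mu = n1 * len(y) / 2
        devs = []
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        for idx in itertools.combinations(range(len(pooled)), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            devs.append(abs(u - mu))
        devs = np.asarray(devs)
        p_brute = np.mean(devs >= abs(u_obs - mu) - 1e-12)
        assert p_obs == pytest.approx(p_brute)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=8)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert u1 == u2
        assert p1 == pytest.approx(p2)

    def test_all_identical_values(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        from scipy.stats import mannwhitneyu

        u, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_group_comparison_runs_per_target():
    cfg = SimQpcrConfig(
        n_case=8,
        n_control=8,
        targets=(QpcrTarget("A", circ_effect=2.0), QpcrTarget("B")),
        seed=2,
    )
    ct, _, _ = gen_ct_table(cfg)
    ratios = circ_lin_ratio(ct)
    out = group_comparison(ratios, fdr_column=True)
    assert set(out["target"]) == {"A", "B"}
    assert (out["fdr_bh"] >= out["p"] - 1e-12).all()
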