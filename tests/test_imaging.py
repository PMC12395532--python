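"""Nuclei/foci segmentation, association and measurement."""

import numpy as np
import pandas as pd
import pytest

from circdm import (
    FOCI_THRESHOLD,
    FociSegmenter,
    SimImageConfig,
    ThresholdParams,
    associate_by_overlap,
    foci_histogram,
    gen_foci_images,
    local_mean_threshold,
    mbnl1_positive_foci,
    mbnl1_union_mask,
    measure,
    refine_mask,
    watershed_label,
)
from skimage.measure import label as cc_label


def disc(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestLocalMeanThreshold:
    def test_constant_image_empty(self):
        img = np.full((20, 20), 0.4)
        assert not local_mean_threshold(img, ThresholdParams(3, 3, 0.01)).any()

    def test_single_bright_pixel_hand_example(self):
        """5x5 zeros with centre 1.0, w=h=1, offset 0.02: centre only.

        The centre's 3x3 mean is 1/9 ~ 0.111, and 1.0 > 0.131; every other
        pixel's value (0) cannot exceed its own local mean + 0.02.
        """
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        mask = local_mean_threshold(img, ThresholdParams(1, 1, 0.02))
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        np.testing.assert_array_equal(mask, expected)

    def test_documented_foci_preset(self):
        assert (FOCI_THRESHOLD.w, FOCI_THRESHOLD.h, FOCI_THRESHOLD.offset) == (4, 4, 0.02)
        img = np.full((30, 30), 0.05)
        img[disc(img.shape, (15, 15), 2)] = 0.9
        mask = local_mean_threshold(img, FOCI_THRESHOLD)
        assert mask[15, 15]

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            local_mean_threshold(np.full((10, 10), 2.0), ThresholdParams(1, 1, 0.0))

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            local_mean_threshold(np.zeros((10, 10)), ThresholdParams(20, 20, 0.0))


class TestRefineMask:
    def test_interior_disc_retained_border_disc_removed(self):
        shape = (60, 60)
        mask = disc(shape, (30, 30), 10) | disc(shape, (0, 40), 10)
        out = refine_mask(mask, "nucleus")
        assert out[30, 30]
        assert not out[0:5, 35:45].any()

    def test_hole_filled(self):
        shape = (40, 40)
        full = disc(shape, (20, 20), 10)
        holed = full.copy()
        holed[20, 20] = False
        out = refine_mask(holed, "nucleus")
        np.testing.assert_array_equal(out, refine_mask(full, "nucleus"))
        assert out[20, 20]  # the hole itself is restored

    def test_focus_min_area_filter(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5] = True  # single pixel: removed
        mask |= disc(mask.shape, (14, 14), 2)  # 13 px: kept
        out = refine_mask(mask, "focus", opening_radius=0, min_area=4)
        assert not out[5, 5]
        assert out[14, 14]

    def test_empty_mask_passthrough(self):
        out = refine_mask(np.zeros((10, 10), dtype=bool), "nucleus")
        assert not out.any()


class TestWatershed:
    def test_separate_discs_match_connected_components(self):
        shape = (60, 60)
        mask = disc(shape, (15, 15), 8) | disc(shape, (45, 45), 8)
        labels = watershed_label(mask, min_seed_distance=6)
        cc = cc_label(mask)
        assert labels.max() == 2
        # identical partition up to label permutation
        for lab in (1, 2):
            vals = np.unique(cc[labels == lab])
            assert len(vals) == 1

    def test_touching_discs_split_at_neck(self):
        shape = (40, 70)
        mask = disc(shape, (20, 25), 10) | disc(shape, (20, 40), 10)
        labels = watershed_label(mask, min_seed_distance=8)
        assert labels.max() == 2
        assert labels[20, 25] != labels[20, 40]

    def test_empty_mask(self):
        labels = watershed_label(np.zeros((10, 10), dtype=bool))
        assert labels.shape == (10, 10)
        assert labels.max() == 0

    def test_labels_contiguous(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(50, 50)) < 0.1
        labels = watershed_label(refine_mask(mask, "focus", min_area=1), 2)
        present = np.unique(labels)
        assert list(present) == list(range(labels.max() + 1))


class TestAssociation:
    def test_full_containment_majority_and_orphan(self):
        shape = (40, 40)
        nuclei = np.zeros(shape, dtype=int)
        nuclei[disc(shape, (10, 10), 8)] = 3
        foci = np.zeros(shape, dtype=int)
        foci[disc(shape, (10, 10), 2)] = 1  # inside nucleus 3
        foci[disc(shape, (35, 35), 2)] = 2  # outside all nuclei
        out = associate_by_overlap(nuclei, foci)
        assert out == {1: 3, 2: 0}

    def test_split_focus_assigned_by_pixel_majority(self):
        nuclei = np.zeros((10, 10), dtype=int)
        nuclei[:, :6] = 1
        nuclei[:, 6:] = 2
        foci = np.zeros((10, 10), dtype=int)
        foci[4, 3:8] = 1  # 3 px in nucleus 1, 2 px in nucleus 2
        assert associate_by_overlap(nuclei, foci)[1] == 1

    def test_tie_breaks_to_lower_label(self):
        nuclei = np.zeros((10, 10), dtype=int)
        nuclei[:, :5] = 2
        nuclei[:, 5:] = 1
        foci = np.zeros((10, 10), dtype=int)
        foci[4, 3:7] = 1  # 2 px in each nucleus
        assert associate_by_overlap(nuclei, foci)[1] == 1

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            associate_by_overlap(np.zeros((5, 5), int), np.zeros((6, 6), int))


class TestMeasure:
    def test_area_fraction_and_intensity(self):
        shape = (20, 20)
        nuclei = np.zeros(shape, dtype=int)
        nuclei[:10, :10] = 1  # 100 px nucleus
        foci = np.zeros(shape, dtype=int)
        foci[2:4, 2:7] = 1  # 10 px focus
        channel = np.zeros(shape)
        channel[foci == 1] = 0.8
        nuc, foc = measure(nuclei, foci, channel)
        assert nuc.loc[0, "pct_area_foci"] == pytest.approx(10.0)
        assert nuc.loc[0, "foci_count"] == 1
        assert foc.loc[0, "mean_intensity"] == pytest.approx(0.8)
        assert foc.loc[0, "area"] == 10

    def test_area_conservation_invariant(self):
        cfg = SimImageConfig(seed=2)
        fields, _ = gen_foci_images(cfg)
        q = FociSegmenter().quantify(fields[0].channels["nuclei"], fields[0].channels["foci"])
        lhs = (q.nucleus_records["pct_area_foci"] * q.nucleus_records["area"] / 100).sum()
        rhs = q.focus_records.loc[q.focus_records["nucleus"] > 0, "area"].sum()
        assert lhs == pytest.approx(rhs)


class TestHistogram:
    def test_small_example(self):
        h = foci_histogram([0, 0, 1, 2], k_max=3)
        assert h.set_index("bin")["percent"].to_dict() == {
            "0": 50.0, "1": 25.0, "2": 25.0, ">=3": 0.0,
        }
        assert h["percent"].sum() == pytest.approx(100.0)

    def test_all_zero(self):
        h = foci_histogram([0] * 5)
        assert h.loc[h["bin"] == "0", "percent"].iloc[0] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            foci_histogram([])

    def test_matches_ground_truth_distribution(self):
        cfg = SimImageConfig(
            n_nuclei_per_image=25,
            foci_count_distribution={"si-NTC": (2.0, 0.5)},
            seed=9,
        )
        _, truth = gen_foci_images(cfg)
        counts = truth["nuclei"]["foci_count"].to_numpy()
        h = foci_histogram(counts, k_max=4)
        for k in range(4):
            assert h.loc[h["bin"] == str(k), "percent"].iloc[0] == pytest.approx(
                100.0 * np.mean(counts == k)
            )


class TestMbnl1:
    def test_union_superset_and_constant_empty(self):
        rng = np.random.default_rng(5)
        img = np.clip(rng.uniform(0, 0.3, (40, 40)), 0, 1)
        p1, p2 = ThresholdParams(4, 4, 0.05), ThresholdParams(2, 2, 0.1)
        union = mbnl1_union_mask(img, p1, p2)
        assert (union | local_mean_threshold(img, p1)).sum() == union.sum()
        assert (union | local_mean_threshold(img, p2)).sum() == union.sum()
        assert not mbnl1_union_mask(np.full((20, 20), 0.5), p1, p2).any()

    def test_empty_mask_zero_counts_full_mask_total_counts(self):
        shape = (40, 40)
        nuclei = np.zeros(shape, dtype=int)
        nuclei[disc(shape, (20, 20), 15)] = 1
        foci = np.zeros(shape, dtype=int)
        foci[disc(shape, (15, 20), 2)] = 1
        foci[disc(shape, (25, 20), 2)] = 2
        empty = mbnl1_positive_foci(nuclei, foci, np.zeros(shape, dtype=bool))
        assert empty["mbnl1_foci_count"].sum() == 0
        full = mbnl1_positive_foci(nuclei, foci, foci > 0)
        assert full.loc[0, "mbnl1_foci_count"] == 2

    def test_colocated_fraction_recovered(self):
        cfg = SimImageConfig(
            n_nuclei_per_image=15,
            foci_count_distribution={"si-NTC": (3.0, 0.0)},
            mbnl1_fraction=0.5,
            seed=3,
        )
        fields, truth = gen_foci_images(cfg)
        fov = fields[0]
        q = FociSegmenter().quantify(
            fov.channels["nuclei"], fov.channels["foci"], fov.channels["mbnl1"]
        )
        got = int(q.mbnl1_records["mbnl1_foci_count"].sum())
        expected = int(truth["foci"]["mbnl1"].sum())
        assert abs(got - expected) <= 2


class TestFullRecovery:
    def test_counts_match_ground_truth(self):
        """Generator images with well-separated bright foci are recovered
        nucleus-for-nucleus by the documented threshold presets."""
        cfg = SimImageConfig(
            n_nuclei_per_image=20,
            foci_count_distribution={"si-NTC": (3.0, 0.0)},
            seed=11,
        )
        fields, truth = gen_foci_images(cfg)
        fov = fields[0]
        q = FociSegmenter().quantify(fov.channels["nuclei"], fov.channels["foci"])
        assert len(q.focus_records) == 60
        recs = q.nucleus_records.set_index("nucleus")
        matched = 0
        for _, row in truth["nuclei"].iterrows():
            lab = q.nuclei_labels[int(row["row"]), int(row["col"])]
            assert lab > 0
            matched += recs.loc[lab, "foci_count"] == row["foci_count"]
        assert matched == 20

    def test_segmentation_deterministic(self):
        cfg = SimImageConfig(seed=4)
        fields, _ = gen_foci_images(cfg)
        fov = fields[0]
        q1 = FociSegmenter().quantify(fov.channels["nuclei"], fov.channels["foci"])
        q2 = FociSegmenter().quantify(fov.channels["nuclei"], fov.channels["foci"])
        np.testing.assert_array_equal(q1.nuclei_labels, q2.nuclei_labels)
        np.testing.assert_array_equal(q1.foci_labels, q2.foci_labels)
        pd.testing.assert_frame_equal(q1.nucleus_records, q2.nucleus_records)

    def test_intensity_bounds(self):
        cfg = SimImageConfig(seed=6)
        fields, _ = gen_foci_images(cfg)
        fov = fields[0]
        q = FociSegmenter().quantify(fov.channels["nuclei"], fov.channels["foci"])
        lo, hi = fov.channels["foci"].min(), fov.channels["foci"].max()
        assert q.focus_records["mean_intensity"].between(lo, hi).all()
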