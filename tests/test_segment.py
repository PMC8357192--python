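"""Depletion segmentation, ROC threshold selection, group statistics."""

import numpy as np
import pytest
from scipy import stats

import flimcart as fc
from conftest import pooled_ratio_values


class TestRocThreshold:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        healthy = rng.uniform(0.30, 0.35, 500)
        depleted = rng.uniform(0.18, 0.22, 500)
        values = np.concatenate([healthy, depleted])
        labels = np.concatenate([np.zeros(500, bool), np.ones(500, bool)])
        roc = fc.roc_threshold(values, labels)
        assert roc.auc == 1.0
        assert 0.22 < roc.chosen_threshold < 0.30

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(0.32, 0.02, 1250), rng.normal(0.20, 0.02, 1250)]
        )
        labels = np.concatenate([np.zeros(1250, bool), np.ones(1250, bool)])
        permuted = rng.permutation(labels)
        roc = fc.roc_threshold(values, permuted)
        assert abs(roc.auc - 0.5) < 0.05

    def test_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0.25, 0.05, 400)
        labels = values + rng.normal(0, 0.03, 400) < 0.25
        roc = fc.roc_threshold(values, labels)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_agrees_with_sklearn(self):
        """Independent cross-check of AUC against scikit-learn."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        values = np.concatenate(
            [rng.normal(0.32, 0.04, 300), rng.normal(0.22, 0.04, 300)]
        )
        labels = np.concatenate([np.zeros(300, bool), np.ones(300, bool)])
        ours = fc.roc_threshold(values, labels).auc
        theirs = roc_auc_score(labels, -values)  # depleted scores low
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_phantom_pair_threshold_brackets_operating_point(
        self, control_run, high_run
    ):
        values, labels = pooled_ratio_values([control_run, high_run])
        roc = fc.roc_threshold(values, labels)
        assert 0.21 <= roc.chosen_threshold <= 0.29
        assert roc.auc > 0.99

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fc.roc_threshold(np.arange(10.0), np.ones(10, bool))


class TestSegmentDepletion:
    def test_noiseless_presets_recover_truth_thickness(
        self, noiseless_low_run, noiseless_high_run, noiseless_control_run
    ):
        for run, expect in (
            (noiseless_low_run, 0.3),
            (noiseless_high_run, 0.7),
            (noiseless_control_run, 0.0),
        ):
            _, truth, maps = run
            seg = fc.segment_depletion(maps, fc.detect_surface(maps))
            assert seg.mean_thickness == pytest.approx(expect, abs=0.1)

    def test_noiseless_mask_exact_for_any_threshold_in_gap(
        self, noiseless_high_run
    ):
        _, truth, maps = noiseless_high_run
        surf = fc.detect_surface(maps)
        for thr in (0.22, 0.25, 0.30):
            seg = fc.segment_depletion(maps, surf, threshold=thr)
            assert np.array_equal(seg.depleted_mask, truth.depleted_mask)

    def test_zero_threshold_gives_zero_thickness(self, noiseless_high_run):
        _, _, maps = noiseless_high_run
        seg = fc.segment_depletion(maps, fc.detect_surface(maps), threshold=0.0)
        assert seg.mean_thickness == 0.0

    def test_thickness_monotone_in_threshold(self, high_run):
        _, _, maps = high_run
        surf = fc.detect_surface(maps)
        thick = [
            fc.segment_depletion(maps, surf, threshold=t).mean_thickness
            for t in (0.05, 0.15, 0.25, 0.35, 0.60)
        ]
        assert np.all(np.diff(thick) >= 0)

    def test_low_below_high(self, noiseless_low_run, noiseless_high_run):
        segs = []
        for _, _, maps in (noiseless_low_run, noiseless_high_run):
            segs.append(fc.segment_depletion(maps, fc.detect_surface(maps)))
        assert segs[0].mean_thickness < segs[1].mean_thickness

    def test_mask_inside_valid_and_thickness_consistent(self, high_run):
        _, _, maps = high_run
        seg = fc.segment_depletion(maps, fc.detect_surface(maps))
        assert np.all(seg.depleted_mask <= maps.valid)
        counts = seg.depleted_mask.sum(axis=0)
        assert np.allclose(seg.thickness_per_column, counts * maps.pixel_pitch)


class TestRoiSummary:
    def test_single_pixel_roi(self, control_run):
        _, truth, maps = control_run
        r, c = np.argwhere(maps.valid)[0]
        roi = np.zeros_like(maps.valid)
        roi[r, c] = True
        s = fc.roi_summary(maps, roi)
        assert s["n"] == 1
        assert np.allclose(s["mean_lt"], maps.lt[r, c])

    def test_depleted_roi_recovers_preset_lifetimes(self, high_run):
        _, truth, maps = high_run
        s = fc.roi_summary(maps, truth.depleted_mask)
        assert s["mean_lt"][1] == pytest.approx(6.34 - 0.44, abs=0.1)
        assert s["mean_lt"][2] == pytest.approx(5.22 - 0.75, abs=0.1)

    def test_empty_roi_rejected(self, control_run):
        _, _, maps = control_run
        with pytest.raises(ValueError, match="ROI"):
            fc.roi_summary(maps, np.zeros_like(maps.valid))


class TestCompareGroups:
    def test_equal_means_give_f_near_zero(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(5, 1, 20), rng.normal(5, 1, 20)
        cmp_ = fc.compare_groups({"a": a, "b": b})
        assert cmp_.p_value > 0.05

    def test_textbook_two_group_anova(self):
        """{1,2,3} vs {11,12,13}: SSB=150, MSW=1 → F=150 (= t² with
        t=12.247); cross-checked against scipy."""
        g1, g2 = np.array([1.0, 2, 3]), np.array([11.0, 12, 13])
        cmp_ = fc.compare_groups({"g1": g1, "g2": g2})
        assert cmp_.f_statistic == pytest.approx(150.0, rel=1e-12)
        f_scipy, p_scipy = stats.f_oneway(g1, g2)
        assert cmp_.f_statistic == pytest.approx(f_scipy)
        assert cmp_.p_value == pytest.approx(p_scipy)
        assert cmp_.p_value < 0.01
        t = (g2.mean() - g1.mean()) / np.sqrt(1.0 * (2 / 3))
        assert cmp_.f_statistic == pytest.approx(t**2)

    def test_tukey_at_least_as_conservative_as_pooled_pairwise_tests(self):
        """The studentized-range adjustment cannot make a pairwise
        comparison more significant than the unadjusted pooled-variance
        (Fisher LSD) test on the same degrees of freedom."""
        groups = {
            "a": np.array([1.0, 2, 3, 2]),
            "b": np.array([2.0, 3, 4, 3]),
            "c": np.array([7.0, 8, 9, 8]),
        }
        cmp_ = fc.compare_groups(groups)
        g = list(groups.values())
        nobs = [len(x) for x in g]
        df = sum(nobs) - len(g)
        msw = sum(((x - x.mean()) ** 2).sum() for x in g) / df
        for i in range(3):
            for j in range(i + 1, 3):
                se = np.sqrt(msw * (1 / nobs[i] + 1 / nobs[j]))
                t = abs(g[i].mean() - g[j].mean()) / se
                p_lsd = 2 * stats.t.sf(t, df)
                assert cmp_.tukey_p[i, j] >= p_lsd - 1e-12

    def test_mean_differences_antisymmetric(self):
        cmp_ = fc.compare_groups(
            {"a": [1.0, 2], "b": [3.0, 4], "c": [5.0, 7]}
        )
        assert np.allclose(cmp_.mean_differences, -cmp_.mean_differences.T)

    def test_degenerate_identical_samples_flagged(self):
        cmp_ = fc.compare_groups({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert cmp_.degenerate
        assert np.isnan(cmp_.f_statistic)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fc.compare_groups({"a": [1.0], "b": [2.0, 3.0]})

    def test_phantom_groups_ordered_and_separable(
        self, noiseless_control_run, noiseless_low_run, noiseless_high_run
    ):
        """Depletion thickness across simulated treatment groups: high is
        separable from control and low."""
        rng_groups = {}
        for name, run in (
            ("control", noiseless_control_run),
            ("low", noiseless_low_run),
            ("high", noiseless_high_run),
        ):
            _, _, maps = run
            seg = fc.segment_depletion(maps, fc.detect_surface(maps))
            # per-column thicknesses split into pseudo-samples of 10 columns
            t = seg.thickness_per_column
            rng_groups[name] = [
                np.nanmean(t[i : i + 10]) for i in range(0, len(t), 10)
            ]
        cmp_ = fc.compare_groups(rng_groups)
        assert cmp_.means[0] < cmp_.means[1] < cmp_.means[2]
        assert cmp_.p_value < 0.01
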