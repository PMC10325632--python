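"""Entropy/MI estimators, connectivity assembly, and edgewise group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from factorlens import (ConnectivityMatrix, Parcellation, RoiTimeSeriesSet,
                        apply_threshold, build_connectivity,
                        edgewise_group_comparison, extract_roi_timeseries,
                        fdr_correct, joint_entropy, marginal_entropy,
                        mutual_information, phantom_parcellation,
                        subnetwork_summary)

series_strategy = hnp.arrays(
    dtype=float, shape=st.integers(8, 60),
    elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False))


class TestEntropy:
    def test_two_level_alternating_series_is_one_bit(self):
        s = np.tile([0.0, 1.0], 8)
        assert marginal_entropy(s, bins=2) == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_is_zero_bits(self):
        assert marginal_entropy(np.full(10, 3.7), bins=16) == 0.0

    def test_four_equifrequent_levels_give_two_bits(self):
        s = np.tile([0.0, 1.0, 2.0, 3.0], 5)
        assert marginal_entropy(s, bins=4) == pytest.approx(2.0, abs=1e-12)

    def test_joint_of_identical_series_equals_marginal(self, rng):
        s = rng.normal(size=100)
        assert joint_entropy(s, s, bins=8) == pytest.approx(
            marginal_entropy(s, bins=8), abs=1e-12)

    def test_joint_uniform_over_four_cells_is_two_bits(self):
        s1 = np.tile([0.0, 0.0, 1.0, 1.0], 6)
        s2 = np.tile([0.0, 1.0, 0.0, 1.0], 6)
        assert joint_entropy(s1, s2, bins=2) == pytest.approx(2.0, abs=1e-12)

    def test_joint_symmetric_in_arguments(self, rng):
        s1, s2 = rng.normal(size=(2, 80))
        assert joint_entropy(s1, s2, 8) == pytest.approx(joint_entropy(s2, s1, 8))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            joint_entropy(np.zeros(5), np.zeros(6), 4)

    @given(s=series_strategy)
    def test_entropy_bounded_by_log_bins(self, s):
        h = marginal_entropy(s, bins=8)
        assert 0.0 <= h <= np.log2(8) + 1e-12


class TestMutualInformation:
    def test_self_information_equals_marginal_entropy(self, rng):
        s = rng.normal(size=200)
        assert mutual_information(s, s, 8) == pytest.approx(
            marginal_entropy(s, 8), abs=1e-12)

    def test_sign_flip_preserves_mutual_information(self, rng):
        # a strictly monotone transform with matched binning keeps MI = H
        s = rng.normal(size=500)
        assert mutual_information(s, -s, 16) == pytest.approx(
            marginal_entropy(s, 16), abs=1e-12)

    def test_independent_uniform_series_near_zero(self):
        rng = np.random.default_rng(99)
        s1, s2 = rng.uniform(size=(2, 100_000))
        assert mutual_information(s1, s2, bins=8) < 0.01

    @given(s=series_strategy, t=series_strategy)
    def test_symmetry_and_nonnegativity_on_fuzzed_inputs(self, s, t):
        n = min(len(s), len(t))
        s, t = s[:n], t[:n]
        mi = mutual_information(s, t, bins=6)
        assert mi >= 0.0
        assert mi == pytest.approx(mutual_information(t, s, bins=6), abs=1e-12)
        assert mi <= min(marginal_entropy(s, 6), marginal_entropy(t, 6)) + 1e-12


class TestRoiExtraction:
    def _parcellation(self, labels):
        nets = {r: "DMN" for r in range(1, labels.max() + 1)}
        return Parcellation(labels=labels, subnet_map=nets)

    def test_constant_volume_gives_constant_series(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        vol = np.full((2, 2, 2, 5), 3.0)
        ts = extract_roi_timeseries(vol, self._parcellation(labels))
        np.testing.assert_allclose(ts.data, 3.0)

    def test_single_voxel_roi_equals_voxel_trace(self, rng):
        labels = np.ones((2, 2, 1), dtype=np.int32)
        labels[1, 1, 0] = 2
        vol = rng.normal(size=(2, 2, 1, 6))
        ts = extract_roi_timeseries(vol, self._parcellation(labels))
        np.testing.assert_allclose(ts.data[1], vol[1, 1, 0])

    def test_two_voxel_roi_averages_traces(self):
        labels = np.zeros((2, 1, 1), dtype=np.int32)
        labels[:, 0, 0] = 1
        vol = np.zeros((2, 1, 1, 2))
        vol[0, 0, 0] = [1.0, 3.0]
        vol[1, 0, 0] = [3.0, 5.0]
        ts = extract_roi_timeseries(vol, self._parcellation(labels))
        np.testing.assert_allclose(ts.data[0], [2.0, 4.0])

    def test_shape_mismatch_rejected(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        with pytest.raises(ValueError, match="extents"):
            extract_roi_timeseries(np.zeros((3, 2, 2, 4)), self._parcellation(labels))

    def test_empty_roi_rejected_by_name(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        labels[0, 0, 0] = 3  # label 2 has no voxels
        with pytest.raises(ValueError, match="2"):
            Parcellation(labels=labels, subnet_map={1: "DMN", 2: "VN", 3: "AN"})


class TestConnectivity:
    def test_two_rois_single_mirrored_entry(self, rng):
        ts = RoiTimeSeriesSet(data=rng.normal(size=(2, 60)))
        cm = build_connectivity(ts, bins=8)
        assert cm.values.shape == (2, 2)
        assert cm.values[0, 1] == cm.values[1, 0] > 0 or cm.values[0, 1] == 0

    def test_duplicate_rows_give_marginal_entropy_off_diagonal(self, rng):
        row = rng.normal(size=80)
        ts = RoiTimeSeriesSet(data=np.vstack([row, row, rng.normal(size=80)]))
        cm = build_connectivity(ts, bins=8)
        assert cm.values[0, 1] == pytest.approx(marginal_entropy(row, 8), abs=1e-12)

    def test_symmetric_nonnegative_with_entropy_diagonal(self, rng):
        ts = RoiTimeSeriesSet(data=rng.normal(size=(6, 100)))
        cm = build_connectivity(ts, bins=8)
        np.testing.assert_allclose(cm.values, cm.values.T)
        assert np.all(cm.off_diagonal() >= 0)
        for r in range(6):
            assert cm.values[r, r] == pytest.approx(
                marginal_entropy(ts.data[r], 8), abs=1e-12)

    def test_phantom_116_roi_matrix_is_116_square(self, rng):
        parc = phantom_parcellation((12, 12, 12), n_rois=116, seed=3)
        vol = rng.normal(size=(12, 12, 12, 40))
        ts = extract_roi_timeseries(vol, parc)
        cm = build_connectivity(ts, bins=8)
        assert cm.values.shape == (116, 116)
        summary = subnetwork_summary(cm, parc)
        assert summary.shape == (8, 8)

    def test_threshold_conventions(self, rng):
        ts = RoiTimeSeriesSet(data=rng.normal(size=(4, 80)))
        cm = build_connectivity(ts, bins=8)
        off = cm.off_diagonal()
        complete = apply_threshold(cm, off.min() - 1e-9)
        assert complete.sum() == 4 * 3  # all ordered pairs, no self-loops
        assert not apply_threshold(cm, off.max()).any() or (
            apply_threshold(cm, off.max()).sum()
            == 2 * (off == off.max()).sum() - 2 * (off == off.max()).sum())
        assert apply_threshold(cm, off.max() + 1e-9).sum() == 0
        # boundary: an edge exactly at the threshold is absent
        boundary = apply_threshold(cm, off.max())
        assert not boundary[np.isclose(cm.values, off.max())].any()


class TestFdr:
    def test_strong_uniform_signal_all_pass(self):
        q, mask = fdr_correct(np.full(10, 0.001), q=0.05)
        assert mask.all()

    def test_hand_computed_bh_step_up(self):
        p = np.array([0.01, 0.02, 0.04, 0.8])
        # BH adjusted: p*(m/rank) with monotonicity enforcement
        expected_q = np.array([0.04, 0.04, 16 / 300, 0.8])
        q, mask = fdr_correct(p, q=0.05)
        np.testing.assert_allclose(q, expected_q, atol=1e-12)
        # 0.04 > 3/4 * 0.05, so the third hypothesis is NOT rejected
        assert mask.tolist() == [True, True, False, False]

    def test_adjusted_values_dominate_raw_pvalues(self, rng):
        p = rng.uniform(size=200)
        q, _ = fdr_correct(p)
        assert np.all(q >= p - 1e-15)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.1, 1.2])


def _matrices_from_edges(rng, n, R=6, shift=None):
    mats = []
    for _ in range(n):
        m = rng.normal(size=(R, R))
        m = np.abs(m + m.T) / 2
        if shift is not None:
            m[shift[0], shift[1]] += shift[2]
            m[shift[1], shift[0]] += shift[2]
        np.fill_diagonal(m, 1.0)
        mats.append(m)
    return mats


class TestGroupComparison:
    def test_identical_groups_yield_no_significant_edges(self, rng):
        group = _matrices_from_edges(rng, 6)
        result = edgewise_group_comparison(group, group)
        assert result.mask.sum() == 0
        assert np.all(result.qvalues >= result.pvalues - 1e-15)

    def test_no_covariates_matches_two_sample_t_test(self, rng):
        a = _matrices_from_edges(rng, 8)
        b = _matrices_from_edges(rng, 9)
        result = edgewise_group_comparison(a, b)
        iu = np.triu_indices(6, k=1)
        from scipy import stats
        for e in range(5):
            xa = [m[iu][e] for m in a]
            xb = [m[iu][e] for m in b]
            t, p = stats.ttest_ind(xa, xb, equal_var=True)
            assert result.pvalues[e] == pytest.approx(p, abs=1e-10)
            assert result.stat[e] == pytest.approx(t * t, rel=1e-10)

    def test_group_effect_matches_statsmodels_ancova(self, rng):
        import statsmodels.api as sm
        a = _matrices_from_edges(rng, 10)
        b = _matrices_from_edges(rng, 10)
        cov = pd.DataFrame({"age": rng.uniform(20, 40, 20)})
        result = edgewise_group_comparison(a, b, covariates=cov)
        iu = np.triu_indices(6, k=1)
        y = np.array([m[iu][3] for m in a + b])
        X = sm.add_constant(np.column_stack([
            np.r_[np.zeros(10), np.ones(10)], cov["age"]]))
        fit = sm.OLS(y, X).fit()
        assert result.pvalues[3] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_planted_shift_is_detected(self, rng):
        a = _matrices_from_edges(rng, 15)
        b = _matrices_from_edges(rng, 15, shift=(1, 4, 5.0))
        result = edgewise_group_comparison(a, b)
        sig = result.significance_matrix()
        assert sig[1, 4]

    def test_rank_deficient_covariates_rejected(self, rng):
        a = _matrices_from_edges(rng, 5)
        b = _matrices_from_edges(rng, 5)
        cov = pd.DataFrame({"c1": np.ones(10)})  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            edgewise_group_comparison(a, b, covariates=cov)

    def test_too_few_subjects_rejected(self, rng):
        a = _matrices_from_edges(rng, 1)
        b = _matrices_from_edges(rng, 5)
        with pytest.raises(ValueError, match="2 subjects"):
            edgewise_group_comparison(a, b)


class TestSubnetworkSummary:
    def test_single_subnetwork_collapses_to_total(self, rng):
        parc = phantom_parcellation((5, 5, 5), n_rois=4, seed=1)
        parc = Parcellation(labels=parc.labels,
                            subnet_map={r: "DMN" for r in range(1, 5)})
        a = _matrices_from_edges(rng, 5, R=4)
        b = _matrices_from_edges(rng, 5, R=4, shift=(0, 2, 6.0))
        result = edgewise_group_comparison(a, b)
        summary = subnetwork_summary(result, parc)
        assert summary.shape == (1, 1)
        assert summary.iloc[0, 0] == result.mask.sum()

    def test_significance_isolated_to_one_block(self, rng):
        parc = phantom_parcellation((6, 6, 6), n_rois=6, seed=2)
        nets = {1: "DMN", 2: "DMN", 3: "VN", 4: "VN", 5: "AN", 6: "AN"}
        parc = Parcellation(labels=parc.labels, subnet_map=nets)
        a = _matrices_from_edges(rng, 15, R=6)
        b = _matrices_from_edges(rng, 15, R=6, shift=(0, 1, 8.0))  # inside DMN
        result = edgewise_group_comparison(a, b)
        summary = subnetwork_summary(result, parc)
        assert summary.loc["DMN", "DMN"] >= 1
        off_dmn = summary.to_numpy().sum() - summary.loc["DMN", "DMN"]
        assert off_dmn == 0

    def test_mean_mi_summary_is_symmetric(self, rng):
        parc = phantom_parcellation((6, 6, 6), n_rois=10, seed=5)
        ts = RoiTimeSeriesSet(data=rng.normal(size=(10, 80)))
        cm = build_connectivity(ts, bins=8)
        summary = subnetwork_summary(cm, parc)
        np.testing.assert_allclose(summary.to_numpy(), summary.to_numpy().T)
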