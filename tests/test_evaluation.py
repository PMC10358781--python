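"""Alignment R^2, folds, paired tests, GNB decoding, lag and dimensionality
selection."""

import numpy as np
import pytest
from scipy import stats

from cilds.evaluation import (FoldSpec, PredictionReport, align_latents,
                              compare_likelihoods, gnb_cross_validate,
                              gnb_decode, gnb_fit, gnb_posteriors, make_folds,
                              paired_compare, r2_per_latent,
                              select_decoding_lag, select_dimensionality,
                              window_features)
from cilds.simulation import make_grating_schedule

from oracles import pearson_by_hand


class TestFolds:
    @pytest.mark.parametrize("n,k,sizes", [(10, 5, {2}), (7, 2, {3, 4})])
    def test_partition_sizes(self, n, k, sizes):
        spec = make_folds(n, k, seed=0)
        counts = np.bincount(spec.assignment, minlength=k)
        assert set(counts) == sizes
        assert counts.sum() == n

    def test_deterministic(self):
        assert np.array_equal(make_folds(9, 3, seed=5).assignment,
                              make_folds(9, 3, seed=5).assignment)

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            make_folds(3, 5)


class TestAlignment:
    def test_identity_when_equal(self):
        Z = np.random.default_rng(0).standard_normal((2, 200))
        res = align_latents(Z, Z)
        assert np.allclose(res.r2, 1.0)
        for W in res.W_per_half:
            assert np.allclose(W, np.eye(2), atol=1e-8)

    def test_invertible_remixing_recovered(self):
        """Z_est = M Z_true: alignment inverts M exactly, R^2 = 1."""
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((3, 300))
        M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        res = align_latents(M @ Z, Z)
        assert np.allclose(res.r2, 1.0, atol=1e-8)
        assert np.abs(res.Z_hat - Z).max() < 1e-6

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(2)
        Zt = rng.standard_normal((2, 200))
        Ze = rng.standard_normal((2, 200))
        res = align_latents(Ze, Zt)
        # first half fit: W solves Zt_half ~ W Ze_half
        W_ref = np.linalg.lstsq(Ze[:, :100].T, Zt[:, :100].T, rcond=None)[0].T
        assert np.abs(res.W_per_half[0] - W_ref).max() < 1e-8

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            align_latents(np.zeros((3, 4)), np.zeros((3, 4)))

    def test_r2_invariant_to_remixing_of_estimates(self):
        """Any invertible remixing of the estimated latents leaves the aligned
        R^2 unchanged (noiseless case, exact)."""
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((2, 400))
        E = Z + 0.0
        M = np.array([[2.0, 0.5], [-0.3, 1.5]])
        r_plain = align_latents(E, Z).r2
        r_mixed = align_latents(M @ E, Z).r2
        assert np.allclose(r_plain, r_mixed, atol=1e-8)


class TestR2:
    def test_reference_values(self):
        assert r2_per_latent([1, 2, 3], [1, 2, 3]) == 1.0
        assert r2_per_latent([1, 2, 3], [2, 2, 2]) == 0.0
        assert np.isclose(r2_per_latent([1, 2, 3], [1, 1, 3]), 0.5)

    def test_can_be_negative(self):
        assert r2_per_latent([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) < 0

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            r2_per_latent([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestPairedTests:
    def test_identical_reports_null(self):
        corr = np.random.default_rng(4).uniform(0, 1, (3, 6))
        a = PredictionReport(correlations=corr.copy())
        b = PredictionReport(correlations=corr.copy())
        res = paired_compare(a, b)
        assert np.allclose(res["t_per_neuron"], 0.0)
        assert np.allclose(res["p_per_neuron"], 1.0)

    def test_textbook_t_statistic(self):
        """Differences (1, 2, 3): t = 2 sqrt(3), two-tailed p with 2 df."""
        base = np.zeros((1, 3))
        a = PredictionReport(correlations=np.array([[1.0, 2.0, 3.0]]))
        b = PredictionReport(correlations=base)
        res = paired_compare(a, b)
        t = res["t_per_neuron"][0]
        assert np.isclose(t, 2.0 * np.sqrt(3.0))
        assert np.isclose(res["p_per_neuron"][0], 2 * stats.t.sf(t, df=2))

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(5)
        a = PredictionReport(correlations=rng.uniform(0, 1, (2, 8)))
        b = PredictionReport(correlations=rng.uniform(0, 1, (2, 8)))
        r1, r2 = paired_compare(a, b), paired_compare(b, a)
        assert np.allclose(r1["t_per_neuron"], -r2["t_per_neuron"])
        assert np.allclose(r1["p_per_neuron"], r2["p_per_neuron"])

    def test_pearson_hand_instance(self):
        assert np.isclose(pearson_by_hand([0, 1, 2], [0, 2, 2]),
                          np.sqrt(3.0) / 2.0)


class TestWindowFeatures:
    def test_counts_and_constant_latents(self):
        sched = make_grating_schedule(2, 3, repeats_per_class=2,
                                      duration_timepoints=5, seed=0)
        latents = np.ones((2, 3, 100))
        X, y = window_features(latents, sched, lag=0)
        assert X.shape == (2 * len(sched.onsets), 3)
        assert np.allclose(X, 1.0)
        assert len(y) == len(X)

    def test_single_point_windows_pick_samples(self):
        rng = np.random.default_rng(6)
        latents = rng.standard_normal((1, 2, 50))
        sched = make_grating_schedule(1, 2, repeats_per_class=2,
                                      duration_timepoints=1, seed=1)
        X, _ = window_features(latents, sched, lag=0)
        for i, onset in enumerate(sched.onsets):
            assert np.array_equal(X[i], latents[0, :, onset])

    def test_shifted_out_windows_dropped(self):
        latents = np.zeros((1, 1, 20))
        sched = make_grating_schedule(1, 1, repeats_per_class=3,
                                      duration_timepoints=5, seed=2)
        X, _ = window_features(latents, sched, lag=10)
        assert len(X) < 3 * 1


class TestGNB:
    def test_symmetric_boundary(self):
        X = np.concatenate([np.full(50, -10.0), np.full(50, 10.0)])[:, None]
        X = X + np.random.default_rng(7).standard_normal((100, 1))
        y = np.repeat([1, 2], 50)
        dec = gnb_fit(X, y)
        assert gnb_decode(dec, [[-0.5]])[0] == 1
        assert gnb_decode(dec, [[0.5]])[0] == 2

    def test_shared_diagonal_covariance(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 3))
        X[:, 1] = X[:, 0] * 0.9 + 0.1 * X[:, 1]  # correlated features
        y = rng.integers(1, 4, 200)
        dec = gnb_fit(X, y)
        assert dec.var_diag.shape == (3,)  # diagonal by construction

    def test_two_class_posterior_closed_form(self):
        """1-D classes at 0 and 2, unit variance, z = 0.5: the posterior of the
        nearer class is 1 / (1 + e^{-1})."""
        dec_params = gnb_fit(
            np.array([[0.0], [0.0], [2.0], [2.0]]), np.array([1, 1, 2, 2]))
        # force exact unit variance for the closed-form check
        dec_params.var_diag = np.array([1.0])
        post = gnb_posteriors(dec_params, [[0.5]])[0]
        assert np.isclose(post[0], 1.0 / (1.0 + np.exp(-1.0)))

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            gnb_fit(np.zeros((3, 1)), np.array([1, 1, 1]), classes=np.array([1, 2]))

    def test_tie_goes_to_lowest_class(self):
        dec = gnb_fit(np.array([[-1.0], [1.0]]), np.array([1, 2]))
        dec.var_diag = np.array([1.0])
        assert gnb_decode(dec, [[0.0]])[0] == 1

    def test_separable_classes_perfect(self):
        rng = np.random.default_rng(9)
        means = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 30.0]])
        y = np.repeat([1, 2, 3], 40)
        X = means[y - 1] + rng.standard_normal((120, 2))
        _, acc = gnb_decode(gnb_fit(X, y), X, y)
        assert acc == 1.0

    def test_chance_level_on_independent_features(self):
        rng = np.random.default_rng(10)
        K, n = 10, 4000
        X = rng.standard_normal((n, 3))
        y = rng.integers(1, K + 1, n)
        acc = gnb_cross_validate(X, y, k=5, seed=0)
        se = np.sqrt((1 / K) * (1 - 1 / K) / n)
        assert abs(acc - 1 / K) < 3 * se


class TestLagSelection:
    def _latents_with_shift(self, shift, seed=0):
        rng = np.random.default_rng(seed)
        sched = make_grating_schedule(2, 2, repeats_per_class=5,
                                      duration_timepoints=4, seed=1)
        means = rng.standard_normal((4, 2)) * 5
        latents = np.zeros((6, 2, 200))
        for tr in range(6):
            for onset, lab in zip(sched.onsets, sched.labels):
                lo, hi = onset + shift, onset + shift + 4
                latents[tr, :, lo:hi] += means[lab - 1][:, None]
        latents += 0.5 * rng.standard_normal(latents.shape)
        return latents, sched

    def test_constructed_shift_recovered(self):
        latents, sched = self._latents_with_shift(3)
        best, acc = select_decoding_lag(latents, sched, [0, 1, 2, 3, 4, 5])
        assert best == 3

    def test_zero_shift(self):
        latents, sched = self._latents_with_shift(0)
        best, _ = select_decoding_lag(latents, sched, [0, 1, 2, 3])
        assert best == 0

    def test_flat_curve_smallest_lag(self):
        latents = np.zeros((2, 2, 100))
        sched = make_grating_schedule(1, 2, repeats_per_class=3,
                                      duration_timepoints=4, seed=2)
        best, acc = select_decoding_lag(latents, sched, [1, 2, 3])
        assert best == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_decoding_lag(np.zeros((1, 1, 10)), None, [])


class TestDimensionalitySelection:
    def test_cross_model_comparison_refused(self):
        with pytest.raises(ValueError, match="refused"):
            compare_likelihoods({"lds": -10.0, "cilds": -5.0})
        assert compare_likelihoods({"lds": [-10.0, -9.0]})

    def test_single_value_grid_short_circuits(self):
        Y = np.random.default_rng(11).standard_normal((4, 5, 20))
        best, lls = select_dimensionality(Y, "lds", [2], make_folds(4, 2, 0))
        assert best == 2 and lls == {2: None}

    def test_grid_validated(self):
        Y = np.zeros((4, 5, 20))
        with pytest.raises(ValueError):
            select_dimensionality(Y, "lds", [5], make_folds(4, 2, 0))

    def test_true_dimensionality_selected(self):
        """LDS data with p_true = 2: the CV likelihood picks 2 over 1 and 4 in
        most seeded replicates."""
        from conftest import random_lds_params
        from cilds.models import sample_lds

        wins = 0
        n_rep = 5
        for seed in range(n_rep):
            rng = np.random.default_rng(200 + seed)
            params = random_lds_params(rng, 8, 2)
            params.A *= 2.0
            _, Y = sample_lds(params, 80, 6, seed=seed)
            best, _ = select_dimensionality(
                Y, "lds", [1, 2, 4], make_folds(6, 2, seed), max_iter=40)
            wins += best == 2
        assert wins >= 0.8 * n_rep


class TestLeaveNeuronOut:
    def test_pipeline_on_shared_signal(self):
        """Neurons driven by one strong shared latent: held-out predictions
        correlate positively for every neuron, and the report is complete."""
        from cilds.evaluation import lno_evaluate
        from cilds.models import LDSParams, sample_lds

        rng = np.random.default_rng(12)
        q = 5
        params = LDSParams(A=rng.uniform(1.0, 2.0, (q, 1)), b=np.zeros(q),
                           R_diag=np.full(q, 0.1), D_diag=np.array([0.95]),
                           P_diag=np.array([1.0 - 0.95 ** 2]),
                           h1=np.zeros(1), G1_diag=np.ones(1))
        _, Y = sample_lds(params, 60, 6, seed=13)
        report = lno_evaluate("lds", Y, 1, make_folds(6, 2, seed=0), max_iter=30)
        assert report.correlations.shape == (q, 6)
        assert not np.isnan(report.correlations).any()
        assert np.all(report.per_neuron_mean > 0.5)

    def test_degenerate_traces_flagged_not_fatal(self):
        """A zero-variance recorded trace yields a NaN-flagged cell that is
        excluded from per-neuron means."""
        from cilds.evaluation import PredictionReport

        corr = np.array([[0.5, np.nan], [0.2, 0.4]])
        rep = PredictionReport(correlations=corr)
        assert np.allclose(rep.per_neuron_mean, [0.5, 0.3])
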