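import numpy as np
import pytest

from roldsis import benchmark, core, simulate
from roldsis.benchmark import (
    cv_error,
    lasso_fit,
    make_folds,
    overdetermined_sweep,
    ridge_fit,
    spls_fit,
    tune,
)


class TestMakeFolds:
    def test_even_split(self):
        plan = make_folds([10, 10, 10], k=5, seed=0)
        for s in range(3):
            sizes = [plan.fold_indices(s, f).size for f in range(5)]
            assert sizes == [2] * 5

    def test_deterministic(self):
        p1 = make_folds([9, 9], k=3, seed=7)
        p2 = make_folds([9, 9], k=3, seed=7)
        for a, b in zip(p1.assignment, p2.assignment):
            np.testing.assert_array_equal(a, b)

    def test_unbalanced_sizes(self):
        plan = make_folds([7], k=3, seed=1)
        sizes = sorted(plan.fold_indices(0, f).size for f in range(3))
        assert sizes == [2, 2, 3]

    def test_partition(self):
        plan = make_folds([11], k=4, seed=2)
        all_idx = np.concatenate([plan.fold_indices(0, f) for f in range(4)])
        assert sorted(all_idx) == list(range(11))

    def test_too_few_trials(self):
        with pytest.raises(ValueError, match="cannot be split"):
            make_folds([2], k=3, seed=0)


class TestRidge:
    def test_lambda_zero_overdetermined_is_ols(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        a, b = ridge_fit(X, y, 0.0)
        design = np.hstack([np.ones((10, 1)), X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert a == pytest.approx(coef[0], abs=1e-8)
        np.testing.assert_allclose(b, coef[1:], atol=1e-8)

    def test_dual_matches_primal(self, rng):
        # Oracle: direct primal-form solve on an HDLSS instance.
        X = rng.standard_normal((5, 128))
        y = rng.standard_normal(5)
        lam = 0.37
        _, b_dual = ridge_fit(X, y, lam)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        b_primal = np.linalg.solve(Xc.T @ Xc + lam * np.eye(128), Xc.T @ yc)
        np.testing.assert_allclose(b_dual, b_primal, atol=1e-8)

    def test_shrinkage_monotone_to_zero(self, rng):
        X = rng.standard_normal((6, 30))
        y = rng.standard_normal(6)
        norms = [
            np.linalg.norm(ridge_fit(X, y, lam)[1])
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0, 1e4)
        ]
        assert all(n1 > n2 for n1, n2 in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            ridge_fit(rng.standard_normal((3, 5)), np.zeros(3), -1.0)


class TestLasso:
    def test_full_shrinkage_above_critical_lambda(self, rng):
        X = rng.standard_normal((8, 20))
        y = rng.standard_normal(8)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        lam_max = 2.0 * np.abs(Xc.T @ yc).max()
        _, b = lasso_fit(X, y, lam_max * 1.01)
        np.testing.assert_allclose(b, 0.0, atol=1e-10)

    def test_small_lambda_near_least_squares(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.01 * rng.standard_normal(30)
        _, b = lasso_fit(X, y, 1e-8)
        np.testing.assert_allclose(b, [1.0, -2.0, 0.5], atol=0.05)


class TestSpls:
    def test_recovers_sparse_signal(self, rng):
        n = 40
        b_true = np.zeros(n)
        b_true[[3, 17]] = [2.0, -1.5]
        X = rng.standard_normal((60, n))
        y = X @ b_true + 0.01 * rng.standard_normal(60)
        _, b = spls_fit(X, y, zeta=0.5, n_components=2)
        # the two active coordinates dominate
        top2 = np.argsort(np.abs(b))[-2:]
        assert set(top2) == {3, 17}

    def test_sparsity_increases_with_zeta(self, rng):
        X = rng.standard_normal((20, 50))
        y = rng.standard_normal(20)
        nz_lo = np.count_nonzero(spls_fit(X, y, zeta=0.05, n_components=2)[1])
        nz_hi = np.count_nonzero(spls_fit(X, y, zeta=0.9, n_components=2)[1])
        assert nz_hi <= nz_lo

    def test_invalid_zeta(self, rng):
        with pytest.raises(ValueError, match="zeta"):
            spls_fit(rng.standard_normal((5, 8)), np.zeros(5), 1.5, 1)

    def test_invalid_component_count(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            spls_fit(rng.standard_normal((5, 8)), np.zeros(5), 0.5, 7)


class TestCvError:
    def test_noiseless_roldsis_mse_zero(self, noiseless_experiment):
        exp = noiseless_experiment
        trials = [np.tile(t, (4, 1)) for t in exp.templates]
        plan = make_folds([4] * 5, k=2, seed=0)
        res = cv_error("roldsis", plan, trials, exp.phi)
        assert res.mean_mse == pytest.approx(0.0, abs=1e-12)

    def test_ridge_infinite_lambda_predicts_training_mean(self, noisy_experiment):
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=3, seed=1)
        res = cv_error("ridge", plan, exp.trials, exp.phi, {"lam": 1e12})
        # with b ~ 0 the prediction is the training mean of y
        expected = np.var(exp.phi)  # test y about (equal) training mean
        assert res.mean_mse == pytest.approx(expected, rel=1e-3)

    def test_matches_handrolled_loop(self, noisy_experiment):
        # Oracle: independent CV loop written from scratch.
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=3, seed=5)
        res = cv_error("roldsis", plan, exp.trials, exp.phi)
        oracle_mse = []
        for fold in range(3):
            X_tr, y_tr, X_te, y_te = [], [], [], []
            for s, t in enumerate(exp.trials):
                for f in range(3):
                    idx = np.flatnonzero(plan.assignment[s] == f)
                    avg = t[idx].mean(axis=0)
                    (X_te if f == fold else X_tr).append(avg)
                    (y_te if f == fold else y_tr).append(exp.phi[s])
            fit = core.fit(core.ObservationSet(np.vstack(X_tr), np.array(y_tr)))
            preds = [core.predict(fit, x) for x in X_te]
            oracle_mse.append(np.mean((np.array(preds) - np.array(y_te)) ** 2))
        np.testing.assert_allclose(res.fold_mse, oracle_mse, rtol=1e-10)

    def test_invariant_to_fold_relabeling(self, noisy_experiment):
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=3, seed=2)
        relabeled = benchmark.FoldPlan(
            k=3,
            assignment=[(a + 1) % 3 for a in plan.assignment],
            seed=None,
        )
        r1 = cv_error("roldsis", plan, exp.trials, exp.phi)
        r2 = cv_error("roldsis", relabeled, exp.trials, exp.phi)
        assert r1.mean_mse == pytest.approx(r2.mean_mse, rel=1e-12)

    def test_unknown_method(self, noisy_experiment):
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=2, seed=0)
        with pytest.raises(ValueError, match="unknown method"):
            cv_error("pcr", plan, exp.trials, exp.phi)


class TestTune:
    def test_roldsis_has_no_parameter(self, noisy_experiment):
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=2, seed=0)
        with pytest.raises(ValueError, match="no tunable"):
            tune("roldsis", plan, exp.trials, exp.phi)

    def test_ridge_optimum_matches_grid_scan(self, noisy_experiment):
        # Oracle: dense grid scan of the CV curve.
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=3, seed=3)
        res = tune("ridge", plan, exp.trials, exp.phi,
                   {"log10_lambda": (-4, 4)})
        grid = np.logspace(-4, 4, 200)
        grid_best = min(
            cv_error("ridge", plan, exp.trials, exp.phi, {"lam": lam}).mean_mse
            for lam in grid
        )
        assert res.mean_mse <= grid_best * (1 + 1e-3)

    def test_noiseless_lambda_at_lower_edge(self, noiseless_experiment):
        exp = noiseless_experiment
        trials = [np.tile(t, (4, 1)) for t in exp.templates]
        plan = make_folds([4] * 5, k=2, seed=0)
        res = tune("ridge", plan, trials, exp.phi, {"log10_lambda": (-6, 2)})
        assert res.params["lam"] <= 10 ** -5.5

    def test_spls_returns_best_over_components(self, noisy_experiment):
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=2, seed=4)
        res = tune("spls", plan, exp.trials, exp.phi, {"max_components": 2})
        assert res.method == "spls"
        assert 1 <= res.params["n_components"] <= 2
        assert 0 < res.params["zeta"] < 1


class TestOverdeterminedSweep:
    def test_zero_noise_rms_zero(self, rng):
        config = simulate.SyntheticConfig(
            n_features=8, n_stimuli=5, trials_per_stimulus=6,
            angle_deg=45.0, noise_sd=0.0, seed=3,
        )
        exp = simulate.generate(config)
        out = overdetermined_sweep(exp.trials, exp.phi, group_sizes=(1, 2), seed=0)
        for rms in out.values():
            assert rms == pytest.approx(0.0, abs=1e-8)

    def test_rms_decreases_with_group_size(self):
        # Stochastic battery over seeds: averaging more trials per
        # observation reduces the in-sample RMS error.
        wins = 0
        for seed in range(5):
            config = simulate.SyntheticConfig(
                n_features=8, n_stimuli=5, trials_per_stimulus=30,
                angle_deg=45.0, snr_db=-5.0, seed=seed,
            )
            exp = simulate.generate(config)
            out = overdetermined_sweep(
                exp.trials, exp.phi, group_sizes=(1, 6), seed=seed
            )
            if out[6] < out[1]:
                wins += 1
        assert wins >= 4

    def test_underdetermined_rejected(self, rng):
        trials = [rng.standard_normal((3, 100)) for _ in range(5)]
        with pytest.raises(ValueError, match="overdetermined"):
            overdetermined_sweep(trials, np.arange(5.0), group_sizes=(1,), seed=0)

    def test_partition_bookkeeping(self, rng):
        # every trial used at most once: observation count = floor(T/g) per stimulus
        trials = [rng.standard_normal((7, 3)) for _ in range(5)]
        out = overdetermined_sweep(trials, np.arange(5.0), group_sizes=(2,), seed=1)
        assert set(out) == {2}


class TestRoldsisVsRidge:
    def test_comparable_cv_error_at_matched_noise(self, noisy_experiment):
        # Mirrors the paper's qualitative finding: no meaningful difference
        # between the exact fit and tuned ridge on this kind of data.
        exp = noisy_experiment
        plan = make_folds([t.shape[0] for t in exp.trials], k=3, seed=6)
        mse_roldsis = cv_error("roldsis", plan, exp.trials, exp.phi).mean_mse
        mse_ridge = tune(
            "ridge", plan, exp.trials, exp.phi, {"log10_lambda": (-6, 4)}
        ).mean_mse
        assert mse_ridge <= mse_roldsis * 1.05  # tuned ridge can only do better
        assert mse_roldsis <= mse_ridge * 3.0   # but not dramatically better
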