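"""Elastic-net solver correctness, grid search, selection and prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest

import methclock as mc
from methclock import enet

from conftest import beta_frame


def _standardized(rng, n, p):
    X = rng.normal(size=(n, p))
    return (X - X.mean(0)) / X.std(0)


class TestSolverOracles:
    def test_at_lambda_max_all_coefficients_zero(self):
        rng = np.random.default_rng(0)
        X = _standardized(rng, 30, 5)
        y = rng.normal(size=30) + 2 * X[:, 0]
        Xs, mu, sd = enet.standardize(X)
        lam_max = enet.make_lambda_path(Xs, y, 1.0)[0]
        fit = enet.fit_enet_cv(X, y, l1_ratio=1.0, lambdas=[lam_max * 1.001], n_folds=5)
        assert fit.n_nonzero == 0
        assert fit.intercept == pytest.approx(y.mean())

    @pytest.mark.parametrize("l1_ratio,lam", [(0.5, 0.3), (0.9, 0.1), (1.0, 0.05)])
    def test_objective_beats_brute_force_grid(self, l1_ratio, lam):
        """Solver objective <= dense grid minimum of the stated objective."""
        rng = np.random.default_rng(4)
        n, p = 6, 2
        X = _standardized(rng, n, p)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        fit = enet.fit_enet_cv(
            X, y, l1_ratio=l1_ratio, lambdas=[lam], tol=1e-12, n_folds=3
        )
        obj_fit = enet.enet_objective(X, y, fit.intercept, fit.coef, lam, l1_ratio)
        grid = np.arange(-3.0, 3.0, 0.01)
        best = np.inf
        for b1 in grid:
            # profile out b2 and intercept on a fine 1-D scan for speed
            for b2 in grid:
                b = np.array([b1, b2])
                b0 = np.mean(y - X @ b)  # unpenalized intercept optimum
                best = min(best, enet.enet_objective(X, y, b0, b, lam, l1_ratio))
        assert obj_fit <= best + 1e-8

    def test_lambda_to_zero_recovers_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = X @ beta + 0.5 + rng.normal(0, 0.1, 50)
        fit = enet.fit_enet_cv(X, y, l1_ratio=0.5, lambdas=[1e-10], tol=1e-14, n_folds=5)
        Z = np.column_stack([np.ones(50), X])
        ols = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols[1:], atol=1e-6)
        assert fit.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_ridge_matches_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        y = X[:, 0] - X[:, 2] + rng.normal(0, 0.2, 40)
        lam = 0.7
        fit = enet.fit_enet_cv(X, y, l1_ratio=0.0, lambdas=[lam], n_folds=5)
        Xs, mu, sd = enet.standardize(X)
        n = 40
        b_std = np.linalg.solve(Xs.T @ Xs + n * lam * np.eye(4), Xs.T @ (y - y.mean()))
        np.testing.assert_allclose(fit.coef, b_std / sd, atol=1e-6)

    def test_sparsity_monotone_along_lasso_path(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 30))
        y = X[:, 0] * 2 + X[:, 1] - X[:, 2] + rng.normal(0, 0.5, 40)
        Xs, _, _ = enet.standardize(X)
        path = enet.make_lambda_path(Xs, y, 1.0, n_lambdas=50)
        coefs = enet.coef_path(Xs, y - y.mean(), 1.0, path, tol=1e-8)
        nnz = (np.abs(coefs) > 1e-10).sum(axis=0)
        # larger lambda (earlier in path) never has more nonzeros
        assert np.all(np.diff(nnz) >= -1e-9) or np.all(np.diff(nnz.astype(int)) >= 0)

    def test_support_recovery_noise_free(self):
        rng = np.random.default_rng(5)
        n, p = 20, 5
        X = _standardized(rng, n, p)
        beta = np.zeros(p)
        beta[[1, 3]] = [2.0, -1.5]
        y = X @ beta + 3.0
        fit = enet.fit_enet_cv(X, y, l1_ratio=0.9, n_folds=5, tol=1e-10)
        support = set(np.flatnonzero(fit.coef))
        assert support == {1, 3}
        # within 5% of the OLS fit on the true support (here: the truth)
        np.testing.assert_allclose(fit.coef[[1, 3]], beta[[1, 3]], rtol=0.05)

    def test_constant_y_is_degenerate(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        with pytest.raises(mc.InsufficientDataError):
            enet.fit_enet_cv(X, np.full(12, 5.0), l1_ratio=0.5, n_folds=3)

    def test_alpha_out_of_range(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        with pytest.raises(ValueError):
            enet.fit_enet_cv(X, np.arange(12.0), l1_ratio=1.5, n_folds=3)


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = mc.ElasticNetClockCV(l1_ratio=0.7, random_state=1)
        params = est.get_params()
        assert params["l1_ratio"] == 0.7
        est2 = clone(est).set_params(l1_ratio=0.3)
        assert est2.get_params()["l1_ratio"] == 0.3

    def test_fit_predict_and_export(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(1, 15, 25)
        X = pd.DataFrame(
            {
                "cg00000001": np.clip(0.2 + 0.03 * ages + rng.normal(0, 0.01, 25), 0, 1),
                "cg00000002": rng.random(25),
            }
        )
        est = mc.ElasticNetClockCV(l1_ratio=0.9, n_folds=5, random_state=0).fit(X, ages)
        pred = est.predict(X)
        assert np.corrcoef(pred, ages)[0, 1] > 0.95
        model = est.to_clock_model(n_training=25)
        assert "cg00000001" in model.coefficients
        assert model.n_terms == est.n_nonzero_


@pytest.fixture(scope="module")
def fixture_grid():
    cfg = mc.SyntheticConfig(
        n_samples=30, n_probes=120, n_informative=4, noise_sd=0.02, seed=11,
        detection_fail_rate=0.05,
    )
    m, meta, truth = mc.generate(cfg)
    spec = mc.ElasticNetSpec(seed=11, n_folds=5)
    grid = mc.alpha_grid_search(
        m, meta, thresholds=(0, 10, 20, 30), alphas=mc.clock.DEFAULT_ALPHAS,
        spec=spec,
    )
    return m, meta, truth, spec, grid


class TestGridSearch:
    def test_grid_cardinality(self, fixture_grid):
        _, _, _, _, grid = fixture_grid
        assert len(grid.rows) == 9 * 4

    def test_sparsity_trend_in_alpha(self, fixture_grid):
        """Coefficient count trends downward as alpha rises (ties allowed)."""
        _, _, _, _, grid = fixture_grid
        df = grid.to_frame()
        for thr, sub in df.groupby("cpg_filter_threshold"):
            nnz = sub.sort_values("alpha")["n_coefficients"].to_numpy()
            assert nnz[-1] <= nnz[0]
            # Spearman-style trend: decreasing on average
            assert np.polyfit(np.arange(len(nnz)), nnz, 1)[0] <= 0

    def test_grid_deterministic_under_seed(self, fixture_grid):
        m, meta, _, spec, grid = fixture_grid
        grid2 = mc.alpha_grid_search(
            m, meta, thresholds=(0, 10, 20, 30), alphas=mc.clock.DEFAULT_ALPHAS,
            spec=spec,
        )
        df1, df2 = grid.to_frame(), grid2.to_frame()
        pd.testing.assert_frame_equal(df1, df2)
        for r1, r2 in zip(grid.rows, grid2.rows):
            assert r1["model"].coefficients == r2["model"].coefficients
            assert r1["model"].intercept == r2["model"].intercept


class TestSelectModel:
    def _row(self, alpha, thr, nterms, medae):
        metrics = mc.Metrics(medae, medae, 0.9, 0.81, 1.0, 0.0, 1e-6)
        model = mc.ClockModel(0.0, {f"cg{i:05d}": 1.0 for i in range(nterms)},
                              {"alpha": alpha, "cpg_filter_threshold": thr})
        return {"alpha": alpha, "cpg_filter_threshold": thr,
                "n_coefficients": nterms, "metrics": metrics, "model": model}

    def test_single_row(self):
        grid = mc.CandidateGrid([self._row(0.5, 10, 3, 2.0)])
        assert mc.select_model(grid).n_terms == 3

    def test_parsimony_within_tolerance(self):
        grid = mc.CandidateGrid(
            [self._row(0.9, 10, 8, 1.54), self._row(0.1, 0, 112, 1.55)]
        )
        chosen = mc.select_model(grid, medae_tolerance=0.05)
        assert chosen.n_terms == 8

    def test_tie_breaks_prefer_larger_alpha_then_threshold(self):
        rows = [self._row(0.5, 10, 5, 1.0), self._row(0.9, 0, 5, 1.0),
                self._row(0.9, 20, 5, 1.02)]
        chosen = mc.select_model(mc.CandidateGrid(rows), medae_tolerance=0.05)
        assert chosen.training_meta["alpha"] == 0.9
        assert chosen.training_meta["cpg_filter_threshold"] == 20

    def test_invariant_under_row_permutation(self):
        rows = [self._row(a, t, n, m) for (a, t, n, m) in
                [(0.1, 0, 50, 1.2), (0.5, 10, 9, 1.21), (0.9, 30, 9, 1.23)]]
        # both 9-term rows are within tolerance; the alpha tie-break decides
        for perm in itertools.permutations(rows):
            chosen = mc.select_model(mc.CandidateGrid(list(perm)), 0.05)
            assert chosen.training_meta["alpha"] == 0.9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            mc.select_model(mc.CandidateGrid([]))


class TestPredictAge:
    def test_published_clock_boundary_values(self, published_clock):
        probes = published_clock.probe_ids
        zeros = mc.BetaMatrix(beta_frame(np.zeros((8, 1)), probes=probes))
        assert mc.predict_age(published_clock, zeros)["s0"] == pytest.approx(
            -4.6720053, abs=1e-12
        )
        ones = mc.BetaMatrix(beta_frame(np.ones((8, 1)), probes=probes))
        # intercept plus the sum of all eight printed coefficients
        expected = -4.6720053 + sum(published_clock.coefficients.values())
        assert mc.predict_age(published_clock, ones)["s0"] == pytest.approx(expected)
        assert expected == pytest.approx(-1.3618315, abs=1e-7)

    def test_identical_betas_identical_predictions(self, published_clock):
        rng = np.random.default_rng(8)
        col = rng.random(8)
        m = mc.BetaMatrix(
            beta_frame(np.tile(col[:, None], (1, 2)), probes=published_clock.probe_ids)
        )
        out = mc.predict_age(published_clock, m)
        assert out["s0"] == out["s1"]

    def test_missing_probe_policies(self, published_clock):
        m = mc.BetaMatrix(beta_frame(np.full((7, 1), 0.5),
                                     probes=published_clock.probe_ids[:7]))
        with pytest.raises(mc.ValidationError, match="cg"):
            mc.predict_age(published_clock, m, missing_policy="error")
        assert mc.predict_age(published_clock, m, missing_policy="skip_sample") == {}

    def test_nan_beta_respects_policy(self, published_clock):
        vals = np.full((8, 2), 0.5)
        vals[3, 1] = np.nan
        m = mc.BetaMatrix(beta_frame(vals, probes=published_clock.probe_ids))
        out = mc.predict_age(published_clock, m, missing_policy="skip_sample")
        assert set(out) == {"s0"}
        with pytest.raises(mc.ValidationError, match="s1"):
            mc.predict_age(published_clock, m, missing_policy="error")


class TestMergeAndOverlap:
    def _setpair(self, probes, samples, seed):
        rng = np.random.default_rng(seed)
        m = mc.BetaMatrix(beta_frame(rng.random((len(probes), len(samples))),
                                     probes=probes, samples=samples))
        meta = [mc.SampleMetadata(s, age_years=float(i + 1), confidence_tier="strict",
                                  group_label=f"g{seed}")
                for i, s in enumerate(samples)]
        return m, meta

    def test_probe_intersection_and_counts(self):
        a = self._setpair(["cga", "cgb", "cgc"], [f"a{i}" for i in range(67)], 1)
        b = self._setpair(["cgb", "cgc", "cgd"], [f"b{i}" for i in range(31)], 2)
        merged, meta = mc.merge_training_sets(a, b)
        assert set(merged.probe_ids) == {"cgb", "cgc"}
        assert merged.n_samples == 98 and len(meta) == 98
        labels = {r.group_label for r in meta}
        assert labels == {"g1", "g2"}  # species labels preserved, no covariate

    def test_merge_commutative_up_to_order(self):
        a = self._setpair(["cga", "cgb"], ["a0", "a1"], 3)
        b = self._setpair(["cgb", "cga"], ["b0"], 4)
        m1, _ = mc.merge_training_sets(a, b)
        m2, _ = mc.merge_training_sets(b, a)
        assert set(m1.sample_ids) == set(m2.sample_ids)
        for s in m1.sample_ids:
            pd.testing.assert_series_equal(
                m1.betas[s].sort_index(), m2.betas[s].sort_index()
            )

    def test_merge_errors(self):
        a = self._setpair(["cga"], ["x"], 5)
        b = self._setpair(["cgb"], ["y"], 6)
        with pytest.raises(mc.MergeError):
            mc.merge_training_sets(a, b)
        c = self._setpair(["cga"], ["x"], 7)
        with pytest.raises(mc.MergeError):
            mc.merge_training_sets(a, c)

    def test_clock_overlap_matches_nested_scan(self):
        rng = np.random.default_rng(9)
        ka = [f"cg{i:03d}" for i in rng.choice(50, 12, replace=False)]
        kb = [f"cg{i:03d}" for i in rng.choice(50, 15, replace=False)]
        a = mc.ClockModel(0, {k: 1.0 for k in ka})
        b = mc.ClockModel(0, {k: -1.0 for k in kb})
        brute = {x for x in a.coefficients for y in b.coefficients if x == y}
        assert mc.clock_overlap(a, b) == brute
        assert mc.clock_overlap(a, a) == set(a.coefficients)
        disjoint = mc.ClockModel(0, {"cgzz": 2.0})
        assert mc.clock_overlap(a, disjoint) == set()
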