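import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from borealdeer.landscape import SiteCovariateTable
from borealdeer.persistence import (
    PersistenceResponse,
    deviance_explained,
    diagnostics,
    fit_binomial_glm,
    morans_i,
    prepare_covariates,
    prune_by_pvalue,
    rank_candidate_models,
    scan_scales,
    stepwise_reduce,
)


def _table_from_wide(wide: pd.DataFrame, radii=(1000.0,), kinds=None) -> SiteCovariateTable:
    """Tidy table with the same values at each radius."""
    rows = []
    for r in radii:
        for sid, row in wide.iterrows():
            for var, val in row.items():
                rows.append((sid, r, var, val))
    df = pd.DataFrame(rows, columns=["site_id", "radius_m", "variable", "value"])
    kinds = kinds or {v: "percent" for v in wide.columns}
    return SiteCovariateTable(data=df, kinds=kinds)


def _simulated(n=120, beta=(0.8, -0.5), trials=36, seed=0, noise_terms=0):
    rng = np.random.default_rng(seed)
    k = len(beta) + noise_terms
    X = pd.DataFrame(
        rng.normal(size=(n, k)), columns=[f"v{i}" for i in range(k)],
        index=[f"s{i}" for i in range(n)],
    )
    X = (X - X.mean()) / X.std(ddof=1)
    eta = 0.2 + X.iloc[:, : len(beta)].to_numpy() @ np.asarray(beta)
    succ = rng.binomial(trials, expit(eta))
    resp = PersistenceResponse(
        site_ids=list(X.index), successes=succ.astype(float),
        trials=np.full(n, float(trials)),
        coordinates=rng.uniform(0, 2e4, size=(n, 2)),
    )
    return resp, X


class TestPrepare:
    def test_duplicate_column_one_survivor(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 50, 30)
        wide = pd.DataFrame(
            {"a": a, "b": a.copy(), "c": rng.uniform(10, 50, 30)},
            index=[f"s{i}" for i in range(30)],
        )
        prep = prepare_covariates(_table_from_wide(wide), 1000.0)
        assert len(prep.X.columns) == 2
        assert len(prep.dropped_correlated) == 1
        assert {"a", "b"} & set(prep.X.columns)

    def test_sparse_variables_combined(self):
        rng = np.random.default_rng(1)
        wide = pd.DataFrame(
            {
                "common": rng.uniform(20, 60, 40),
                "rare1": rng.uniform(0, 1.0, 40),  # ~0.5% mean cover
                "rare2": rng.uniform(0, 1.5, 40),
            },
            index=[f"s{i}" for i in range(40)],
        )
        prep = prepare_covariates(_table_from_wide(wide), 1000.0, sparse_cutoff_pct=2.0)
        assert set(prep.combined_members) == {"rare1", "rare2"}
        assert "combined_sparse" in prep.X.columns
        assert "rare1" not in prep.X.columns

    def test_output_standardized(self):
        rng = np.random.default_rng(2)
        wide = pd.DataFrame(
            rng.uniform(5, 80, size=(25, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(25)],
        )
        prep = prepare_covariates(_table_from_wide(wide), 1000.0)
        np.testing.assert_allclose(prep.X.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(prep.X.std(ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_dropped_with_warning(self):
        wide = pd.DataFrame(
            {"flat": np.full(20, 30.0), "ok": np.linspace(10, 60, 20)},
            index=[f"s{i}" for i in range(20)],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            prep = prepare_covariates(_table_from_wide(wide), 1000.0)
        assert list(prep.X.columns) == ["ok"]

    def test_retained_pairs_below_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=50)
        wide = pd.DataFrame(
            {
                "x1": 30 + 5 * base,
                "x2": 30 + 5 * base + rng.normal(0, 1.0, 50),
                "x3": rng.uniform(10, 60, 50),
            },
            index=[f"s{i}" for i in range(50)],
        )
        prep = prepare_covariates(_table_from_wide(wide), 1000.0, r_max=0.7)
        corr = prep.X.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.7


class TestGlm:
    def test_intercept_only_closed_form(self):
        resp, X = _simulated(seed=4)
        fit = fit_binomial_glm(resp, X, terms=[])
        expect = logit(resp.successes.sum() / resp.trials.sum())
        assert fit.params[0] == pytest.approx(expect, abs=1e-8)

    def test_irls_matches_direct_newton(self):
        # independent maximizer of the binomial log-likelihood on a 5-site toy
        resp, X = _simulated(n=5, beta=(0.5,), seed=5)
        fit = fit_binomial_glm(resp, X, terms=["v0"])
        y, m = resp.successes, resp.trials
        Z = np.column_stack([np.ones(5), X["v0"]])

        def nll(b):
            eta = Z @ b
            return -(y * eta - m * np.logaddexp(0, eta)).sum()

        direct = minimize(nll, np.zeros(2), method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(fit.params, direct.x, atol=1e-6)

    def test_beta_recovery_within_2se(self):
        resp, X = _simulated(n=200, beta=(0.8, -0.5), seed=6)
        fit = fit_binomial_glm(resp, X)
        est, se = fit.params[1:], fit.bse[1:]
        assert np.all(np.abs(est - np.array([0.8, -0.5])) <= 2 * se)

    def test_residual_deviance_decreases_with_terms(self):
        resp, X = _simulated(seed=7, noise_terms=2)
        small = fit_binomial_glm(resp, X, terms=["v0"])
        big = fit_binomial_glm(resp, X, terms=["v0", "v1", "v2"])
        assert big.deviance <= small.deviance + 1e-9
        assert small.deviance <= small.null_deviance + 1e-9


class TestSelection:
    def test_stepwise_improves_aic_and_is_submodel(self):
        resp, X = _simulated(seed=8, noise_terms=3)
        full = fit_binomial_glm(resp, X)
        red = stepwise_reduce(full)
        assert red.aic <= full.aic
        assert set(red.model.terms) <= set(full.model.terms)

    def test_stepwise_eliminates_pure_noise(self):
        hits = 0
        for s in range(10):
            resp, X = _simulated(n=150, beta=(0.9, -0.6), seed=100 + s, noise_terms=1)
            red = stepwise_reduce(fit_binomial_glm(resp, X))
            if "v2" not in red.model.terms and {"v0", "v1"} <= set(red.model.terms):
                hits += 1
        assert hits >= 8

    def test_strong_effects_all_retained(self):
        resp, X = _simulated(n=200, beta=(1.0, -0.8), seed=9)
        red = stepwise_reduce(fit_binomial_glm(resp, X))
        assert set(red.model.terms) == {"v0", "v1"}

    def test_prune_keeps_significant_model_unchanged(self):
        resp, X = _simulated(n=200, beta=(1.0, -0.8), seed=10)
        fit = fit_binomial_glm(resp, X)
        assert np.all(fit.pvalues[1:] < 0.2)
        pruned = prune_by_pvalue(fit, alpha=0.2)
        assert pruned.model.terms == fit.model.terms

    def test_prune_removes_noise_term(self):
        resp, X = _simulated(n=200, beta=(1.0,), seed=11, noise_terms=1)
        fit = fit_binomial_glm(resp, X)
        if fit.pvalues[2] <= 0.2:  # noise happened to look significant
            pytest.skip("noise term not prunable at this seed")
        pruned = prune_by_pvalue(fit, alpha=0.2)
        assert pruned.model.terms == ["v0"]

    def test_prune_everything_warns_intercept_only(self):
        resp, X = _simulated(n=100, beta=(0.0,), seed=12)
        fit = fit_binomial_glm(resp, X)
        with pytest.warns(UserWarning, match="intercept-only"):
            pruned = prune_by_pvalue(fit, alpha=1e-9)
        assert pruned.model.terms == []

    def test_scan_identical_covariates_equal_weights(self):
        rng = np.random.default_rng(13)
        wide = pd.DataFrame(
            rng.uniform(5, 60, size=(40, 2)), columns=["a", "b"],
            index=[f"s{i}" for i in range(40)],
        )
        tab = _table_from_wide(wide, radii=(500.0, 1000.0, 2000.0))
        resp, _ = _simulated(n=40, beta=(0.0,), seed=13)
        resp.site_ids = list(wide.index)
        scan = scan_scales(resp, tab)
        np.testing.assert_allclose(scan.table["weight"], 1 / 3, atol=1e-9)
        assert scan.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_candidate_ranking(self):
        resp, X = _simulated(n=150, beta=(0.9, -0.6), seed=14)
        from borealdeer.persistence import PreparedCovariates

        prep = PreparedCovariates(
            X=X, radius_m=1000.0, scaling=pd.DataFrame(),
            dropped_correlated=[], combined_members=[],
        )
        ranking, fits = rank_candidate_models(
            resp, prep, {"true": ["v0", "v1"], "half": ["v0"], "null": []}
        )
        assert ranking.best == "true"
        assert ranking.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(KeyError, match="unknown terms"):
            rank_candidate_models(resp, prep, {"bad": ["nope"]})

    def test_single_candidate_weight_one(self):
        resp, X = _simulated(n=60, seed=15)
        from borealdeer.persistence import PreparedCovariates

        prep = PreparedCovariates(
            X=X, radius_m=1000.0, scaling=pd.DataFrame(),
            dropped_correlated=[], combined_members=[],
        )
        ranking, _ = rank_candidate_models(resp, prep, {"only": ["v0"]})
        assert ranking.table["weight"].iloc[0] == pytest.approx(1.0)


class TestDiagnostics:
    def test_deviance_explained_from_reported_deviances(self):
        # printed deviance pairs are exact desk checks of the formula
        assert deviance_explained(465.4, 191.26) == pytest.approx(0.589, abs=5e-4)
        assert deviance_explained(295.9, 160.27) == pytest.approx(0.458, abs=5e-4)

    def test_moran_matches_double_loop_oracle(self):
        rng = np.random.default_rng(16)
        n = 61
        coords = rng.uniform(0, 3e4, size=(n, 2))
        z = rng.normal(size=n)
        res = morans_i(z, coords)
        # naive O(n^2) computation
        zc = z - z.mean()
        num = s0 = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                w = 1.0 / np.hypot(*(coords[i] - coords[j]))
                num += w * zc[i] * zc[j]
                s0 += w
        expect = (n / s0) * num / (zc @ zc)
        assert res["I"] == pytest.approx(expect, abs=1e-12)
        assert res["expected"] == pytest.approx(-1 / 60, abs=1e-15)

    def test_moran_permutation_agrees_with_normal_p(self):
        rng = np.random.default_rng(17)
        n = 61
        coords = rng.uniform(0, 3e4, size=(n, 2))
        z = rng.normal(size=n)
        res = morans_i(z, coords, permutations=999, seed=1)
        assert abs(res["p"] - res["p_perm"]) < 0.05

    def test_moran_coincident_sites_error(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="oincident"):
            morans_i(np.array([1.0, 2.0, 3.0]), coords)

    def test_cv_perfect_predictions_zero_error(self):
        # identical sites: held-out predictions equal observed proportions
        n = 20
        resp = PersistenceResponse(
            site_ids=[f"s{i}" for i in range(n)],
            successes=np.full(n, 18.0), trials=np.full(n, 36.0),
            coordinates=np.column_stack([np.arange(n), np.zeros(n)]) * 1000.0,
        )
        X = pd.DataFrame(index=resp.site_ids)
        fit = fit_binomial_glm(resp, X, terms=[])
        diag = diagnostics(fit, k=5, seed=0)
        assert diag.cv_error == pytest.approx(0.0, abs=1e-12)

    def test_cv_seeded_reproducibility_and_k_validation(self):
        resp, X = _simulated(n=60, seed=18)
        fit = fit_binomial_glm(resp, X)
        d1 = diagnostics(fit, k=10, seed=3)
        d2 = diagnostics(fit, k=10, seed=3)
        assert d1.cv_error == d2.cv_error
        with pytest.raises(ValueError, match="folds exceed"):
            diagnostics(fit, k=61, seed=0)

    def test_dispersion_near_one_for_binomial_data(self):
        resp, X = _simulated(n=300, beta=(0.7, -0.4), seed=19)
        fit = fit_binomial_glm(resp, X)
        diag = diagnostics(fit, k=10, seed=0)
        assert 0.6 < diag.dispersion < 1.5
        assert 0.0 <= diag.deviance_explained <= 1.0
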