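"""Association layers: PTA OLS, GRM, mixed-model equations, EM-REML."""

import numpy as np
import pandas as pd
import pytest

from rohpipe.assoc import (
    AssocConfig,
    ModelSpec,
    build_grm,
    em_reml,
    fit_trait_class_models,
    incidence_matrices,
    pta_regression,
    reml_loglik,
    solve_mme,
)
from rohpipe.summaries import DistinctROH, FrohTable

from conftest import make_dataset


def distinct(carriers, chrom=1, start=10**6, end=3 * 10**6):
    return DistinctROH(chrom, start, end, 0, 10, tuple(carriers))


def froh_table(animals, values=None):
    values = np.zeros(len(animals)) if values is None else np.asarray(values, float)
    return FrohTable(pd.DataFrame({
        "animal_id": list(animals),
        "sum_roh_bp": (values * 10**9).astype(np.int64),
        "l_aut_bp": 10**9,
        "froh": values,
    }))


class TestPTARegression:
    def test_group_mean_difference_exact(self):
        animals = [f"a{k}" for k in range(8)]
        pta = pd.DataFrame({"animal_id": animals,
                            "pta_milk": [2.0] * 4 + [0.0] * 4})
        res = pta_regression(pta, [distinct(animals[:4])], min_carriers=2)
        assert res["beta"].iloc[0] == pytest.approx(2.0)
        assert res["p"].iloc[0] < 1e-10  # zero residual

    def test_identical_group_means_give_zero_beta(self):
        animals = [f"a{k}" for k in range(6)]
        pta = pd.DataFrame({"animal_id": animals, "pta_milk": [1.0, 2.0, 3.0] * 2})
        res = pta_regression(pta, [distinct(animals[:3])], min_carriers=1)
        assert res["beta"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_and_statsmodels(self, rng):
        """8-animal worked table against hand OLS and statsmodels."""
        import statsmodels.api as sm

        animals = [f"a{k}" for k in range(8)]
        y = rng.normal(size=8)
        carriers = animals[:3]
        pta = pd.DataFrame({"animal_id": animals, "pta_milk": y})
        res = pta_regression(pta, [distinct(carriers)], min_carriers=1)
        x = np.array([1.0] * 3 + [0.0] * 5)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res["beta"].iloc[0] == pytest.approx(fit.params[1], rel=1e-12)
        assert res["se"].iloc[0] == pytest.approx(fit.bse[1], rel=1e-12)
        assert res["t"].iloc[0] == pytest.approx(fit.tvalues[1], rel=1e-12)
        assert res["p"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-10)
        assert res["df"].iloc[0] == 6

    def test_non_informative_indicator_skipped(self):
        animals = [f"a{k}" for k in range(4)]
        pta = pd.DataFrame({"animal_id": animals, "pta_milk": [1.0, 2, 3, 4]})
        res = pta_regression(pta, [distinct(animals)], min_carriers=1)
        assert len(res) == 0

    def test_min_carriers_filter_and_missing_carrier(self):
        animals = [f"a{k}" for k in range(6)]
        pta = pd.DataFrame({"animal_id": animals, "pta_milk": np.arange(6.0)})
        assert len(pta_regression(pta, [distinct(animals[:2])], min_carriers=3)) == 0
        with pytest.raises(ValueError, match="absent from PTA"):
            pta_regression(pta, [distinct(["ghost", *animals[:2]])], min_carriers=1)


class TestGRM:
    def test_identical_animals_rank_one(self):
        calls = np.tile(np.array([0, 1, 2, 0, 1], dtype=np.int8), (3, 1))
        g = build_grm(make_dataset(calls))
        assert np.allclose(g, g[0, 0])

    def test_hand_computed_three_by_five(self):
        calls = np.array(
            [[0, 1, 2, 0, 1],
             [1, 1, 0, 2, 0],
             [2, 0, 0, 1, -1]], dtype=np.int8)
        ds = make_dataset(calls)
        d = calls.astype(float)
        d[d < 0] = np.nan
        p = np.nanmean(d, axis=0) / 2
        d2 = d.copy()
        d2[2, 4] = 2 * p[4]
        w = d2 - 2 * p
        expected = w @ w.T / (2 * np.sum(p * (1 - p)))
        g = build_grm(ds)
        assert np.allclose(g, expected, atol=1e-12)
        assert np.allclose(g, g.T)

    def test_no_polymorphic_markers_errors(self):
        calls = np.zeros((3, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="polymorphic"):
            build_grm(make_dataset(calls))


def toy_phenotypes(n=10, n_hy=2, n_months=2, trait="milk_305d", rng=None):
    rng = rng or np.random.default_rng(0)
    animals = [f"c{k}" for k in range(n)]
    return pd.DataFrame({
        "cow_id": animals,
        trait: rng.normal(100, 10, n),
        "herd_year": [f"H{k % n_hy}" for k in range(n)],
        "calving_month": [(k // n_hy) % n_months + 1 for k in range(n)],
        "age_at_calving": rng.uniform(22, 40, n),
    })


class TestIncidence:
    def test_column_count_example(self):
        """10 cows, 2 herd-years, 2 months, 1 ROH -> 6 columns."""
        ph = toy_phenotypes()
        animals = ph["cow_id"].tolist()
        spec = ModelSpec("milk_305d", "2-4", [distinct(animals[:4])], min_carriers=1)
        mats = incidence_matrices(ph, froh_table(animals, np.linspace(0, 0.1, 10)), spec)
        assert mats["X"].shape == (10, 6)
        assert mats["X_names"] == ["mu", "hy:H1", "month:2", "age", "froh",
                                   "roh:1:1000000-3000000"]
        assert np.allclose(mats["Z"], np.eye(10))

    def test_single_herd_year_absorbed(self):
        ph = toy_phenotypes(n_hy=1)
        animals = ph["cow_id"].tolist()
        spec = ModelSpec("milk_305d", "2-4", [], min_carriers=1)
        mats = incidence_matrices(ph, froh_table(animals, np.linspace(0, 0.1, 10)), spec)
        assert not any(n.startswith("hy:") for n in mats["X_names"])

    def test_collinear_column_dropped(self):
        ph = toy_phenotypes()
        animals = ph["cow_id"].tolist()
        # constant froh duplicates the intercept -> dropped, logged
        spec = ModelSpec("milk_305d", "2-4", [], min_carriers=1)
        mats = incidence_matrices(ph, froh_table(animals, np.full(10, 0.03)), spec)
        assert "froh" in mats["dropped"]

    def test_xty_matches_accumulation(self, rng):
        ph = toy_phenotypes(n=30, n_hy=3, n_months=4, rng=rng)
        animals = ph["cow_id"].tolist()
        spec = ModelSpec("milk_305d", "2-4", [distinct(animals[::3])], min_carriers=1)
        mats = incidence_matrices(ph, froh_table(animals, rng.uniform(0, 0.1, 30)), spec)
        y, X = mats["y"], mats["X"]
        manual = np.zeros(X.shape[1])
        for i in range(len(y)):
            manual += X[i] * y[i]
        assert np.allclose(X.T @ y, manual)

    def test_missing_froh_errors(self):
        ph = toy_phenotypes()
        spec = ModelSpec("milk_305d", "2-4", [], min_carriers=1)
        with pytest.raises(ValueError, match="without Froh"):
            incidence_matrices(ph, froh_table(["c0"]), spec)


class TestSolveMME:
    @pytest.fixture
    def system(self, rng):
        n, q = 12, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        Z = np.zeros((n, q))
        Z[np.arange(n), rng.integers(0, q, n)] = 1.0
        A = rng.normal(size=(q, q))
        G = A @ A.T / q + 0.5 * np.eye(q)
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=n) * 2
        return y, X, Z, G

    def test_matches_gls_oracle(self, system):
        """Henderson solutions equal the direct GLS route to 1e-10."""
        y, X, Z, G = system
        lam = 2.5
        res = solve_mme(y, X, Z, G, lam)
        V = Z @ G @ Z.T + np.eye(len(y)) * lam  # sigma_a2=1, sigma_e2=lam
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = G @ Z.T @ Vi @ (y - X @ b)
        assert np.allclose(res.beta, b, rtol=1e-10, atol=1e-12)
        assert np.allclose(res.u, u, rtol=1e-10, atol=1e-12)
        assert res.solution_residual < 1e-8 * max(1.0, np.abs(y).max())

    def test_infinite_lambda_is_ols(self, system):
        y, X, Z, G = system
        res = solve_mme(y, X, Z, G, 1e12)
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(res.beta, b_ols, atol=1e-6)
        assert np.abs(res.u).max() < 1e-6

    def test_no_random_term_is_exact_ols(self, system):
        y, X, *_ = system
        res = solve_mme(y, X, None, None, 1.0)
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(res.beta, b_ols, atol=1e-12)
        # SEs match the standard OLS formula
        sigma2 = ((y - X @ b_ols) @ (y - X @ b_ols)) / (len(y) - 3)
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
        assert np.allclose(res.se_beta, se, rtol=1e-10)

    def test_identity_g_is_ridge_per_cow(self, system):
        y, X, Z, _ = system
        lam = 3.0
        res = solve_mme(y, X, Z, np.eye(Z.shape[1]), lam)
        # direct dense solve of [X Z] with ridge on the u block
        p, q = X.shape[1], Z.shape[1]
        W = np.hstack([X, Z])
        D = np.zeros((p + q, p + q))
        D[p:, p:] = lam * np.eye(q)
        sol = np.linalg.solve(W.T @ W + D, W.T @ y)
        assert np.allclose(np.concatenate([res.beta, res.u]), sol, rtol=1e-10)

    def test_bad_lambda(self, system):
        y, X, Z, G = system
        with pytest.raises(ValueError, match="lambda"):
            solve_mme(y, X, Z, G, 0.0)


class TestEMREML:
    def test_max_iter_zero_returns_start(self, system_small=None):
        rng = np.random.default_rng(5)
        n = 20
        X = np.ones((n, 1))
        Z = np.eye(n)
        G = np.eye(n)
        y = rng.normal(size=n)
        out = em_reml(y, X, Z, G, start=(2.0, 3.0), max_iter=0)
        assert (out["sigma_a2"], out["sigma_e2"]) == (2.0, 3.0)

    def test_nonpositive_start_errors(self):
        with pytest.raises(ValueError, match="positive"):
            em_reml(np.zeros(3), np.ones((3, 1)), np.eye(3), np.eye(3), start=(0.0, 1.0))

    def test_loglik_nondecreasing(self, rng):
        n = 60
        A = rng.normal(size=(n, n))
        G = A @ A.T / n + 0.3 * np.eye(n)
        L = np.linalg.cholesky(G)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = np.eye(n)
        y = X @ np.array([3.0, 1.0]) + L @ rng.standard_normal(n) + rng.normal(size=n)
        out = em_reml(y, X, Z, G, start=(0.2, 2.0), max_iter=25)
        lls = [reml_loglik(y, X, Z, G, sa, se) for sa, se in out["history"]]
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-8 * abs(a)

    def test_lambda_recovery_calibration(self):
        """sigma_a2 = sigma_e2: estimated lambda in [0.5, 2] in >=90% of 20
        seeded replicates at n = 300 cows with a marker-based G."""
        ok = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            n, m = 300, 500
            calls = rng.binomial(2, rng.uniform(0.1, 0.5, m)[None, :], size=(n, m)).astype(np.int8)
            G = build_grm(make_dataset(calls, animal_ids=[f"c{k}" for k in range(n)]))
            L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
            y = 10 + L @ rng.standard_normal(n) + rng.standard_normal(n)
            v = y.var()
            out = em_reml(y, np.ones((n, 1)), np.eye(n), G, start=(v / 2, v / 2),
                          max_iter=60, tol=1e-5)
            ok += 0.5 <= out["lambda"] <= 2.0
        assert ok >= 18


class TestFitTraitClassModels:
    def test_constant_trait_flagged_degenerate(self):
        ph = toy_phenotypes()
        ph["milk_305d"] = 5000.0
        animals = ph["cow_id"].tolist()
        G = np.eye(10)
        res = fit_trait_class_models(
            ph, froh_table(animals, np.linspace(0, 0.1, 10)),
            [distinct(animals[:4])],
            config=AssocConfig(traits=("milk_305d",), min_carriers=2),
            G=G, grm_animal_ids=animals,
        )
        assert len(res) == 1
        assert bool(res["degenerate"].iloc[0]) is True
        assert res["beta"].iloc[0] == 0.0

    def test_classes_without_terms_skipped_and_bh_column(self, rng):
        ph = toy_phenotypes(n=40, n_hy=2, n_months=3, rng=rng)
        animals = ph["cow_id"].tolist()
        terms = [
            distinct(animals[:12], start=10**6, end=2 * 10**6 + 500_000),  # class 1-2? 1.5Mb
            distinct(animals[5:20], start=10**6, end=6 * 10**6),  # 5 Mb -> class 4-6
        ]
        res = fit_trait_class_models(
            ph, froh_table(animals, rng.uniform(0, 0.08, 40)), terms,
            config=AssocConfig(traits=("milk_305d",), min_carriers=5),
            G=np.eye(40), grm_animal_ids=animals,
        )
        assert set(res["length_class"]) == {"1-2", "4-6"}
        assert res["p_bh"].notna().all()
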