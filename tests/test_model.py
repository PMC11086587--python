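from itertools import combinations

import numpy as np
import pytest
import statsmodels.api as sm

import formtypic as ft
from formtypic.model import (TypicalityConfig, best_subsets, cv_select,
                             fit_robust, screen_predictors, typicality_scores)


def naive_best_subsets(X, y, kmax):
    """Enumeration oracle: OLS with intercept via lstsq for every subset."""
    n, p = X.shape
    out = {}
    for k in range(1, kmax + 1):
        best = None
        for idx in combinations(range(p), k):
            A = np.column_stack([np.ones(n), X[:, list(idx)]])
            resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            rss = float(resid @ resid)
            if best is None or rss < best[0]:
                best = (rss, idx)
        out[k] = best
    return out


class TestScreenPredictors:
    def test_constant_column_dropped(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 2] = 7.0
        rep = screen_predictors(X, ["a", "b", "c", "d"])
        assert rep.dropped_zero_variance == ["c"]
        assert rep.kept_columns == ["a", "b", "d"]

    def test_linear_combo_dropped(self, rng):
        X = rng.normal(size=(40, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        rep = screen_predictors(X)
        assert rep.dropped_linear_combo == ["x2"]  # earlier columns preferred
        assert rep.kept_columns == ["x0", "x1"]
        kept = X[:, rep.kept_indices]
        assert np.linalg.matrix_rank(kept) == kept.shape[1]

    def test_full_rank_keeps_all_matches_rank_oracle(self, rng):
        for _ in range(10):
            n, p = 50, 8
            X = rng.normal(size=(n, p))
            rep = screen_predictors(X)
            # oracle: rank via SVD of [1 | X]
            oracle_rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
            assert len(rep.kept_columns) == oracle_rank - 1
            assert rep.kept_columns == [f"x{j}" for j in range(p)]

    def test_intercept_redundancy_resolved(self, rng):
        # three indicators summing to one: exactly one must fall
        g = rng.integers(0, 3, size=60)
        X = np.column_stack([(g == k).astype(float) for k in range(3)]
                            + [rng.normal(size=60)])
        rep = screen_predictors(X)
        assert len(rep.dropped_linear_combo) == 1
        assert rep.dropped_linear_combo == ["x2"]

    def test_all_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            screen_predictors(np.ones((10, 3)))

    def test_missing_values_raise(self, rng):
        X = rng.normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            screen_predictors(X)


class TestBestSubsets:
    def test_matches_enumeration_oracle_p3(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ [1.0, -2.0, 0.0] + rng.normal(size=50)
        cands = best_subsets(X, y, kmax=3)
        oracle = naive_best_subsets(X, y, 3)
        for cand in cands:
            rss_o, idx_o = oracle[cand.size]
            assert cand.rss == pytest.approx(rss_o, rel=1e-9)
            assert cand.columns == tuple(f"x{j}" for j in idx_o)
            assert cand.exact

    def test_full_model_rss_equals_ols(self, rng):
        n, p = 60, 5
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        cands = best_subsets(X, y, kmax=p)
        A = np.column_stack([np.ones(n), X])
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert cands[-1].rss == pytest.approx(float(resid @ resid), rel=1e-9)
        assert cands[-1].size == p

    def test_orthonormal_design_picks_largest_correlations(self, rng):
        # centred-orthonormal columns: size-k winner = top-k |corr with y|
        n, p = 80, 6
        M = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        y = rng.normal(size=n)
        scores = np.abs(Q.T @ (y - y.mean()))
        order = np.argsort(-scores)
        cands = best_subsets(Q, y, kmax=4)
        for cand in cands:
            assert set(cand.columns) == {f"x{j}" for j in order[:cand.size]}

    def test_rss_non_increasing_in_k(self, rng):
        X = rng.normal(size=(100, 10))
        y = rng.normal(size=100)
        cands = best_subsets(X, y, kmax=10)
        rsss = [c.rss for c in cands]
        assert all(a >= b - 1e-9 for a, b in zip(rsss, rsss[1:]))

    def test_hybrid_flagged_not_exact(self, rng):
        X = rng.normal(size=(100, 20))
        y = rng.normal(size=100)
        cands = best_subsets(X, y, kmax=5, exact_limit=10)
        assert all(not c.exact for c in cands)

    def test_hybrid_close_to_exact_on_small_p(self, rng):
        # forward/backward hybrid should match enumeration on easy signals
        X = rng.normal(size=(200, 8))
        y = X @ [3, 0, 0, 2, 0, 0, 0, -2.5] + rng.normal(size=200)
        hybrid = best_subsets(X, y, kmax=4, exact_limit=2)
        oracle = naive_best_subsets(X, y, 4)
        assert set(hybrid[2].columns) == {f"x{j}" for j in oracle[3][1]}

    def test_kmax_validation(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            best_subsets(X, y, kmax=0)
        with pytest.raises(ValueError):
            best_subsets(X[:3], y[:3], kmax=3)


class TestCvSelect:
    def test_single_candidate_chosen(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        cands = best_subsets(X, y, kmax=1)
        sel = cv_select(X, y, cands, folds=5, repeats=3, seed=1)
        assert sel.chosen == cands[0]

    def test_same_seed_identical(self, rng):
        X = rng.normal(size=(80, 6))
        y = X[:, 0] + rng.normal(size=80)
        cands = best_subsets(X, y, kmax=4)
        a = cv_select(X, y, cands, folds=5, repeats=5, seed=7)
        b = cv_select(X, y, cands, folds=5, repeats=5, seed=7)
        assert a.chosen == b.chosen
        assert a.cv_rmse_by_size == b.cv_rmse_by_size

    def test_different_seed_differs_somewhere(self, rng):
        X = rng.normal(size=(80, 6))
        y = X[:, 0] + rng.normal(size=80)
        cands = best_subsets(X, y, kmax=3)
        a = cv_select(X, y, cands, folds=5, repeats=5, seed=1)
        b = cv_select(X, y, cands, folds=5, repeats=5, seed=2)
        assert a.cv_rmse_by_size != b.cv_rmse_by_size

    def test_chosen_no_worse_than_full_model(self, rng):
        X = rng.normal(size=(120, 8))
        y = X[:, 0] - X[:, 3] + rng.normal(size=120)
        cands = best_subsets(X, y, kmax=8)
        sel = cv_select(X, y, cands, folds=10, repeats=10, seed=3)
        full_rmse = sel.cv_rmse_by_size[8][0]
        chosen_rmse = sel.cv_rmse_by_size[sel.chosen.size][0]
        assert chosen_rmse <= full_rmse + 1e-12

    def test_too_few_rows_raises(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        cands = best_subsets(X, y, kmax=2)
        with pytest.raises(ValueError):
            cv_select(X, y, cands, folds=10, repeats=1, seed=0)


class TestFitRobust:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        model = fit_robust(x[:, None], 2.0 * x, ["x"])
        assert model.beta == pytest.approx([0.0, 2.0], abs=1e-10)
        assert model.robust_se == pytest.approx([0.0, 0.0], abs=1e-8)
        assert model.adjusted_r2 == pytest.approx(1.0, abs=1e-12)

    def test_small_fixed_dataset_hand_oracle(self):
        # n=8, p=2: closed-form normal equations + explicit HC0 sandwich
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 2.0],
                      [5.0, 7.0], [6.0, 1.0], [7.0, 4.0], [8.0, 9.0]])
        y = np.array([1.2, 0.8, 3.1, 2.2, 5.3, 2.9, 4.4, 7.5])
        model = fit_robust(X, y, ["x1", "x2"], hc_flavor="HC0")

        A = np.column_stack([np.ones(8), X])
        beta_hand = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta_hand
        bread = np.linalg.inv(A.T @ A)
        meat = sum(resid[i] ** 2 * np.outer(A[i], A[i]) for i in range(8))
        cov_hand = bread @ meat @ bread
        assert model.beta == pytest.approx(beta_hand, rel=1e-10)
        assert model.robust_se == pytest.approx(np.sqrt(np.diag(cov_hand)),
                                                rel=1e-10)

    @pytest.mark.parametrize("flavor", ["HC0", "HC1", "HC2", "HC3"])
    def test_matches_statsmodels(self, rng, flavor):
        n = 200
        X = rng.normal(size=(n, 3))
        y = X @ [1.0, 0.5, -0.3] + rng.normal(size=n) * (1 + np.abs(X[:, 0]))
        model = fit_robust(X, y, hc_flavor=flavor)
        smf = sm.OLS(y, sm.add_constant(X)).fit(cov_type=flavor)
        assert model.beta == pytest.approx(smf.params, rel=1e-9)
        assert model.robust_se == pytest.approx(smf.bse, rel=1e-9)
        assert model.r2 == pytest.approx(smf.rsquared, rel=1e-9)
        assert model.adjusted_r2 == pytest.approx(smf.rsquared_adj, rel=1e-9)

    def test_t_and_df(self, rng):
        n = 50
        X = rng.normal(size=(n, 2))
        y = X[:, 0] + rng.normal(size=n)
        model = fit_robust(X, y)
        assert model.df_resid == n - 3
        ok = model.robust_se > 0
        assert model.t[ok] == pytest.approx(model.beta[ok] / model.robust_se[ok])
        assert np.all((model.p[ok] >= 0) & (model.p[ok] <= 1))
        assert model.adjusted_r2 <= model.r2

    def test_rank_deficiency_raises(self, rng):
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            fit_robust(X, rng.normal(size=30))

    def test_too_few_rows_raises(self, rng):
        with pytest.raises(ValueError):
            fit_robust(rng.normal(size=(3, 3)), rng.normal(size=3))

    def test_homoscedastic_hc_close_to_classical(self, rng):
        n = 5000
        X = rng.normal(size=(n, 2))
        y = X @ [1.0, -1.0] + rng.normal(size=n)
        model = fit_robust(X, y, hc_flavor="HC2")
        classical = sm.OLS(y, sm.add_constant(X)).fit()
        ratio = model.robust_se / classical.bse
        assert np.all(np.abs(ratio - 1) < 0.10)

    def test_planted_coefficients_covered(self, rng):
        hits = total = 0
        beta_true = np.array([0.5, -1.0, 2.0])
        for _ in range(150):
            X = rng.normal(size=(150, 2))
            y = beta_true[0] + X @ beta_true[1:] + rng.normal(size=150)
            m = fit_robust(X, y)
            for j in range(3):
                total += 1
                hits += abs(m.beta[j] - beta_true[j]) <= 2 * m.robust_se[j]
        assert 0.90 <= hits / total <= 0.99


class TestTypicalityScores:
    def test_mean_zero_sd_one(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 0] + rng.normal(size=100)
        model = fit_robust(X[:, :2], y, ["x0", "x1"])
        sc = typicality_scores(model, X, ["x0", "x1", "x2"])
        assert abs(sc.z.mean()) < 1e-10
        assert abs(sc.z.std(ddof=1) - 1) < 1e-10

    def test_identical_rows_identical_scores(self, rng):
        X = rng.normal(size=(50, 2))
        X[1] = X[0]
        y = X[:, 0] + rng.normal(size=50)
        model = fit_robust(X, y, ["a", "b"])
        sc = typicality_scores(model, X, ["a", "b"])
        assert sc.z[0] == sc.z[1]

    def test_rescaling_invariance_with_refit(self, rng):
        X = rng.normal(size=(80, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=80)
        names = ["a", "b", "c"]
        sc1 = typicality_scores(fit_robust(X, y, names), X, names)
        X2 = X.copy()
        X2[:, 1] *= 37.5
        sc2 = typicality_scores(fit_robust(X2, y, names), X2, names)
        assert sc1.z == pytest.approx(sc2.z, abs=1e-8)

    def test_monotone_in_fitted(self, rng):
        X = rng.normal(size=(60, 2))
        y = X[:, 0] + rng.normal(size=60)
        model = fit_robust(X, y, ["a", "b"])
        sc = typicality_scores(model, X, ["a", "b"])
        order_f = np.argsort(sc.fitted)
        order_z = np.argsort(sc.z)
        assert np.array_equal(order_f, order_z)

    def test_zero_variance_raises(self, rng):
        X = rng.normal(size=(20, 1))
        y = rng.normal(size=20)
        model = fit_robust(X, y, ["a"])
        model.beta[1] = 0.0  # force constant fitted values
        with pytest.raises(ValueError, match="zero variance"):
            typicality_scores(model, X, ["a"])


@pytest.fixture(scope="module")
def planted():
    cfg = ft.GeneratorConfig(
        n_words=800, seed=11, raters_per_word=40, rater_sd=0.8,
        planted_beta={"valence": {"n_manner_fricative": -0.6,
                                  "n_height_open": 0.4}},
        target_r2={"valence": 0.25})
    return ft.plant_affect(ft.generate_lexicon(cfg), cfg)


class TestRunTypicality:
    def test_reproducible_given_seed(self, planted, inventory):
        cfg = TypicalityConfig(repeats=2, kmax=5, seed=4)
        r1 = ft.run_typicality(planted, inventory, "valence", cfg)
        r2 = ft.run_typicality(planted, inventory, "valence", cfg)
        assert r1.selection.chosen == r2.selection.chosen
        assert np.array_equal(r1.scores.z, r2.scores.z)
        assert r1.model.beta == pytest.approx(r2.model.beta, abs=0)

    def test_model_table_layout(self, planted, inventory):
        run = ft.run_typicality(planted, inventory, "valence",
                                TypicalityConfig(repeats=2, kmax=5, seed=4))
        table = run.model.table()
        assert table[0]["term"] == "(Intercept)"
        assert set(table[0]) == {"term", "estimate", "std_error", "t", "p"}
        assert run.manifest["n_form_variables"] == 83

    def test_unknown_dv_raises(self, planted, inventory):
        with pytest.raises(ValueError, match="unknown dv"):
            ft.run_typicality(planted, inventory, "happiness")
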