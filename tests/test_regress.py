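"""Selection + OLS + cross-validation engine."""

import numpy as np
import pandas as pd
import pytest

from lncreg.regress import (ClassModelOptions, cross_validated_r2,
                            draw_control_pool, model_class, ols_fit,
                            residualize_by_model, select_predictors)


def _frame(X, prefix="c"):
    return pd.DataFrame(X, index=[f"{prefix}{i}" for i in range(X.shape[0])])


class TestSelectPredictors:
    def test_few_candidates_pass_through(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.standard_normal((5, 50)))
        y = rng.standard_normal(50)
        assert select_predictors(y, X, k_target=10) == list(X.index)

    def test_exclusion_removes_target(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.standard_normal((5, 50)))
        y = rng.standard_normal(50)
        sel = select_predictors(y, X, k_target=10, exclude={"c2"})
        assert "c2" not in sel

    def test_planted_predictor_always_selected(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _frame(rng.standard_normal((50, 400)))
            y = 2 * X.loc["c3"].to_numpy() + 0.2 * rng.standard_normal(400)
            assert "c3" in select_predictors(y, X)

    def test_null_selection_near_target_size(self):
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = _frame(rng.standard_normal((50, 400)))
            sizes.append(len(select_predictors(rng.standard_normal(400), X)))
        assert max(sizes) <= 12 and min(sizes) >= 8  # support path granularity

    def test_matches_sklearn_path_support(self):
        from sklearn.linear_model import enet_path
        from lncreg._enet import enet_alpha_grid, enet_support_path
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 30))
        beta = np.zeros(30)
        beta[[2, 9, 17]] = [1.0, -0.7, 0.5]
        y = X @ beta + rng.standard_normal(120) * 0.5
        alphas, coefs = enet_support_path(X, y, tol=1e-8, n_alphas=60)
        _, ref, _ = enet_path(X, y, l1_ratio=0.5, alphas=alphas,
                              tol=1e-10, max_iter=10_000)
        assert np.abs(coefs - ref).max() < 1e-5
        assert ((coefs != 0) == (ref != 0)).all()

    def test_degenerate_inputs(self):
        X = _frame(np.random.default_rng(0).standard_normal((3, 20)))
        with pytest.raises(ValueError, match="zero-variance"):
            select_predictors(np.ones(20), X)
        with pytest.raises(ValueError, match="empty"):
            select_predictors(np.random.default_rng(0).standard_normal(20),
                              X.iloc[0:0])


class TestOlsFit:
    def test_identity_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        fit = ols_fit(x, _frame(x[None, :]))
        assert fit.coefficients[0] == pytest.approx(1.0)
        assert fit.overall_r2 == pytest.approx(1.0)
        assert fit.coef_pvalues[0] < 1e-12

    def test_orthogonal_predictor(self):
        y = np.array([1.0, 1, -1, -1])
        x = np.array([1.0, -1, 1, -1])
        fit = ols_fit(y, _frame(x[None, :]))
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.overall_r2 == pytest.approx(0.0, abs=1e-12)

    def test_four_point_hand_least_squares(self):
        # y = (1,2,3,5), x = (0,1,2,3): slope 1.3, intercept 0.8,
        # R^2 = (1.3^2 * 5) / 8.75
        fit = ols_fit(np.array([1.0, 2, 3, 5]),
                      _frame(np.array([[0.0, 1, 2, 3]])))
        assert fit.coefficients[0] == pytest.approx(1.3)
        assert fit.intercept == pytest.approx(0.8)
        assert fit.overall_r2 == pytest.approx(1.3**2 * 5 / 8.75)

    def test_pvalues_match_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 4))
        y = X @ [0.5, 0, -0.3, 0.1] + rng.standard_normal(80)
        fit = ols_fit(y, _frame(X.T))
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.coefficients, ref.params[1:])
        assert np.allclose(fit.coef_pvalues, ref.pvalues[1:], atol=1e-12)
        assert fit.overall_r2 == pytest.approx(ref.rsquared)

    def test_duplicate_dropped_and_rank_deficiency_raises(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        dup = _frame(np.vstack([x, x]))
        fit = ols_fit(x + rng.standard_normal(30), dup)
        assert len(fit.predictor_ids) == 1
        z = rng.standard_normal(30)
        collinear = _frame(np.vstack([x, z, x + z]))
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(rng.standard_normal(30), collinear)

    def test_too_few_samples(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="n > p"):
            ols_fit(rng.standard_normal(4), _frame(rng.standard_normal((4, 4))))


class TestCrossValidation:
    def test_noiseless_signal_recovered_in_every_fold(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.standard_normal((5, 60)))
        y = 1.5 * X.loc["c2"].to_numpy()
        cv = cross_validated_r2(y, X, k_target=10, seed=0)
        assert all(r > 0.999 for r in cv.fold_test_r2)
        assert cv.test_pcc > 0.999

    def test_null_target_has_no_skill(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = _frame(rng.standard_normal((50, 500)))
            cv = cross_validated_r2(rng.standard_normal(500), X, seed=seed)
            vals.append(cv.mean_test_r2)
        assert np.mean(vals) < 0.05
        assert min(vals) < 0.0  # negative test R^2 preserved

    def test_selection_ignores_held_out_samples(self):
        # corrupting the held-out block must not change in-fold selection
        rng = np.random.default_rng(2)
        X = _frame(rng.standard_normal((30, 100)))
        y = X.loc["c5"].to_numpy() + 0.5 * rng.standard_normal(100)
        cv1 = cross_validated_r2(y, X, seed=3)
        from lncreg.regress import _fold_indices
        folds = _fold_indices(100, 5, 3)
        y2 = y.copy()
        y2[folds[0]] += 100.0  # wreck fold 0's held-out values
        cv2 = cross_validated_r2(y2, X, seed=3)
        assert cv1.fold_selected[0] == cv2.fold_selected[0]

    def test_fold_means_and_partition(self):
        from lncreg.regress import _fold_indices
        folds = _fold_indices(23, 5, 0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(23))
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1


class TestResidualizeByModel:
    def test_perfect_fit_flagged_constant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        X = _frame(x[None, :])
        fit = ols_fit(2 * x + 1, X)
        resid, const = residualize_by_model(2 * x + 1, fit, X)
        assert const and np.allclose(resid, 0)

    def test_empty_predictor_set_centers(self):
        y = np.array([1.0, 2, 3, 4])
        fit = ols_fit(y, _frame(np.empty((0, 4))))
        resid, const = residualize_by_model(y, fit, _frame(np.empty((0, 4))))
        assert not const
        centered = y - y.mean()
        assert np.allclose(resid, centered / centered.std())

    def test_two_layer_variance_recovery(self):
        """y = TF + lnc + noise: after TF residualization the lncRNA CV R^2
        approaches the lncRNA's share of the residual variance."""
        shares = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            tf = rng.standard_normal(n)
            lnc = rng.standard_normal(n)
            y = tf + lnc + rng.standard_normal(n)
            Xtf = _frame(tf[None, :], "tf")
            fit = ols_fit(y, Xtf)
            resid, _ = residualize_by_model(y, fit, Xtf)
            cv = cross_validated_r2(resid, _frame(lnc[None, :], "lnc"),
                                    seed=seed)
            shares.append(cv.mean_test_r2)
        assert np.mean(shares) == pytest.approx(0.5, abs=0.1)


class TestModelClass:
    def test_single_candidate_gives_single_predictor(self, small_expr):
        E = small_expr.values
        genes = list(E.index)
        res, table = model_class([genes[0]], {genes[0]: [genes[1]]}, E)
        fit, cv = res[genes[0]]
        assert fit.predictor_ids == [genes[1]]

    def test_target_with_no_candidates_recorded_unmodeled(self, small_expr):
        E = small_expr.values
        g = list(E.index)[0]
        res, table = model_class([g], {g: []}, E)
        assert g not in res
        assert (table["status"] == "unmodeled").any()

    def test_control_pool_draw_is_seeded_and_sized(self):
        pool = [f"e{i}" for i in range(50)]
        a = draw_control_pool(pool, 20, seed=5)
        b = draw_control_pool(pool, 20, seed=5)
        c = draw_control_pool(pool, 20, seed=6)
        assert a == b and len(a) == 20 and a != c
        with pytest.raises(ValueError):
            draw_control_pool(pool, 51, seed=0)
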