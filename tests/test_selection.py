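"""Random-forest selection, LOOCV, GLM panel and ROC contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ebcpanel.selection import (
    RFConfig,
    _forest,
    default_mtry_grid,
    fit_panel_glm,
    loocv_accuracy,
    loocv_subset_eval,
    oob_permutation_importance,
    rfe_select,
    roc_analysis,
    run_panel_discovery,
    tune_mtry,
)
from tests.conftest import gaussian_panel_data


class TestTuneMtry:
    def test_single_feature_forced(self):
        X, y = gaussian_panel_data(0, n_per_group=8, n_features=1, n_planted=1)
        assert tune_mtry(X.to_numpy(), y, RFConfig(n_trees=20, seed=0)) == 1

    def test_tie_returns_smallest(self):
        # two identical perfectly separating columns: every mtry behaves
        # the same, so CV accuracies tie exactly
        x = np.r_[np.zeros(8), np.ones(8)]
        X = np.c_[x, x]
        y = np.array(["a"] * 8 + ["b"] * 8)
        cfg = RFConfig(n_trees=20, seed=1, mtry_grid=(1, 2))
        assert tune_mtry(X, y, cfg) == 1

    def test_predictive_feature_high_cv_accuracy(self):
        accs = []
        for seed in range(5):
            X, y = gaussian_panel_data(seed, n_per_group=10, n_features=6,
                                      n_planted=1, effect=6.0)
            cfg = RFConfig(n_trees=50, seed=seed)
            m = tune_mtry(X.to_numpy(), y, cfg)
            acc, _ = loocv_accuracy(X.to_numpy(), y, cfg, mtry=m)
            accs.append(acc)
        assert np.mean(accs) >= 0.9

    def test_single_class_rejected(self):
        X, _ = gaussian_panel_data(0, n_per_group=5, n_features=2)
        with pytest.raises(ValueError):
            tune_mtry(X.to_numpy(), np.array(["a"] * 10), RFConfig(n_trees=10))

    def test_default_grid(self):
        assert default_mtry_grid(1) == (1,)
        assert default_mtry_grid(9) == (1, 3, 9)
        assert default_mtry_grid(128) == (1, 11, 42, 128)


class TestPermutationImportance:
    def test_constant_feature_importance_exactly_zero(self):
        X, y = gaussian_panel_data(0, n_per_group=10, n_features=4, n_planted=1)
        X["hsa-miR-0003"] = 1.0
        clf = _forest(50, 2, seed=0).fit(X.to_numpy(), y)
        imp = oob_permutation_importance(clf, X.to_numpy(), y, seed=0)
        assert imp[3] == 0.0

    def test_label_defining_feature_positive_every_seed(self):
        for seed in range(10):
            X, y = gaussian_panel_data(seed, n_per_group=10, n_features=4,
                                      n_planted=1, effect=8.0)
            clf = _forest(50, 2, seed=seed).fit(X.to_numpy(), y)
            imp = oob_permutation_importance(clf, X.to_numpy(), y, seed=seed)
            assert imp[0] > 0

    def test_pure_noise_importance_centered_at_zero(self):
        imps = []
        for seed in range(20):
            X, y = gaussian_panel_data(seed, n_per_group=10, n_features=3,
                                      n_planted=0)
            clf = _forest(50, 1, seed=seed).fit(X.to_numpy(), y)
            imps.append(oob_permutation_importance(clf, X.to_numpy(), y, seed=seed))
        imps = np.array(imps)
        assert abs(imps.mean()) < 2 * imps.std()


class TestRFE:
    def test_three_features_noop(self):
        X, y = gaussian_panel_data(0, n_per_group=8, n_features=3)
        trace = rfe_select(X, y, RFConfig(n_trees=20, seed=0))
        assert trace.iterations == []
        assert trace.selected == list(X.columns)

    def test_trace_structure_and_no_reappearance(self):
        X, y = gaussian_panel_data(1, n_per_group=10, n_features=8, n_planted=2,
                                  effect=3.0)
        trace = rfe_select(X, y, RFConfig(n_trees=30, cv_folds=3, seed=1))
        assert len(trace.iterations) == 8 - 3
        gone: set[str] = set()
        for it in trace.iterations:
            assert not gone & set(it.features)
            assert it.eliminated in it.features
            assert it.importance[it.eliminated] == it.importance.min()
            gone.add(it.eliminated)
        assert len(trace.selected) == 3

    def test_deterministic_given_seed(self):
        X, y = gaussian_panel_data(2, n_per_group=8, n_features=6, n_planted=1)
        cfg = RFConfig(n_trees=30, cv_folds=3, seed=5)
        a = rfe_select(X, y, cfg)
        b = rfe_select(X, y, cfg)
        assert a.selected == b.selected
        for ia, ib in zip(a.iterations, b.iterations):
            pd.testing.assert_series_equal(ia.importance, ib.importance)

    def test_too_few_features_rejected(self):
        X, y = gaussian_panel_data(0, n_per_group=8, n_features=2)
        with pytest.raises(ValueError):
            rfe_select(X, y, RFConfig(n_trees=10))

    def test_importance_tie_drops_lexicographically_last(self):
        # all-constant features: no tree can split, every importance is
        # exactly 0, so the full tie resolves to the last id
        X, y = gaussian_panel_data(3, n_per_group=8, n_features=5, n_planted=0)
        X.loc[:, :] = 1.0
        trace = rfe_select(X, y, RFConfig(n_trees=20, cv_folds=3, seed=0), target_k=4)
        assert trace.iterations[0].eliminated == "hsa-miR-0004"


class TestLOOCV:
    def test_seven_subsets(self):
        X, y = gaussian_panel_data(0, n_per_group=6, n_features=3, effect=3.0)
        ev = loocv_subset_eval(X, y, list(X.columns), RFConfig(n_trees=20, seed=0))
        assert len(ev.results) == 7
        sizes = sorted(len(k) for k in ev.results)
        assert sizes == [1, 1, 1, 2, 2, 2, 3]
        assert all(0 <= v["accuracy"] <= 1 for v in ev.results.values())
        assert all(len(v["probabilities"]) == len(y) for v in ev.results.values())

    def test_perfectly_separable_full_trio_accuracy_one(self):
        X, y = gaussian_panel_data(1, n_per_group=8, n_features=3, n_planted=3,
                                  effect=20.0)
        ev = loocv_subset_eval(X, y, list(X.columns), RFConfig(n_trees=30, seed=1))
        full = tuple(sorted(X.columns))
        assert ev.results[full]["accuracy"] == 1.0
        assert ev.best_subset == full or ev.results[ev.best_subset]["accuracy"] == 1.0

    def test_null_labels_accuracy_near_half(self):
        accs = []
        for seed in range(20):
            X, y = gaussian_panel_data(seed, n_per_group=8, n_features=3,
                                      n_planted=0)
            acc, _ = loocv_accuracy(
                X.to_numpy(), y, RFConfig(n_trees=25, seed=seed)
            )
            accs.append(acc)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.15)

    def test_held_out_sample_never_trains_its_fold(self):
        X, y = gaussian_panel_data(2, n_per_group=6, n_features=3, effect=2.0)
        cfg = RFConfig(n_trees=20, seed=9)
        Xmod = X.copy()
        Xmod.iloc[0] = 99.0  # poison the held-out sample's features
        _, probs = loocv_accuracy(Xmod.to_numpy(), y, cfg)
        # rebuild fold 0's model externally: trained without sample 0,
        # seeded identically -> must give the same held-out probability
        m = max(1, int(np.sqrt(3)))
        clf = _forest(20, m, seed=cfg.seed + 0).fit(Xmod.to_numpy()[1:], y[1:])
        pos = np.where(clf.classes_ == np.unique(y)[-1])[0][0]
        expected = clf.predict_proba(Xmod.to_numpy()[:1])[0][pos]
        assert probs[0] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self):
        X, y = gaussian_panel_data(0, n_per_group=6, n_features=3)
        with pytest.raises(ValueError):
            loocv_subset_eval(X.iloc[:3], y[:3], list(X.columns),
                              RFConfig(n_trees=10))


class TestPanelGLM:
    def test_symmetric_data_zero_intercept(self):
        x = np.r_[-np.arange(1, 11.0), np.arange(1, 11.0)]
        y = np.array(["a"] * 10 + ["b"] * 10)
        pm = fit_panel_glm(pd.DataFrame({"f": x}), y)
        assert abs(pm.coef["intercept"]) < 1e-6

    def test_coefficients_match_independent_optimizer(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        eta = 0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = np.where(rng.random(20) < 1 / (1 + np.exp(-eta)), "b", "a")
        if len(np.unique(y)) < 2:  # pragma: no cover - seed chosen to avoid
            pytest.skip("degenerate draw")
        pm = fit_panel_glm(pd.DataFrame(X, columns=["f1", "f2"]), y)
        assert not pm.separation

        yb = (y == "b").astype(float)
        D = np.c_[np.ones(20), X]

        def nll(beta):
            eta = D @ beta
            return float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - yb * eta))

        res = optimize.minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(pm.coef.to_numpy(), res.x, atol=1e-6)

    def test_perfect_separation_flagged_finite(self):
        x = np.r_[np.zeros(8), np.ones(8) * 5]
        y = np.array(["a"] * 8 + ["b"] * 8)
        pm = fit_panel_glm(pd.DataFrame({"f": x}), y)
        assert pm.separation
        assert np.isfinite(pm.coef.to_numpy()).all()
        assert ((pm.fitted_probabilities > 0) & (pm.fitted_probabilities < 1)).all()

    def test_nonfinite_features_rejected(self):
        X = pd.DataFrame({"f": [0.0, np.nan, 1.0, 2.0]})
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            fit_panel_glm(X, y)


def rank_auc(scores, labels):
    """Exhaustive pair-counting oracle: (concordant + ties/2) / (n1*n0)."""
    pos = scores[labels == np.unique(labels)[-1]]
    neg = scores[labels != np.unique(labels)[-1]]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_auc_one(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array(["a", "a", "b", "b"])
        assert roc_analysis(s, y).auc == pytest.approx(1.0)

    def test_all_ties_auc_half(self):
        s = np.ones(6)
        y = np.array(["a"] * 3 + ["b"] * 3)
        assert roc_analysis(s, y).auc == pytest.approx(0.5)

    def test_worked_example_matches_pair_counting(self):
        s = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array(["a", "a", "b", "b"])
        roc = roc_analysis(s, y)
        assert roc.auc == pytest.approx(rank_auc(s, y), abs=1e-12)

    def test_trapezoid_equals_rank_statistic_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            s = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = np.where(rng.random(n) < 0.5, "a", "b")
            if len(np.unique(y)) < 2:
                continue
            roc = roc_analysis(s, y)
            ref = rank_auc(-s if roc.flipped else s, y)
            assert roc.auc == pytest.approx(ref, abs=1e-12)

    def test_monotone_curve_and_orientation(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=30)
        y = np.where(rng.random(30) < 0.5, "a", "b")
        roc = roc_analysis(s, y)
        assert roc.auc >= 0.5
        assert np.all(np.diff(roc.sensitivity) >= -1e-12)
        assert np.all(np.diff(roc.specificity) <= 1e-12)
        j = roc.youden_sensitivity + roc.youden_specificity - 1
        assert j == pytest.approx(np.max(roc.sensitivity + roc.specificity - 1))

    def test_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        for _ in range(50):
            s = rng.normal(size=25)
            y = np.where(rng.random(25) < 0.5, 0, 1)
            if len(np.unique(y)) < 2:
                continue
            roc = roc_analysis(s, y)
            ref = roc_auc_score(y, -s if roc.flipped else s)
            assert roc.auc == pytest.approx(ref, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(4.0), np.array(["a"] * 4))


class TestRunPanelDiscovery:
    def _inputs(self, seed=0):
        X, y = gaussian_panel_data(seed, n_per_group=10, n_features=10,
                                  n_planted=3, effect=2.5)
        expr = X.T  # features x samples
        expr.columns = [f"s{j}" for j in range(len(y))]
        meta = pd.DataFrame({"sample_id": expr.columns, "cancer":
                             np.where(y == "case", "cancer", "healthy")})
        return expr, meta

    def test_report_structure_and_determinism(self):
        expr, meta = self._inputs()
        cfg = RFConfig(n_trees=25, cv_folds=3, seed=3)
        a = run_panel_discovery(expr, meta, "cancer", cfg)
        b = run_panel_discovery(expr, meta, "cancer", cfg)
        assert a.summary() == b.summary()
        assert len(a.trace.selected) == 3
        assert len(a.subset_eval.results) == 7
        assert set(a.roc_individual) == set(a.trace.selected)
        assert a.case == "healthy" or a.case in ("cancer",)  # two levels present

    def test_contrast_with_missing_levels_rejected(self):
        expr, meta = self._inputs()
        meta["cancer"] = "cancer"
        with pytest.raises(ValueError):
            run_panel_discovery(expr, meta, "cancer", RFConfig(n_trees=10))

    def test_small_level_rejected(self):
        expr, meta = self._inputs()
        meta.loc[3:, "cancer"] = "cancer"
        with pytest.raises(ValueError, match="< 4 samples"):
            run_panel_discovery(expr, meta, "cancer", RFConfig(n_trees=10))
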