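"""Screening stage: assembly, scaling, RFE, tuning, evaluation, SHAP."""

import numpy as np
import pandas as pd
import pytest

from aplscreen import screen
from aplscreen.quant import FEATURE_NAMES
from aplscreen.synthgram import (ROUTINE_PARAM_NAMES, ConfigurationError,
                                 ValidationError)
from conftest import make_tabular_cohort


def oracle_auc(scores, labels):
    """O(n^2) concordant-pair AUC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def tables():
    scatter, routine = make_tabular_cohort(
        {"APL": 20, "AML": 15, "ALL": 10, "HC": 15}, seed=3)
    return scatter, routine


class TestAssemble:
    def test_rfc_s_has_70_columns(self, tables):
        table = screen.assemble_features(*tables, mode="rfc-s")
        assert table.X.shape[1] == 70
        assert list(table.X.columns[:20]) == list(FEATURE_NAMES)

    def test_rfc_c_has_50_columns(self, tables):
        _, routine = tables
        table = screen.assemble_features(None, routine, mode="rfc-c")
        assert table.X.shape[1] == 50
        assert list(table.X.columns) == list(ROUTINE_PARAM_NAMES)

    def test_duplicate_sample_dropped_with_warning(self, tables):
        scatter, routine = tables
        dup = pd.concat([routine, routine.iloc[[0]]], ignore_index=True)
        with pytest.warns(UserWarning, match="duplicate"):
            table = screen.assemble_features(None, dup, mode="rfc-c")
        assert len(table.X) == len(routine)

    def test_nonfinite_rows_dropped(self, tables):
        _, routine = tables
        bad = routine.copy()
        bad.loc[0, "PLT"] = np.nan
        with pytest.warns(UserWarning, match="non-finite"):
            table = screen.assemble_features(None, bad, mode="rfc-c")
        assert len(table.X) == len(routine) - 1

    def test_id_mismatch_rejected(self, tables):
        scatter, routine = tables
        other = scatter.copy()
        other["sample_id"] = "x-" + other["sample_id"]
        with pytest.raises(ValidationError):
            screen.assemble_features(other, routine, mode="rfc-s")


class TestStandardize:
    def test_train_columns_zscored(self, tables):
        table = screen.assemble_features(*tables, mode="rfc-s")
        (z,), params = screen.standardize(table)
        mu = z.X.to_numpy().mean(axis=0)
        sd = z.X.to_numpy().std(axis=0)
        assert np.abs(mu).max() < 1e-9
        assert np.abs(sd[sd > 0] - 1).max() < 1e-9

    def test_closed_form_transfer(self):
        # train = {0, 2} -> mean 1, sd 1; test value 4 scales to 3.0
        rng = np.random.default_rng(1)
        cols = list(ROUTINE_PARAM_NAMES)
        Xtr = pd.DataFrame(rng.random((2, 50)), columns=cols, index=["a", "b"])
        Xtr["PLT"] = [0.0, 2.0]
        Xte = pd.DataFrame(rng.random((1, 50)), columns=cols, index=["c"])
        Xte["PLT"] = 4.0
        tr = screen.FeatureTable(Xtr, np.array([0, 1]), "rfc-c")
        te = screen.FeatureTable(Xte, np.array([1]), "rfc-c")
        (_, zte), _ = screen.standardize(tr, te)
        assert zte.X.loc["c", "PLT"] == pytest.approx(3.0)

    def test_scaler_ignores_other_tables(self, tables):
        table = screen.assemble_features(*tables, mode="rfc-s")
        idx = np.arange(len(table.y))
        train, test = table.subset(idx[:60]), table.subset(idx[60:])
        (_, _), p1 = screen.standardize(train, test)
        perturbed = screen.FeatureTable(test.X * 100 + 3, test.y, test.mode,
                                        test.class_names)
        (_, _), p2 = screen.standardize(train, perturbed)
        np.testing.assert_array_equal(p1.mean, p2.mean)
        np.testing.assert_array_equal(p1.sd, p2.sd)

    def test_degenerate_column_guard(self):
        X = pd.DataFrame({n: np.random.default_rng(0).random(10)
                          for n in ROUTINE_PARAM_NAMES})
        X["PLT"] = 5.0
        X.index = [f"s{i}" for i in range(10)]
        table = screen.FeatureTable(X, np.array([0, 1] * 5), "rfc-c")
        (z,), params = screen.standardize(table)
        assert params.sd[list(X.columns).index("PLT")] == 1.0
        assert (z.X["PLT"] == 0).all()


class TestRfe:
    def test_plateau_rule_on_handcrafted_curve(self):
        curve = screen.RfeCurve(
            counts=np.array([5, 4, 3, 2, 1]),
            scores=np.array([0.99, 0.99, 0.988, 0.95, 0.90]),
            elimination_order=["a", "b", "c", "d"],
            feature_names=["a", "b", "c", "d", "e"], tol=0.003)
        assert curve.selected_count == 3

    def test_curve_covers_every_width_and_keeps_separator(self):
        rng = np.random.default_rng(4)
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.standard_normal((n, 10)),
                         columns=[f"noise{i}" for i in range(10)])
        X["signal"] = y * 2.0 + rng.normal(0, 0.01, n)
        X.index = [f"s{i}" for i in range(n)]
        cols = list(ROUTINE_PARAM_NAMES)[:39]
        for c in cols:
            X[c] = rng.standard_normal(n)
        table = screen.FeatureTable(X, y, "rfc-c")
        curve = screen.rfe_cv(table, "rfc", folds=5, seed=0,
                              hyperparams={"n_estimators": 60})
        assert len(curve.counts) == 50
        for k in curve.counts:
            assert "signal" in curve.features_at(int(k))
        assert curve.scores[-1] >= 0.999      # separator alone: CV AUC ~ 1

    def test_determinism(self, tables):
        table = screen.assemble_features(None, tables[1], mode="rfc-c")
        (z,), _ = screen.standardize(table)
        kw = dict(folds=3, seed=5, hyperparams={"n_estimators": 30})
        c1 = screen.rfe_cv(z, "rfc", **kw)
        c2 = screen.rfe_cv(z, "rfc", **kw)
        np.testing.assert_array_equal(c1.scores, c2.scores)
        assert c1.elimination_order == c2.elimination_order

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((6, 50)),
                         columns=list(ROUTINE_PARAM_NAMES),
                         index=[f"s{i}" for i in range(6)])
        table = screen.FeatureTable(X, np.array([1, 0, 0, 0, 0, 0]), "rfc-c")
        with pytest.raises(ValidationError):
            screen.rfe_cv(table, "rfc", folds=5)


class TestGridSearch:
    def _table(self):
        scatter, routine = make_tabular_cohort({"APL": 15, "HC": 15}, seed=9)
        table = screen.assemble_features(scatter, routine, mode="rfc-s")
        (z,), _ = screen.standardize(table)
        return z

    def test_singleton_grid(self):
        z = self._table()
        best, scores = screen.grid_search(z, "rfc", [{"n_estimators": 20}],
                                          folds=3, seed=0)
        assert best == {"n_estimators": 20}
        assert len(scores) == 1

    def test_argmax_matches_explicit_loop(self):
        z = self._table()
        grid = [{"n_estimators": 10}, {"n_estimators": 40}]
        best, scores = screen.grid_search(z, "rfc", grid, folds=3, seed=1)
        loops = [screen._cv_auc("rfc", z.X.to_numpy(), z.y, 3, 1, g)
                 for g in grid]
        assert scores == pytest.approx(loops)
        assert best == grid[int(np.argmax(loops))]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            screen.grid_search(self._table(), "rfc", [], folds=3, seed=0)


class TestThreshold:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        t = screen.tune_threshold(scores, labels, 0.95)
        assert t == 0.8
        assert (scores >= t).astype(int).tolist() == [1, 1, 0, 0]

    def test_hand_enumerated_cuts(self):
        scores = np.array([0.9, 0.8, 0.4, 0.5, 0.3])
        labels = np.array([1, 1, 1, 0, 0])
        assert screen.tune_threshold(scores, labels, 0.95) == 0.4

    def test_zero_floor_maximizes_specificity(self):
        scores = np.array([0.9, 0.8, 0.4, 0.5, 0.3])
        labels = np.array([1, 1, 1, 0, 0])
        t = screen.tune_threshold(scores, labels, 0.0)
        pred = scores >= t
        spec = ((~pred) & (labels == 0)).sum() / 2
        assert spec == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            screen.tune_threshold(np.array([0.1]), np.array([0]))


class TestEvaluate:
    def test_confusion_identities_closed_form(self):
        rep = screen.EvaluationReport.from_confusion(9, 1, 1, 89, auc=0.99)
        assert rep.accuracy == pytest.approx(0.980)
        assert rep.sensitivity == pytest.approx(0.900)
        assert rep.specificity == pytest.approx(89 / 90)
        assert rep.ppv == pytest.approx(0.900)
        assert rep.npv == pytest.approx(89 / 90)

    def test_constant_scores_give_half_auc(self):
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_auc_equals_pair_counting(self):
        rng = np.random.default_rng(0)
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(10, 100))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)   # force ties
            assert roc_auc_score(y, s) == pytest.approx(
                oracle_auc(s, y), abs=1e-12)


class TestShap:
    def _fit(self, n=60, seed=0, trees=40):
        scatter, routine = make_tabular_cohort({"APL": n // 2, "HC": n // 2},
                                               seed=seed)
        table = screen.assemble_features(scatter, routine, mode="rfc-s")
        (z,), params = screen.standardize(table)
        bundle = screen.train_classifier(
            z, z.feature_names, params, seed=seed,
            hyperparams={"n_estimators": trees})
        return z, bundle

    def test_local_accuracy(self):
        z, bundle = self._fit()
        attr = screen.shap_explain(bundle, z, standardized=True)
        proba = bundle.model.predict_proba(z.X.to_numpy())[:, 1]
        np.testing.assert_allclose(attr.base_value + attr.values.sum(axis=1),
                                   proba, atol=1e-6)

    def test_unused_constant_feature_gets_zero(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((40, 50)),
                         columns=list(ROUTINE_PARAM_NAMES),
                         index=[f"s{i}" for i in range(40)])
        X["PLT"] = 0.0
        y = (X["WBC"] > 0).astype(int).to_numpy()
        table = screen.FeatureTable(X, y, "rfc-c")
        params = screen.ScalerParams(np.zeros(50), np.ones(50),
                                     list(X.columns))
        bundle = screen.train_classifier(table, list(X.columns), params,
                                         hyperparams={"n_estimators": 20})
        attr = screen.shap_explain(bundle, table, standardized=True)
        j = list(X.columns).index("PLT")
        assert np.abs(attr.values[:, j]).max() == 0.0

    def test_depth_one_tree_matches_hand_shapley(self):
        """One split on one feature: phi_j = leaf value - cover-weighted
        mean; all other attributions vanish."""
        from sklearn.ensemble import RandomForestClassifier

        X = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        y = np.array([0, 0, 1, 1])
        rf = RandomForestClassifier(n_estimators=1, max_depth=1,
                                    bootstrap=False, random_state=0)
        rf.fit(X, y)
        from aplscreen import treeshap

        phi, base = treeshap.forest_shap(rf, X)
        proba = rf.predict_proba(X)[:, 1]
        np.testing.assert_allclose(base + phi.sum(axis=1), proba, atol=1e-12)
        np.testing.assert_allclose(phi[:, 1], 0.0, atol=1e-12)
        # hand Shapley for the single-feature game: v({1}) - v({})
        np.testing.assert_allclose(phi[:, 0], proba - base, atol=1e-12)

    def test_non_forest_rejected(self):
        z, bundle = self._fit(n=20, trees=5)
        bundle = screen.ModelBundle("lr", {}, object(), bundle.selected_features,
                                    bundle.scaler, 0.5, 0, "rfc-s")
        with pytest.raises(ConfigurationError):
            screen.shap_explain(bundle, z, standardized=True)


class TestCompare:
    def _separable(self, n=60):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({
            "f0": y * 10.0 + rng.normal(0, 0.01, n),
            "f1": rng.standard_normal(n)})
        for c in list(ROUTINE_PARAM_NAMES)[:48]:
            X[c] = rng.standard_normal(n)
        X.index = [f"s{i}" for i in range(n)]
        # margin check: the fixture is linearly separable on f0 alone
        assert X.loc[y == 1, "f0"].min() > X.loc[y == 0, "f0"].max()
        return screen.FeatureTable(X, y, "rfc-c")

    def test_five_families_reach_full_auc_on_separable_fixture(self):
        table = self._separable()
        curves = screen.compare_classifiers(
            table, seed=0, folds=3,
            hyperparams={"rfc": {"n_estimators": 100},
                         "adaboost": {"n_estimators": 30}})
        assert set(curves) == {"lr", "svm", "lda", "rfc", "adaboost"}
        for name, curve in curves.items():
            assert curve.scores[0] == pytest.approx(1.0), name

    def test_shared_seed_determinism(self):
        table = self._separable(20)
        kw = dict(seed=2, folds=2, estimators=("lr", "rfc"),
                  hyperparams={"rfc": {"n_estimators": 10}})
        c1 = screen.compare_classifiers(table, **kw)
        c2 = screen.compare_classifiers(table, **kw)
        for name in c1:
            np.testing.assert_array_equal(c1[name].scores, c2[name].scores)


class TestGroupCorrelation:
    def test_indicator_parameter_and_shape(self, tables):
        scatter, routine = tables
        labels = routine["class"]
        sc = scatter.copy()
        sc["N-APL-Ratio-YZ"] = (labels == "APL").astype(float).to_numpy()
        corr = screen.group_correlation(sc, labels)
        assert corr.shape == (20, 4)
        assert corr.loc["N-APL-Ratio-YZ", "APL"] == pytest.approx(1.0)
        assert (corr.loc["N-APL-Ratio-YZ",
                         [c for c in corr.columns if c != "APL"]] < 0).all()

    def test_label_independent_parameter_near_zero(self):
        scatter, routine = make_tabular_cohort({"APL": 60, "HC": 60}, seed=13)
        rng = np.random.default_rng(0)
        sc = scatter.copy()
        sc["D-Neu-Area-XY"] = rng.standard_normal(len(sc))
        corr = screen.group_correlation(sc, routine["class"])
        assert abs(corr.loc["D-Neu-Area-XY", "APL"]) < 3 / np.sqrt(len(sc))

    def test_zero_variance_parameter_warns(self, tables):
        scatter, routine = tables
        sc = scatter.copy()
        sc["D-APL-Ratio-YZ"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = screen.group_correlation(sc, routine["class"])
        assert (corr.loc["D-APL-Ratio-YZ"] == 0).all()


class TestModelResults:
    def test_fit_produces_summary_and_reports(self, tables):
        scatter, routine = tables
        model = screen.ScreeningModel.from_dataframe(
            routine, scatter, mode="rfc-s",
            config=screen.ScreenConfig(mode="rfc-s", folds=3, rfe_trees=30,
                                       grid={"n_estimators": [30]}))
        res = model.fit(seed=0)
        text = res.summary()
        assert "RFC-S" in text and "threshold" in text
        assert res.bundle.hyperparams["n_estimators"] == 30
        assert 0 < res.bundle.threshold < 1
        assert res.rfe_curve is not None
        assert set(res.bundle.selected_features) <= set(model.table.feature_names)

    def test_default_tree_counts_by_mode(self, tables):
        scatter, routine = tables
        t_s = screen.assemble_features(scatter, routine, "rfc-s")
        t_c = screen.assemble_features(None, routine, "rfc-c")
        (z_s,), p_s = screen.standardize(t_s)
        (z_c,), p_c = screen.standardize(t_c)
        b_s = screen.train_classifier(z_s, z_s.feature_names, p_s, seed=0)
        b_c = screen.train_classifier(z_c, z_c.feature_names, p_c, seed=0)
        assert b_s.hyperparams["n_estimators"] == 300
        assert b_c.hyperparams["n_estimators"] == 150
        assert b_s.hyperparams["class_weight"] == "balanced_subsample"

    def test_repeat_training_gives_identical_scores(self, tables):
        scatter, routine = tables
        t = screen.assemble_features(scatter, routine, "rfc-s")
        (z,), p = screen.standardize(t)
        s1 = screen.train_classifier(z, z.feature_names, p, seed=3,
                                     hyperparams={"n_estimators": 50}
                                     ).scores(z, standardized=True)
        s2 = screen.train_classifier(z, z.feature_names, p, seed=3,
                                     hyperparams={"n_estimators": 50}
                                     ).scores(z, standardized=True)
        np.testing.assert_array_equal(s1, s2)

    def test_stratified_split_is_deterministic_and_proportional(self):
        y = np.array([1] * 20 + [0] * 80)
        tr1, te1 = screen.stratified_split(y, 0.2, seed=4)
        tr2, te2 = screen.stratified_split(y, 0.2, seed=4)
        np.testing.assert_array_equal(te1, te2)
        assert len(te1) == 20
        assert y[te1].sum() == 4
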