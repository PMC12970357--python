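import numpy as np
import pandas as pd
import pytest

from wmhpheno import progression
from wmhpheno.progression import (PredictorSetBuilder, annualised_change,
                                  balanced_accuracy, compare_groups, evaluate,
                                  label_progression, mcnemar_compare,
                                  residualize, train_classifier)
from wmhpheno.regions import REGION_COLUMNS

SMALL_GRID = {"n_estimators": (50,), "max_depth": (2,)}


def pair_table(v0, v1, interval, icv=1.5e6):
    region = {c: 0.0 for c in REGION_COLUMNS}
    region[REGION_COLUMNS[0]] = 1.0
    rows = []
    for i, (a, b, t) in enumerate(zip(v0, v1, interval)):
        for tp, vol, iv in ((0, a, 0.0), (1, b, t)):
            rows.append({"participant_id": f"P{i}", "timepoint": tp,
                         "total_wmh_mm3": vol, "icv_mm3": icv,
                         "interval_years": iv,
                         **{k: v * vol for k, v in region.items()}})
    return pd.DataFrame(rows)


class TestAnnualisedChange:
    def test_reference_icv_identity(self):
        table = pair_table([1000.0], [1600.0], [2.0])
        out = annualised_change(table, 1.5e6)
        assert out["annualised_mm3_per_year"][0] == pytest.approx(300.0)

    def test_identical_volumes_zero(self):
        table = pair_table([1200.0], [1200.0], [1.5])
        out = annualised_change(table, 1.5e6)
        assert out["annualised_mm3_per_year"][0] == 0.0

    def test_icv_twice_reference_halves_change(self):
        table = pair_table([1000.0], [1500.0], [1.0], icv=3.0e6)
        out = annualised_change(table, 1.5e6)
        assert out["annualised_mm3_per_year"][0] == pytest.approx(250.0)

    def test_window_excludes_and_earliest_kept(self):
        table = pair_table([1000.0, 1000.0], [2000.0, 2000.0], [0.5, 2.0])
        out = annualised_change(table, 1.5e6, interval_window=(1.0, 7.0))
        assert out["participant_id"].tolist() == ["P1"]
        # multiple follow-ups: earliest in window wins
        extra = pair_table([1000.0], [9000.0], [4.0])
        extra = pd.concat([table[table.participant_id == "P1"],
                           extra[extra.timepoint == 1]
                           .assign(participant_id="P1")])
        out2 = annualised_change(extra, 1.5e6)
        assert out2["interval_years"][0] == 2.0


class TestLabelProgression:
    def test_strict_threshold_rule(self):
        changes = pd.DataFrame({
            "participant_id": list("abcde"),
            "annualised_mm3_per_year": [-50.0, 100.0, 250.0, 251.0, 600.0],
            "interval_years": [1.0] * 5})
        out = label_progression(changes)
        assert out["progressor"].tolist() == [False, False, False, True, True]
        assert out["progressor"].sum() == 2


class TestResidualize:
    def _df(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "age": rng.normal(66, 8, n),
            "sex": rng.choice(["male", "female"], n),
            "v": rng.normal(size=n)})

    def test_uncorrelated_variable_roughly_centred(self):
        df = self._df()
        resid = residualize(df, "v")
        assert abs(resid.mean()) < 1e-10
        assert np.corrcoef(resid, df["v"])[0, 1] > 0.95

    def test_exact_linear_function_residuals_zero(self):
        df = self._df(seed=1)
        df["v"] = 2.0 * df["age"]
        resid = residualize(df, "v")
        assert np.allclose(resid, 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self):
        df = self._df(seed=2)
        df["v"] = df["v"] + 0.1 * df["age"]
        resid = residualize(df, "v")
        assert abs(np.dot(resid, df["age"])) < 1e-6

    def test_constant_covariate_rejected(self):
        df = self._df(seed=3)
        df["age"] = 66.0
        with pytest.raises(ValueError, match="constant"):
            residualize(df, "v")


class TestCompareGroups:
    def test_chi_squared_hand_computed(self):
        # 2x2 table (20,10 / 10,20): Pearson chi2 = 20/3, p ~ 0.0098
        df = pd.DataFrame({
            "age": np.random.default_rng(0).normal(66, 8, 60),
            "sex": ["male", "female"] * 30,
            "cat": ["yes"] * 30 + ["no"] * 30})
        group = np.array([True] * 20 + [False] * 10
                         + [True] * 10 + [False] * 20)
        out = compare_groups(df, pd.Series(group), categorical=["cat"])
        row = out.iloc[0]
        assert row["statistic"] == pytest.approx(20 / 3, rel=1e-9)
        assert row["p"] == pytest.approx(0.009823, abs=2e-5)

    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=100)
        df = pd.DataFrame({"age": rng.normal(66, 8, 200),
                           "sex": rng.choice(["male", "female"], 200),
                           "v": np.concatenate([v, v])})
        group = np.array([True] * 100 + [False] * 100)
        out = compare_groups(df, pd.Series(group), continuous=["v"])
        assert out.iloc[0]["p"] > 0.8

    def test_disjoint_supports_minimal_p(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        n = 8
        df = pd.DataFrame({"age": rng.normal(0, 1e-6, 2 * n),
                           "sex": ["male"] * n + ["female"] * n,
                           "v": np.r_[np.zeros(n), np.ones(n) * 100]})
        group = np.array([False] * n + [True] * n)
        out = compare_groups(df, pd.Series(group), continuous=["v"])
        # oracle: exact minimal two-sided U p-value for these group sizes
        ref = mannwhitneyu(np.arange(n), np.arange(n) + 100,
                           alternative="two-sided", method="exact").pvalue
        assert out.iloc[0]["p"] <= ref * 1.5

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"age": [1.0], "sex": ["male"], "v": [0.0]})
        with pytest.raises(ValueError, match="nonempty"):
            compare_groups(df, pd.Series([True]), continuous=["v"])

    def test_low_expected_count_flagged(self):
        df = pd.DataFrame({"age": np.arange(12, dtype=float),
                           "sex": ["male", "female"] * 6,
                           "cat": ["yes"] * 2 + ["no"] * 10})
        group = pd.Series([True, False] * 6)
        out = compare_groups(df, group, categorical=["cat"])
        assert out.iloc[0]["flag"] == "low-expected-count"


class TestPredictorSets:
    def _train(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.dirichlet(np.ones(36), n) * 2000,
                          columns=list(REGION_COLUMNS))
        df["total_wmh_mm3"] = df[list(REGION_COLUMNS)].sum(axis=1)
        df["icv_mm3"] = 1.5e6
        df["age"] = rng.normal(66, 8, n)
        df["sex"] = rng.choice(["male", "female"], n)
        df["sbp"] = rng.normal(135, 18, n)
        return df

    def test_pcv_retains_minimal_components(self):
        # variance concentrated in 2 of 36 dims -> exactly 2 PCs pass 80%
        rng = np.random.default_rng(1)
        df = self._train()
        vals = np.zeros((len(df), 36))
        vals[:, 0] = rng.normal(0, 100, len(df))
        vals[:, 1] = rng.normal(0, 60, len(df))
        vals[:, 2:] = rng.normal(0, 1, (len(df), 34))
        df[list(REGION_COLUMNS)] = np.abs(vals)
        builder = PredictorSetBuilder(feature_matrix_fn=None).fit(df)
        assert builder.n_components_ == 2

    def test_cluster_and_distance_column_counts(self, blob_data):
        from wmhpheno.engines import fit

        df = self._train()
        _, props_keep = None, None
        X36 = df[list(REGION_COLUMNS)].to_numpy()
        X36 = X36 / X36.sum(axis=1, keepdims=True)
        model = fit("kmeans", X36, 5, seed=0)

        def feature_fn(frame):
            V = frame[list(REGION_COLUMNS)].to_numpy()
            return V / V.sum(axis=1, keepdims=True), np.ones(len(frame), bool)

        builder = PredictorSetBuilder(feature_matrix_fn=feature_fn,
                                      model=model).fit(df)
        assert builder.transform(df, "distance").shape[1] == 5
        clusters = builder.transform(df, "clusters")
        assert clusters.shape[1] == 5
        assert np.allclose(clusters.sum(axis=1), 1.0)

    def test_composite_set_concatenates(self):
        df = self._train()
        builder = PredictorSetBuilder(feature_matrix_fn=None).fit(df)
        rf = builder.transform(df, "RF")
        wmhv = builder.transform(df, "WMHV")
        combo = builder.transform(df, "RF+WMHV")
        assert list(combo.columns) == list(rf.columns) + list(wmhv.columns)

    def test_unknown_set_rejected(self):
        df = self._train()
        builder = PredictorSetBuilder(feature_matrix_fn=None).fit(df)
        with pytest.raises(ValueError, match="unknown predictor set"):
            builder.transform(df, "RWMHV+bogus")


class TestClassifier:
    def separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2 == 0
        X = rng.normal(0, 0.1, (n, 3))
        X[y, 0] += 10.0
        return X, y

    def test_separable_cv_balanced_accuracy_one(self):
        X, y = self.separable()
        _, _, cv = train_classifier(X, y, seed=1, grid=SMALL_GRID)
        assert cv == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        scores = []
        for rep in range(5):
            X = rng.normal(size=(80, 4))
            y = rng.random(80) < 0.5
            _, _, cv = train_classifier(X, y, seed=rep, grid=SMALL_GRID)
            scores.append(cv)
        assert abs(np.mean(scores) - 0.5) < 0.08

    def test_same_seed_same_hyperparameters(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(70, 3))
        y = rng.random(70) < 0.4
        grid = {"n_estimators": (50, 100), "max_depth": (2, 3)}
        _, p1, c1 = train_classifier(X, y, seed=4, grid=grid)
        _, p2, c2 = train_classifier(X, y, seed=4, grid=grid)
        assert p1 == p2 and c1 == c2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(np.zeros((10, 2)), np.ones(10, bool))


class TestEvaluation:
    def test_balanced_accuracy_formula(self):
        # confusion TP=40 FN=10 TN=30 FP=20 -> (0.8 + 0.6)/2 = 0.7
        y_true = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        y_pred = np.r_[np.ones(40, bool), np.zeros(10, bool),
                       np.ones(20, bool), np.zeros(30, bool)]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.7)

    def test_matches_sklearn(self):
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(0)
        y = rng.random(200) < 0.3
        p = rng.random(200) < 0.5
        assert balanced_accuracy(y, p) == pytest.approx(
            balanced_accuracy_score(y, p))

    def test_perfect_predictions_ci_collapses(self):
        class Perfect:
            def predict(self, X):
                return X[:, 0] > 0

        X = np.r_[np.ones((20, 1)), -np.ones((20, 1))]
        y = X[:, 0] > 0
        out = evaluate(Perfect(), X, y, n_boot=100, seed=0)
        assert out["balanced_accuracy"] == 1.0
        assert out["ci_low"] == 1.0 and out["ci_high"] == 1.0

    def test_absent_class_named(self):
        class Dummy:
            def predict(self, X):
                return np.zeros(len(X), bool)

        with pytest.raises(ValueError, match="progressor"):
            evaluate(Dummy(), np.zeros((5, 1)), np.zeros(5, bool))

    def test_prevalence_invariance_in_expectation(self):
        # resample a fixed test set at two prevalences: balanced accuracy of
        # a fixed rule stays put because sensitivity/specificity do
        rng = np.random.default_rng(1)
        n = 4000
        y = rng.random(n) < 0.5
        pred = np.where(rng.random(n) < 0.8, y, ~y)  # 80% accurate per class

        def at_prevalence(p, seed):
            r = np.random.default_rng(seed)
            pos = np.flatnonzero(y)
            neg = np.flatnonzero(~y)
            take_pos = r.choice(pos, int(2000 * p))
            take_neg = r.choice(neg, 2000 - int(2000 * p))
            idx = np.r_[take_pos, take_neg]
            return balanced_accuracy(y[idx], pred[idx])

        b1 = np.mean([at_prevalence(0.2, s) for s in range(20)])
        b2 = np.mean([at_prevalence(0.7, s) for s in range(20)])
        assert abs(b1 - b2) < 0.02


class TestPredictorOrdering:
    def test_regional_volumes_beat_total_volume_on_average(self):
        # seeded tendency over 10 replicates, not a per-replicate assertion
        from wmhpheno.progression import build_predictor_sets

        gains = []
        for seed in range(10):
            spec = synthetic_cohort(seed)
            table = _longitudinal(spec)
            changes = annualised_change(table, spec.icv_mean_mm3)
            labelled = label_progression(changes)
            base = table[table["timepoint"] == 0].set_index("participant_id")
            rows = base.loc[labelled["participant_id"]].reset_index()
            y = labelled["progressor"].to_numpy()
            builder, sets = build_predictor_sets(rows, ["WMHV", "RWMHV"],
                                                 feature_matrix_fn=None)
            scores = {}
            for name in ("WMHV", "RWMHV"):
                _, _, cv = train_classifier(sets[name].to_numpy(), y,
                                            seed=seed, grid=SMALL_GRID)
                scores[name] = cv
            gains.append(scores["RWMHV"] - scores["WMHV"])
        assert np.mean(gains) >= 0


def synthetic_cohort(seed):
    from wmhpheno import synthetic

    spec = synthetic.default_cohort_spec(n_participants=350, seed=seed)
    spec.followup_fraction = 1.0
    return spec


def _longitudinal(spec):
    from wmhpheno import synthetic

    return synthetic.generate_longitudinal(
        synthetic.generate_cross_sectional(spec), spec)


class TestMcNemar:
    def test_symmetric_discordance_large_p(self):
        y = np.zeros(40, bool)
        a = y.copy()
        b = y.copy()
        a[:10] = True  # A wrong on 10, B wrong on a different 10
        b[10:20] = True
        out = mcnemar_compare(a, b, y)
        assert out["b"] == 10 and out["c"] == 10
        assert out["p"] > 0.5

    def test_one_sided_dominance_small_p(self):
        y = np.zeros(100, bool)
        a = y.copy()  # A always right
        b = y.copy()
        b[:30] = True  # B wrong 30 times
        out = mcnemar_compare(a, b, y)
        assert out["p"] < 1e-5
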