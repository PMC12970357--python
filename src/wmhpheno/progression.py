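"""Longitudinal progression: labelling, group comparison, prediction.

Annualised change in total lesion volume (on the reference-ICV scale)
dichotomises participants at 250 mm^3/year into progressors and
non-progressors. Group comparisons use Mann-Whitney U on age/sex
residualised continuous variables and chi-squared on categorical tables.
Prediction uses a gradient-boosted tree classifier over configurable
predictor sets with train-fitted transforms (PCA retaining > 80% variance),
inverse class weighting, balanced accuracy, percentile-bootstrap CIs and
McNemar paired comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import bh_adjust, centroid_distances
from .regions import REGION_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "annualised_change",
    "label_progression",
    "residualize",
    "compare_groups",
    "PredictorSetBuilder",
    "build_predictor_sets",
    "train_classifier",
    "balanced_accuracy",
    "evaluate",
    "mcnemar_compare",
    "predict_progression",
    "PredictionReport",
]

PROGRESSION_THRESHOLD = 250.0  # mm^3/year on the reference-ICV scale
HYPERPARAM_GRID = {"n_estimators": (50, 100, 200), "max_depth": (2, 3, 4, 5)}


def annualised_change(table: pd.DataFrame, reference_icv_mm3: float,
                      interval_window: tuple[float, float] = (1.0, 7.0)
                      ) -> pd.DataFrame:
    """Per-participant annualised total-volume change, reference-ICV scale.

    Both timepoints are normalised by the participant's baseline ICV and
    rescaled by the reference ICV before differencing; change is divided by
    the follow-up interval. Participants without a follow-up inside the
    interval window are dropped; with several eligible follow-ups the
    earliest is used.
    """
    lo, hi = interval_window
    base = table[table["timepoint"] == 0].set_index("participant_id")
    follow = table[(table["timepoint"] > 0)
                   & (table["interval_years"] >= lo)
                   & (table["interval_years"] <= hi)]
    follow = (follow.sort_values("interval_years")
              .drop_duplicates("participant_id", keep="first")
              .set_index("participant_id"))
    ids = base.index.intersection(follow.index)

    rows = []
    for pid in ids:
        b, f = base.loc[pid], follow.loc[pid]
        interval = float(f["interval_years"])
        if interval <= 0:
            raise ValueError(f"non-positive interval for {pid}")
        icv = float(b["icv_mm3"])
        scale = reference_icv_mm3 / icv
        change = (float(f["total_wmh_mm3"]) - float(b["total_wmh_mm3"])) * scale
        rows.append({"participant_id": pid,
                     "annualised_mm3_per_year": change / interval,
                     "interval_years": interval})
    return pd.DataFrame(rows, columns=["participant_id",
                                       "annualised_mm3_per_year",
                                       "interval_years"])


def label_progression(changes: pd.DataFrame,
                      threshold: float = PROGRESSION_THRESHOLD) -> pd.DataFrame:
    """Strictly-greater-than threshold rule; boundary cases do not progress."""
    out = changes.copy()
    out["progressor"] = out["annualised_mm3_per_year"] > threshold
    return out


def residualize(df: pd.DataFrame, variable: str,
                covariates=("age", "sex")) -> pd.Series:
    """OLS residuals of a continuous variable on covariates (complete cases)."""
    work = df[[variable, *covariates]].dropna()
    parts = []
    for cov in covariates:
        col = work[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True,
                                     dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(cov))
    Xd = sm.add_constant(pd.concat(parts, axis=1))
    if any(Xd[c].nunique() == 1 for c in Xd.columns if c != "const"):
        raise ValueError("constant covariate in residualisation")
    res = sm.OLS(work[variable].astype(float).to_numpy(), Xd).fit()
    return pd.Series(res.resid, index=work.index, name=variable)


def compare_groups(df: pd.DataFrame, group: pd.Series, continuous=(),
                   categorical=(), covariates=("age", "sex")) -> pd.DataFrame:
    """Progressor vs non-progressor comparisons with one BH family.

    Continuous variables: Mann-Whitney U on age/sex residuals. Categorical:
    Pearson chi-squared (no continuity correction) on the raw contingency
    table; expected counts < 5 are flagged, not fatal.
    """
    g = np.asarray(group, dtype=bool)
    if g.all() or not g.any():
        raise ValueError("both groups must be nonempty")
    rows = []
    for var in continuous:
        resid = residualize(df, var, covariates=covariates)
        gv = g[df.index.get_indexer(resid.index)]
        u, p = stats.mannwhitneyu(resid[gv], resid[~gv],
                                  alternative="two-sided")
        rows.append({"variable": var, "test": "mannwhitney-u",
                     "statistic": float(u), "p": float(p), "flag": ""})
    for var in categorical:
        sub = df[[var]].dropna()
        tab = pd.crosstab(sub[var], g[df.index.get_indexer(sub.index)])
        chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(),
                                                        correction=False)
        flag = "low-expected-count" if (expected < 5).any() else ""
        rows.append({"variable": var, "test": "chi-squared",
                     "statistic": float(chi2), "p": float(p), "flag": flag})
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Predictor sets


@dataclass
class PredictorSetBuilder:
    """Train-fitted predictor-set construction (no test-set leakage).

    Atomic sets: RF (age, sex, systolic blood pressure), WMHV (total
    baseline volume), RWMHV (36 regional baseline volumes), distance
    (Euclidean distances to the k centroids), clusters (one-hot
    assignment), PCV (principal-component scores of RWMHV retaining > 80%
    cumulative variance). Composite names join atoms with '+'.
    """

    feature_matrix_fn: "callable"  # df -> (features ndarray, keep mask)
    model: "object | None" = None  # fitted ClusterModel for distance/clusters
    pca_variance: float = 0.80
    pca_mean_: np.ndarray | None = None
    pca_components_: np.ndarray | None = None
    n_components_: int | None = None
    fitted: bool = False
    rosters_: dict = field(default_factory=dict)

    def fit(self, train: pd.DataFrame) -> "PredictorSetBuilder":
        R = train[list(REGION_COLUMNS)].to_numpy(dtype=float)
        self.pca_mean_ = R.mean(axis=0)
        centred = R - self.pca_mean_
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        var = s**2
        ratio = np.cumsum(var) / var.sum()
        self.n_components_ = int(np.searchsorted(ratio, self.pca_variance) + 1)
        self.pca_components_ = vt[: self.n_components_]
        self.fitted = True
        return self

    def _atoms(self, df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        if not self.fitted:
            raise ValueError("builder is not fitted")
        idx = df.index
        atoms: dict[str, pd.DataFrame] = {}
        sex01 = (df["sex"].astype(str) == "female").astype(float)
        atoms["RF"] = pd.DataFrame({"age": df["age"].astype(float),
                                    "sex_female": sex01,
                                    "sbp": df["sbp"].astype(float)}, index=idx)
        atoms["WMHV"] = pd.DataFrame(
            {"total_wmh_mm3": df["total_wmh_mm3"].astype(float)}, index=idx)
        atoms["RWMHV"] = df[list(REGION_COLUMNS)].astype(float)
        R = atoms["RWMHV"].to_numpy()
        scores = (R - self.pca_mean_) @ self.pca_components_.T
        atoms["PCV"] = pd.DataFrame(
            scores, index=idx,
            columns=[f"pc{i + 1}" for i in range(self.n_components_)])
        if self.model is not None:
            feats, keep = self.feature_matrix_fn(df)
            if not keep.all():
                raise ValueError("zero-total rows present; filter before "
                                 "building predictor sets")
            from . import engines

            if self.model.subspace_V is not None:
                P = self.model.subspace_V[:, :self.model.subspace_m]
                dist = centroid_distances(feats @ P, self.model.centroids @ P)
            else:
                dist = centroid_distances(feats, self.model.centroids)
            atoms["distance"] = pd.DataFrame(
                dist, index=idx,
                columns=[f"dist_c{i + 1}" for i in range(self.model.k)])
            labels = engines.assign(self.model, feats)
            onehot = np.eye(self.model.k)[labels]
            atoms["clusters"] = pd.DataFrame(
                onehot, index=idx,
                columns=[f"cluster_{i + 1}" for i in range(self.model.k)])
        return atoms

    def transform(self, df: pd.DataFrame, set_name: str) -> pd.DataFrame:
        atoms = self._atoms(df)
        parts = []
        for atom in set_name.split("+"):
            atom = atom.strip()
            if atom not in atoms:
                raise ValueError(f"unknown predictor set {atom!r}; "
                                 f"available: {sorted(atoms)}")
            parts.append(atoms[atom])
        out = pd.concat(parts, axis=1)
        self.rosters_[set_name] = list(out.columns)
        return out


def build_predictor_sets(train: pd.DataFrame, set_names, feature_matrix_fn,
                         model=None, pca_variance: float = 0.80
                         ) -> tuple[PredictorSetBuilder, dict]:
    """Fit a builder on training rows and materialise the named sets."""
    builder = PredictorSetBuilder(feature_matrix_fn=feature_matrix_fn,
                                  model=model, pca_variance=pca_variance)
    builder.fit(train)
    sets = {name: builder.transform(train, name) for name in set_names}
    return builder, sets


# ---------------------------------------------------------------------------
# Classifier training and evaluation


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of sensitivity and specificity."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    pos = y_true.sum()
    neg = (~y_true).sum()
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    sens = (y_pred & y_true).sum() / pos
    spec = (~y_pred & ~y_true).sum() / neg
    return float((sens + spec) / 2)


def _inverse_class_weights(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=bool)
    n = len(y)
    w_pos = n / (2.0 * y.sum())
    w_neg = n / (2.0 * (~y).sum())
    return np.where(y, w_pos, w_neg)


def train_classifier(X, y, seed: int = 0, grid: dict | None = None,
                     n_folds: int = 5):
    """Gradient-boosted trees with 5-fold CV hyperparameter selection.

    Grid: n_estimators in {50,100,200} x max_depth in {2,3,4,5}. Inverse
    class weights are re-derived inside each training fold. The best
    configuration by mean CV balanced accuracy is refit on all rows.
    Returns ``(model, best_params, cv_score)``.
    """
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data contains a single class")
    grid = grid or HYPERPARAM_GRID

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = None
    for n_est in grid["n_estimators"]:
        for depth in grid["max_depth"]:
            scores = []
            for tr, va in folds:
                clf = GradientBoostingClassifier(
                    n_estimators=n_est, max_depth=depth, random_state=seed)
                clf.fit(X[tr], y[tr],
                        sample_weight=_inverse_class_weights(y[tr]))
                scores.append(balanced_accuracy(y[va], clf.predict(X[va])))
            mean_score = float(np.mean(scores))
            params = {"n_estimators": n_est, "max_depth": depth}
            if best is None or mean_score > best[0]:
                best = (mean_score, params)
    cv_score, best_params = best
    final = GradientBoostingClassifier(random_state=seed, **best_params)
    final.fit(X, y, sample_weight=_inverse_class_weights(y))
    return final, best_params, cv_score


def evaluate(model, X_test, y_test, n_boot: int = 1000, seed: int = 0
             ) -> dict:
    """Balanced accuracy on a test set with a percentile-bootstrap 95% CI."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=bool)
    for cls, present in (("progressor", y_test.any()),
                         ("non-progressor", (~y_test).any())):
        if not present:
            raise ValueError(f"class {cls!r} absent from the test set")
    y_pred = np.asarray(model.predict(X_test), dtype=bool)
    point = balanced_accuracy(y_test, y_pred)
    rng = np.random.default_rng(seed)
    n = len(y_test)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if y_test[idx].all() or not y_test[idx].any():
            continue  # degenerate resample: skip
        boots.append(balanced_accuracy(y_test[idx], y_pred[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"balanced_accuracy": point, "ci_low": float(lo),
            "ci_high": float(hi), "n_boot": len(boots)}


def mcnemar_compare(pred_a, pred_b, y_true) -> dict:
    """McNemar test (chi-squared with continuity correction) on the
    discordant pairs of two classifiers' correctness."""
    from statsmodels.stats.contingency_tables import mcnemar

    a_ok = np.asarray(pred_a, dtype=bool) == np.asarray(y_true, dtype=bool)
    b_ok = np.asarray(pred_b, dtype=bool) == np.asarray(y_true, dtype=bool)
    table = np.array([
        [(a_ok & b_ok).sum(), (a_ok & ~b_ok).sum()],
        [(~a_ok & b_ok).sum(), (~a_ok & ~b_ok).sum()],
    ])
    res = mcnemar(table, exact=False, correction=True)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "b": int(table[0, 1]), "c": int(table[1, 0])}


@dataclass
class PredictionReport:
    """Per-predictor-set performance with pairwise paired comparisons."""

    results: dict  # set name -> {cv_balanced_accuracy, test: {...}, params}
    mcnemar: pd.DataFrame  # columns: set_a, set_b, statistic, p, p_bh

    def to_dict(self) -> dict:
        return {"results": self.results,
                "mcnemar": self.mcnemar.to_dict(orient="records")}


def predict_progression(train: pd.DataFrame, test: pd.DataFrame,
                        y_train, y_test, set_names, feature_matrix_fn,
                        model=None, seed: int = 0, n_boot: int = 1000
                        ) -> PredictionReport:
    """Train and evaluate one classifier per predictor set.

    All transforms (PCA basis, distance model) are fitted on the training
    rows only; the test rows are transformed with train-derived parameters.
    """
    builder, train_sets = build_predictor_sets(train, set_names,
                                               feature_matrix_fn, model=model)
    results = {}
    predictions = {}
    for name in set_names:
        Xtr = train_sets[name].to_numpy()
        Xte = builder.transform(test, name).to_numpy()
        clf, params, cv = train_classifier(Xtr, y_train, seed=seed)
        results[name] = {
            "cv_balanced_accuracy": cv,
            "params": params,
            "roster": builder.rosters_[name],
            "test": evaluate(clf, Xte, y_test, n_boot=n_boot, seed=seed),
        }
        predictions[name] = np.asarray(clf.predict(Xte), dtype=bool)

    rows = []
    for a, b in combinations(set_names, 2):
        mc = mcnemar_compare(predictions[a], predictions[b], y_test)
        rows.append({"set_a": a, "set_b": b, **mc})
    mc_df = pd.DataFrame(rows)
    if len(mc_df):
        mc_df["p_bh"] = bh_adjust(mc_df["p"].to_numpy())
    return PredictionReport(results=results, mcnemar=mc_df)
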