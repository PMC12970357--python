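"""Cross-sectional risk-factor association via centroid proximity.

One ordinary-least-squares model per (risk factor, cluster): the outcome is
proximity (inverse Euclidean distance) of each participant to that
cluster's centroid in the clustering feature space, adjusted for age, sex
and baseline total lesion volume. Continuous predictors are min-max scaled
to [0,1] over complete cases; categorical predictors enter as indicators
against a stated reference level. P-values are Benjamini-Hochberg adjusted
over the whole run's family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "centroid_distances",
    "proximity",
    "fit_association",
    "fit_all_associations",
    "bh_adjust",
    "AssociationResult",
    "CATEGORICAL_REFERENCES",
]

#: Reference level per categorical factor (indicator = level vs reference).
CATEGORICAL_REFERENCES: dict[str, str | int] = {
    "sex": "male",
    "smoking": "never",
    "ethnicity": "white",
    "diabetes": "no",
    "hypertension": "no",
    "med_bp": "no",
    "med_chol": "no",
    "med_dm": "no",
    "apoe4": 0,
}

DEFAULT_COVARIATES = ("age", "sex", "total_wmh_mm3")
PROXIMITY_EPS = 1e-8


def centroid_distances(X, centroids) -> np.ndarray:
    """Euclidean distances (n, k) from rows of X to each centroid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if X.shape[1] != C.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: X has {X.shape[1]}, centroids have "
            f"{C.shape[1]}")
    return np.sqrt(((X[:, None, :] - C[None, :, :])**2).sum(axis=2))


def proximity(distances, eps: float = PROXIMITY_EPS) -> np.ndarray:
    """Inverse distance 1/(d + eps); rows at a centroid get the maximum
    finite value."""
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    return 1.0 / (d + eps)


@dataclass
class AssociationResult:
    cluster: int
    factor: str
    level: str | None  # None for continuous factors
    beta: float
    ci_low: float
    ci_high: float
    p: float
    p_bh: float | None
    n: int


def _minmax(series: pd.Series) -> pd.Series:
    lo, hi = series.min(), series.max()
    if hi == lo:
        raise ValueError(f"constant predictor {series.name!r}")
    return (series - lo) / (hi - lo)


def _encode(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Design columns for one variable; indicators vs reference if
    categorical, min-max scaled if continuous."""
    col = df[name]
    if name in CATEGORICAL_REFERENCES or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype):
        ref = CATEGORICAL_REFERENCES.get(name)
        levels = [lv for lv in pd.unique(col) if lv != ref]
        if ref is not None and ref not in set(pd.unique(col)):
            levels = list(pd.unique(col))[1:]  # fall back: first level as ref
        out = pd.DataFrame(index=df.index)
        for lv in sorted(map(str, levels)):
            out[f"{name}[{lv}]"] = (col.astype(str) == lv).astype(float)
        return out
    return pd.DataFrame({name: _minmax(col.astype(float))})


def fit_association(df: pd.DataFrame, risk_factor: str, proximity_values,
                    cluster: int = 0,
                    covariates=DEFAULT_COVARIATES) -> list[AssociationResult]:
    """OLS of centroid proximity on one risk factor plus covariates.

    Complete-case analysis over the model's variables. Returns one result
    per non-reference level for categorical factors, one for continuous.
    95% CIs use the t distribution on residual degrees of freedom.
    """
    needed = [risk_factor, *[c for c in covariates if c != risk_factor]]
    work = df[needed].copy()
    work["_y"] = np.asarray(proximity_values, dtype=float)
    work = work.dropna()
    design_parts = [_encode(work, risk_factor)]
    for cov in covariates:
        if cov != risk_factor:
            design_parts.append(_encode(work, cov))
    Xd = pd.concat(design_parts, axis=1)
    if len(work) < Xd.shape[1] + 2:
        raise ValueError(
            f"too few complete cases ({len(work)}) for {Xd.shape[1]} "
            "predictors")
    Xd = sm.add_constant(Xd)
    fitres = sm.OLS(work["_y"].to_numpy(), Xd).fit()
    conf = fitres.conf_int(alpha=0.05)

    results = []
    factor_cols = [c for c in Xd.columns
                   if c == risk_factor or c.startswith(f"{risk_factor}[")]
    for col in factor_cols:
        level = col[len(risk_factor) + 1:-1] if col.endswith("]") else None
        results.append(AssociationResult(
            cluster=cluster, factor=risk_factor, level=level,
            beta=float(fitres.params[col]),
            ci_low=float(conf.loc[col, 0]), ci_high=float(conf.loc[col, 1]),
            p=float(fitres.pvalues[col]), p_bh=None, n=int(len(work)),
        ))
    return results


def fit_all_associations(df: pd.DataFrame, X_features, centroids,
                         risk_factors, covariates=DEFAULT_COVARIATES
                         ) -> pd.DataFrame:
    """All (risk factor x cluster) models with one BH family per run.

    Returns a tidy frame: cluster, factor, level, beta, ci_low, ci_high, p,
    p_bh, n.
    """
    dist = centroid_distances(X_features, centroids)
    prox = proximity(dist)
    rows: list[AssociationResult] = []
    for c in range(dist.shape[1]):
        for rf in risk_factors:
            rows.extend(fit_association(df, rf, prox[:, c], cluster=c,
                                        covariates=covariates))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min over j >= i of p_(j) * m / j (with ranks over the sorted
    p-values), clipped at 1. Order-invariant: output aligns with the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
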