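"""Partitioning algorithms behind a uniform fit/assign contract.

Four built-in engines: k-means, mini-batch k-means, Gaussian mixture (all
delegated to scikit-learn) and subspace k-means, which jointly learns an
orthogonal transformation splitting feature space into a clustered subspace
and a noise subspace while partitioning the points. External engines
(e.g. neural clustering) can be registered through :func:`register_engine`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = ["ClusterModel", "fit", "fit_subkmeans", "assign", "register_engine",
           "ENGINES"]


@dataclass
class ClusterModel:
    """A fitted partition with a deterministic assignment rule."""

    algorithm: str
    k: int
    centroids: np.ndarray  # (k, d) in the transformed feature space
    subspace_V: np.ndarray | None = None  # orthogonal (d, d), subkmeans only
    subspace_m: int | None = None  # clustered-space dimension
    gmm_weights: np.ndarray | None = None
    gmm_means: np.ndarray | None = None
    gmm_covariances: np.ndarray | None = None
    seed: int | None = None
    iterations: int = 0
    objective: float = np.nan
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError(
                f"centroid count {self.centroids.shape[0]} != k {self.k}")
        if self.subspace_V is not None:
            V = np.asarray(self.subspace_V, dtype=float)
            d = V.shape[0]
            if not np.allclose(V.T @ V, np.eye(d), atol=1e-8):
                raise ValueError("subspace_V is not orthogonal")
            if not 1 <= int(self.subspace_m) <= d:
                raise ValueError(f"subspace_m {self.subspace_m} outside 1..{d}")
            self.subspace_V = V

    @property
    def d(self) -> int:
        return self.centroids.shape[1]

    def to_json(self, path=None) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        payload = {
            "algorithm": self.algorithm, "k": self.k,
            "centroids": arr(self.centroids),
            "subspace_V": arr(self.subspace_V), "subspace_m": self.subspace_m,
            "gmm_weights": arr(self.gmm_weights),
            "gmm_means": arr(self.gmm_means),
            "gmm_covariances": arr(self.gmm_covariances),
            "seed": self.seed, "iterations": self.iterations,
            "objective": None if np.isnan(self.objective) else self.objective,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClusterModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)

        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            algorithm=payload["algorithm"], k=payload["k"],
            centroids=arr(payload["centroids"]),
            subspace_V=arr(payload["subspace_V"]),
            subspace_m=payload["subspace_m"],
            gmm_weights=arr(payload["gmm_weights"]),
            gmm_means=arr(payload["gmm_means"]),
            gmm_covariances=arr(payload["gmm_covariances"]),
            seed=payload["seed"], iterations=payload["iterations"],
            objective=np.nan if payload["objective"] is None
            else payload["objective"],
            metadata=payload.get("metadata", {}),
        )


def _check_fit_inputs(X: np.ndarray, k: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > X.shape[0]:
        raise ValueError(f"k ({k}) exceeds number of rows ({X.shape[0]})")
    return X


def _fit_kmeans(X, k, seed, **hyper):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=hyper.pop("n_init", 10),
                random_state=seed, **hyper).fit(X)
    return ClusterModel(algorithm="kmeans", k=k, centroids=km.cluster_centers_,
                        seed=seed, iterations=int(km.n_iter_),
                        objective=float(km.inertia_))


def _fit_minibatch(X, k, seed, **hyper):
    from sklearn.cluster import MiniBatchKMeans

    km = MiniBatchKMeans(n_clusters=k, batch_size=hyper.pop("batch_size", 1024),
                         n_init=hyper.pop("n_init", 10), random_state=seed,
                         **hyper).fit(X)
    return ClusterModel(algorithm="minibatch_kmeans", k=k,
                        centroids=km.cluster_centers_, seed=seed,
                        iterations=int(km.n_iter_),
                        objective=float(km.inertia_))


def _fit_gmm(X, k, seed, **hyper):
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=k,
                         covariance_type=hyper.pop("covariance_type", "full"),
                         reg_covar=hyper.pop("reg_covar", 1e-6),
                         n_init=hyper.pop("n_init", 3),
                         random_state=seed, **hyper).fit(X)
    return ClusterModel(algorithm="gmm", k=k, centroids=gm.means_,
                        gmm_weights=gm.weights_, gmm_means=gm.means_,
                        gmm_covariances=gm.covariances_, seed=seed,
                        iterations=int(gm.n_iter_),
                        objective=float(gm.lower_bound_))


# ---------------------------------------------------------------------------
# Subspace k-means


def _subkmeans_objective(X, V, m, centroids, labels, global_mean):
    Pc = V[:, :m]
    Pn = V[:, m:]
    diff_c = (X - centroids[labels]) @ Pc
    diff_n = (X - global_mean) @ Pn
    return float((diff_c**2).sum() + (diff_n**2).sum())


def fit_subkmeans(X, k: int, m_init: int | None = None, seed: int = 0,
                  max_iter: int = 100, n_init: int = 5) -> ClusterModel:
    """Subspace k-means by alternating minimisation.

    Each round: (1) assign points to the nearest centroid in the projected
    m-dimensional clustered space, (2) recompute centroids as cluster means,
    (3) update the orthogonal transform V from the eigendecomposition of
    (sum of within-cluster scatters - total scatter), taking m as the number
    of negative eigenvalues (at least 1). The objective is non-increasing;
    iteration stops at an assignment fixpoint. Of ``n_init`` seeded starts
    the lowest-objective model is kept; a failed eigendecomposition just
    voids that start (logged).
    """
    X = _check_fit_inputs(X, k)
    global_mean = X.mean(axis=0)
    best: ClusterModel | None = None
    last_error: Exception | None = None
    for restart in range(n_init):
        try:
            model = _subkmeans_once(X, k, m_init, seed + restart, max_iter,
                                    global_mean)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            logger.warning("subkmeans eigendecomposition failed (%s) for "
                           "start seed %d; skipped", exc, seed + restart)
            last_error = exc
            continue
        if best is None or model.objective < best.objective:
            best = model
    if best is None:
        raise RuntimeError(f"subkmeans failed in all {n_init} starts"
                           ) from last_error
    return best


def _subkmeans_once(X, k, m_init, seed, max_iter, global_mean):
    from sklearn.cluster import kmeans_plusplus

    n, d = X.shape
    rng = np.random.default_rng(seed)
    m = int(m_init) if m_init is not None else max(1, d // 2)
    if not 1 <= m <= d:
        raise ValueError(f"m_init {m_init} outside 1..{d}")

    # random orthogonal start; centroids via greedy seeding in full space
    V = np.linalg.qr(rng.standard_normal((d, d)))[0]
    centroids, _ = kmeans_plusplus(
        X, n_clusters=k, random_state=int(rng.integers(2**31 - 1)))

    labels = np.full(n, -1)
    objective = np.inf
    history: list[float] = []
    for it in range(1, max_iter + 1):
        Pc = V[:, :m]
        proj = X @ Pc
        cproj = centroids @ Pc
        dist = ((proj[:, None, :] - cproj[None, :, :])**2).sum(axis=2)
        new_labels = dist.argmin(axis=1)

        # empty clusters: reseed at the farthest point
        for c in range(k):
            if not (new_labels == c).any():
                far = dist.min(axis=1).argmax()
                new_labels[far] = c

        for c in range(k):
            centroids[c] = X[new_labels == c].mean(axis=0)

        total = X - global_mean
        S_D = total.T @ total
        M = -S_D.copy()
        for c in range(k):
            within = X[new_labels == c] - centroids[c]
            M += within.T @ within
        eigvals, eigvecs = np.linalg.eigh(M)  # ascending
        scale = max(1.0, float(np.abs(eigvals).max()))
        m = max(1, int((eigvals < -1e-10 * scale).sum()))
        V = eigvecs

        objective = _subkmeans_objective(X, V, m, centroids, new_labels,
                                         global_mean)
        history.append(objective)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels

    return ClusterModel(algorithm="subkmeans", k=k, centroids=centroids,
                        subspace_V=V, subspace_m=m, seed=seed, iterations=it,
                        objective=objective,
                        metadata={"global_mean": global_mean.tolist(),
                                  "objective_history": history})


def _fit_subkmeans_engine(X, k, seed, **hyper):
    return fit_subkmeans(X, k, seed=seed, **hyper)


ENGINES: dict[str, Callable] = {
    "kmeans": _fit_kmeans,
    "minibatch_kmeans": _fit_minibatch,
    "gmm": _fit_gmm,
    "subkmeans": _fit_subkmeans_engine,
}


def register_engine(name: str, fit_fn: Callable) -> None:
    """Register a plugin engine: ``fit_fn(X, k, seed, **hyper) -> ClusterModel``."""
    ENGINES[name] = fit_fn


def fit(algorithm: str, X, k: int, seed: int = 0, **hyperparams) -> ClusterModel:
    """Fit one engine; deterministic under a fixed seed."""
    if algorithm not in ENGINES:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"available: {sorted(ENGINES)}")
    X = _check_fit_inputs(X, k)
    return ENGINES[algorithm](X, k, seed, **hyperparams)


def _gmm_log_responsibilities(model: ClusterModel, X: np.ndarray) -> np.ndarray:
    from scipy.stats import multivariate_normal

    parts = []
    covs = model.gmm_covariances
    for j in range(model.k):
        cov = covs[j] if covs.ndim == 3 else covs
        parts.append(np.log(model.gmm_weights[j]) + multivariate_normal.logpdf(
            X, mean=model.gmm_means[j], cov=cov, allow_singular=True))
    logp = np.column_stack(parts)
    return logp - logsumexp(logp, axis=1, keepdims=True)


def assign(model: ClusterModel, X) -> np.ndarray:
    """Deterministic labels for new observations under a fitted model.

    k-means family: nearest centroid (in the clustered subspace for
    subspace k-means); GMM: maximum posterior responsibility. Ties break to
    the lowest cluster index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.d:
        raise ValueError(f"X has {X.shape[1]} features, model expects {model.d}")
    if model.algorithm == "gmm" and model.gmm_weights is not None:
        resp = _gmm_log_responsibilities(model, X)
        return resp.argmax(axis=1)
    if model.subspace_V is not None:
        P = model.subspace_V[:, :model.subspace_m]
        proj = X @ P
        cproj = model.centroids @ P
    else:
        proj, cproj = X, model.centroids
    dist = ((proj[:, None, :] - cproj[None, :, :])**2).sum(axis=2)
    return dist.argmin(axis=1)  # argmin takes the lowest index on ties
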