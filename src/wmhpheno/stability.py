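"""Bootstrap co-membership stability, optimal-k selection, stable centroids.

For a candidate (algorithm, k): a reference model is fitted on the full
dataset; each of B bootstrap resamples is refitted and extended to all
observations, and every reference cluster is scored by its best Jaccard
overlap with any cluster of the extended bootstrap partition. Cluster-wise
matching by maximum Jaccard (rather than a global bipartite assignment)
tolerates clusters splitting or merging across resamples. The optimal k is
the largest value in range whose mean global stability exceeds the
threshold (default 0.90); centroids are then re-estimated from observations
whose stability exceeds the same threshold and clusters are reordered by
increasing median total lesion volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import engines
from .engines import ClusterModel

logger = logging.getLogger(__name__)

__all__ = [
    "jaccard",
    "bootstrap_stability",
    "BootstrapStabilityResult",
    "stability_profile",
    "StabilityProfile",
    "select_optimal_k",
    "stable_centroids",
    "StableCentroids",
]

DEFAULT_K_RANGE = tuple(range(2, 8))
DEFAULT_THRESHOLD = 0.90


def jaccard(a, b) -> float:
    """Jaccard overlap |a n b| / |a u b|; 1.0 when both sets are empty."""
    a = set(a) if not isinstance(a, np.ndarray) else set(np.flatnonzero(a))
    b = set(b) if not isinstance(b, np.ndarray) else set(np.flatnonzero(b))
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def _pairwise_jaccard(ref_labels: np.ndarray, other_labels: np.ndarray,
                      k_ref: int, k_other: int) -> np.ndarray:
    """Per-reference-cluster max Jaccard against any cluster of the other
    partition, via the k_ref x k_other contingency table."""
    contingency = np.zeros((k_ref, k_other), dtype=np.int64)
    np.add.at(contingency, (ref_labels, other_labels), 1)
    ref_sizes = contingency.sum(axis=1)
    other_sizes = contingency.sum(axis=0)
    union = ref_sizes[:, None] + other_sizes[None, :] - contingency
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, contingency / union, 1.0)
    return jac.max(axis=1)


@dataclass
class BootstrapStabilityResult:
    per_cluster: np.ndarray  # (k,)
    per_observation: np.ndarray  # (n,)
    global_stability: float
    reference_model: ClusterModel
    reference_labels: np.ndarray
    n_degenerate: int = 0  # bootstrap fits that produced an empty cluster
    boot_labels: list = field(default_factory=list)  # B extended partitions
    boot_indices: list = field(default_factory=list)  # B resample index arrays


def bootstrap_stability(X, algorithm: str, k: int, B: int = 20, seed: int = 0,
                        hyperparams: dict | None = None
                        ) -> BootstrapStabilityResult:
    """Jaccard stability of the full-data clustering over B bootstraps.

    Each bootstrap model is extended to the complete set of observations via
    ``assign`` before scoring, so stabilities are comparable across
    iterations without centroid mapping.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if B < 1:
        raise ValueError("B must be >= 1")
    if n < 5 * k:
        raise ValueError(f"need at least 5*k = {5 * k} rows, got {n}")
    hyperparams = hyperparams or {}

    ss = np.random.SeedSequence([seed, 0xB00])
    fit_seed, *boot_seeds = [int(s.generate_state(1)[0] % 2**31)
                             for s in ss.spawn(B + 1)]
    rng = np.random.default_rng(ss.spawn(1)[0])

    ref = engines.fit(algorithm, X, k, seed=fit_seed, **hyperparams)
    ref_labels = engines.assign(ref, X)

    scores = np.zeros((B, k))
    n_degenerate = 0
    all_boot_labels, all_boot_indices = [], []
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot = engines.fit(algorithm, X[idx], k, seed=boot_seeds[b],
                           **hyperparams)
        boot_labels = engines.assign(boot, X)
        if len(np.unique(boot_labels)) < k:
            n_degenerate += 1
        scores[b] = _pairwise_jaccard(ref_labels, boot_labels, k, k)
        all_boot_labels.append(boot_labels)
        all_boot_indices.append(idx)

    per_cluster = scores.mean(axis=0)
    per_observation = per_cluster[ref_labels]
    return BootstrapStabilityResult(
        per_cluster=per_cluster,
        per_observation=per_observation,
        global_stability=float(per_cluster.mean()),
        reference_model=ref,
        reference_labels=ref_labels,
        n_degenerate=n_degenerate,
        boot_labels=all_boot_labels,
        boot_indices=all_boot_indices,
    )


@dataclass
class StabilityProfile:
    """Stability across algorithms and k, with the selection trace."""

    stabilities: dict  # algorithm -> {k: best-replicate mean global stability}
    replicate_stabilities: dict  # algorithm -> {k: list over repeats}
    best_results: dict  # (algorithm, k) -> BootstrapStabilityResult
    algorithm: str  # algorithm whose profile is reported
    selected_k: int | None
    suggestion_k: int | None
    threshold: float
    B: int
    n_repeats: int
    seed: int
    trace: list = field(default_factory=list)

    @property
    def selected_result(self) -> BootstrapStabilityResult | None:
        key_k = self.selected_k if self.selected_k is not None else \
            self.suggestion_k
        return self.best_results.get((self.algorithm, key_k))

    def profile_for(self, algorithm: str | None = None) -> dict:
        return self.stabilities[algorithm or self.algorithm]

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "selected_k": self.selected_k,
            "suggestion_k": self.suggestion_k,
            "threshold": self.threshold,
            "B": self.B,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "stabilities": {alg: {str(k): v for k, v in prof.items()}
                            for alg, prof in self.stabilities.items()},
            "replicate_stabilities": {
                alg: {str(k): v for k, v in prof.items()}
                for alg, prof in self.replicate_stabilities.items()},
            "trace": self.trace,
        }


def stability_profile(X, algorithms=("kmeans",), k_range=DEFAULT_K_RANGE,
                      B: int = 20, n_repeats: int = 5, seed: int = 0,
                      threshold: float = DEFAULT_THRESHOLD,
                      hyperparams: dict | None = None) -> StabilityProfile:
    """Stability profile over algorithms and k; keeps the most stable
    replicate per (algorithm, k) and selects the reporting algorithm as the
    one whose selected (or best) k attains the highest stability."""
    k_range = tuple(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    if isinstance(algorithms, str):
        algorithms = (algorithms,)
    hyperparams = hyperparams or {}

    root = np.random.SeedSequence([seed, 0x5E1])
    stabilities: dict = {}
    replicate_stabilities: dict = {}
    best_results: dict = {}
    trace: list = []

    for ai, alg in enumerate(algorithms):
        stabilities[alg] = {}
        replicate_stabilities[alg] = {}
        for ki, k in enumerate(k_range):
            rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                         for s in root.spawn(n_repeats)]
            best = None
            reps = []
            for r in range(n_repeats):
                res = bootstrap_stability(X, alg, k, B=B, seed=rep_seeds[r],
                                          hyperparams=hyperparams.get(alg, {}))
                reps.append(res.global_stability)
                if best is None or res.global_stability > best.global_stability:
                    best = res
            stabilities[alg][k] = best.global_stability
            replicate_stabilities[alg][k] = reps
            best_results[(alg, k)] = best
            trace.append({"algorithm": alg, "k": k,
                          "replicates": reps,
                          "best": best.global_stability})

    # pick the reporting algorithm: prefer one with a k above threshold,
    # ranked by stability at its selected k; otherwise by overall max
    chosen_alg, chosen_k, chosen_sugg = None, None, None
    chosen_score = -np.inf
    for alg in algorithms:
        sel = select_optimal_k(stabilities[alg], threshold=threshold)
        if sel.selected_k is not None:
            score = (1, stabilities[alg][sel.selected_k])
        else:
            score = (0, stabilities[alg][sel.suggestion_k])
        if chosen_alg is None or score > chosen_score:
            chosen_alg, chosen_score = alg, score
            chosen_k, chosen_sugg = sel.selected_k, sel.suggestion_k

    trace.append({"chosen_algorithm": chosen_alg, "selected_k": chosen_k,
                  "suggestion_k": chosen_sugg})
    return StabilityProfile(
        stabilities=stabilities,
        replicate_stabilities=replicate_stabilities,
        best_results=best_results,
        algorithm=chosen_alg,
        selected_k=chosen_k,
        suggestion_k=chosen_sugg,
        threshold=threshold,
        B=B, n_repeats=n_repeats, seed=seed, trace=trace,
    )


@dataclass
class KSelection:
    selected_k: int | None
    suggestion_k: int | None


def select_optimal_k(profile, threshold: float = DEFAULT_THRESHOLD
                     ) -> KSelection:
    """Largest k with stability strictly above the threshold.

    ``profile`` maps k -> mean global stability (a :class:`StabilityProfile`
    is accepted and read at its reporting algorithm). When no k qualifies,
    ``selected_k`` is None and the argmax k is returned as a suggestion.
    """
    if isinstance(profile, StabilityProfile):
        profile = profile.profile_for()
    if not profile:
        raise ValueError("empty stability profile")
    above = [k for k, s in profile.items() if s > threshold]
    if above:
        return KSelection(selected_k=max(above), suggestion_k=max(above))
    suggestion = max(profile, key=lambda k: (profile[k], -k))
    return KSelection(selected_k=None, suggestion_k=suggestion)


@dataclass
class StableCentroids:
    """Re-estimated centroids with burden-ordered cluster indices."""

    model: ClusterModel  # copy of the source model with reordered centroids
    centroids: np.ndarray  # (k, d), ordered by increasing median burden
    order: np.ndarray  # order[new_index] = original cluster index
    median_burden: np.ndarray  # per new index
    flagged: list  # new indices whose centroid kept the raw estimate


def stable_centroids(model: ClusterModel, per_observation_stability, X,
                     total_burden, threshold: float = DEFAULT_THRESHOLD
                     ) -> StableCentroids:
    """Centroids from observations with stability above the threshold.

    Clusters with no observation above the threshold keep their raw
    centroid and are flagged. Cluster indices are reordered by increasing
    median total lesion burden of their members (all members, not only the
    stable ones). The returned model assigns with the reordered centroids.
    """
    X = np.asarray(X, dtype=float)
    stab = np.asarray(per_observation_stability, dtype=float)
    burden = np.asarray(total_burden, dtype=float)
    if not (len(stab) == len(X) == len(burden)):
        raise ValueError("X, stability and burden must align row-wise")

    labels = engines.assign(model, X)
    k = model.k
    new_centroids = np.array(model.centroids, dtype=float, copy=True)
    flagged_orig = []
    medians = np.full(k, np.nan)
    for c in range(k):
        members = labels == c
        if members.any():
            medians[c] = float(np.median(burden[members]))
        stable = members & (stab > threshold)
        if stable.any():
            new_centroids[c] = X[stable].mean(axis=0)
        else:
            flagged_orig.append(c)
            logger.warning("cluster %d has no observation with stability > "
                           "%.2f; raw centroid kept", c, threshold)

    order = np.argsort(medians, kind="stable")
    reordered = new_centroids[order]

    out_model = ClusterModel(
        algorithm=model.algorithm, k=k, centroids=reordered,
        subspace_V=model.subspace_V, subspace_m=model.subspace_m,
        seed=model.seed, iterations=model.iterations,
        objective=model.objective,
        metadata={**model.metadata, "stable_centroids": True,
                  "burden_order": order.tolist()},
    )
    new_index = {orig: new for new, orig in enumerate(order)}
    return StableCentroids(
        model=out_model,
        centroids=reordered,
        order=order,
        median_burden=medians[order],
        flagged=[new_index[c] for c in flagged_orig],
    )
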