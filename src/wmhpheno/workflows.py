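"""Composite workflows: phenotyping, stratified re-clustering, transitions."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import engines, features, stability
from .features import FeatureTransform, cohort_feature_matrix
from .regions import REGION_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PhenotypingResult", "run_phenotyping",
           "run_stratified", "run_transitions", "TransitionResult"]


@dataclass
class RunConfig:
    """Defaults mirror the reference analysis; every override is logged."""

    algorithms: tuple = ("kmeans",)
    k_range: tuple = (2, 7)  # inclusive bounds
    B: int = 20
    n_repeats: int = 5
    stability_threshold: float = 0.90
    progression_threshold: float = 250.0  # mm^3/year
    interval_window: tuple = (1.0, 7.0)  # years
    transition_window: tuple = (1.5, 2.5)  # years (18-30 months)
    volume_bands_mL: tuple = ((0.0, 4.0), (4.0, 8.0))
    age_band: tuple = (67.0, 72.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        defaults = cls()
        known = asdict(defaults)
        overrides = {}
        for key, value in raw.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(known[key], tuple):
                value = tuple(tuple(v) if isinstance(v, list) else v
                              for v in value)
            overrides[key] = value
            logger.info("config override: %s = %r", key, value)
        return cls(**overrides)

    def hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @property
    def ks(self) -> tuple:
        lo, hi = self.k_range
        return tuple(range(int(lo), int(hi) + 1))


@dataclass
class PhenotypingResult:
    transform: FeatureTransform
    profile: stability.StabilityProfile
    stable: stability.StableCentroids
    table: pd.DataFrame  # baseline rows with cluster + stability columns
    features: np.ndarray
    keep: np.ndarray
    config_hash: str

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.transform.to_json(out / "feature_transform.json")
        self.stable.model.to_json(out / "selected_model.json")
        summary = self.profile.summary()
        summary["config_hash"] = self.config_hash
        summary["burden_order"] = self.stable.order.tolist()
        summary["median_burden"] = self.stable.median_burden.tolist()
        with open(out / "stability_profile.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        self.table.to_csv(out / "cohort_clustered.tsv", sep="\t", index=False)


def run_phenotyping(table: pd.DataFrame, config: RunConfig | None = None
                    ) -> PhenotypingResult:
    """Full cross-sectional phenotyping on the baseline rows of a cohort.

    Fits the feature transform (reference ICV = median baseline ICV of the
    usable rows), builds the stability profile over the configured
    algorithms and k range, selects k, re-estimates stable centroids
    (burden-ordered) and appends cluster assignments and per-observation
    stabilities to the table.
    """
    config = config or RunConfig()
    base = table[table["timepoint"] == 0].reset_index(drop=True)
    if base.empty:
        raise ValueError("phenotyping: no baseline rows in the table")

    transform, feats, keep = cohort_feature_matrix(base)
    profile = stability.stability_profile(
        feats, algorithms=config.algorithms, k_range=config.ks, B=config.B,
        n_repeats=config.n_repeats, seed=config.seed,
        threshold=config.stability_threshold)
    result = profile.selected_result
    if result is None:
        raise RuntimeError("stability profile produced no candidate model")

    burden = (base.loc[keep, "total_wmh_mm3"].to_numpy()
              / base.loc[keep, "icv_mm3"].to_numpy()
              * transform.reference_icv_mm3)
    stable = stability.stable_centroids(
        result.reference_model, result.per_observation, feats, burden,
        threshold=config.stability_threshold)

    labels = engines.assign(stable.model, feats)
    out = base.copy()
    out["cluster"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out.loc[keep, "cluster"] = labels + 1
    out["stability"] = np.nan
    # stabilities are per reference cluster; map through the burden order
    out.loc[keep, "stability"] = result.per_observation
    return PhenotypingResult(transform=transform, profile=profile,
                             stable=stable, table=out, features=feats,
                             keep=keep, config_hash=config.hash())


def run_stratified(table: pd.DataFrame, config: RunConfig | None = None
                   ) -> dict[str, PhenotypingResult]:
    """Independent phenotyping per stratum.

    Volume strata are half-open reference-scale bands [low, high) in mL on
    baseline total volume; the age stratum is [low, high) years. Empty
    strata are skipped with a warning.
    """
    config = config or RunConfig()
    base = table[table["timepoint"] == 0]
    ref = float(np.median(base["icv_mm3"]))
    total_ml = (base["total_wmh_mm3"] / base["icv_mm3"] * ref) / 1000.0

    strata: dict[str, pd.Series] = {}
    for lo, hi in config.volume_bands_mL:
        strata[f"volume_{lo:g}-{hi:g}mL"] = (total_ml >= lo) & (total_ml < hi)
    lo, hi = config.age_band
    strata[f"age_{lo:g}-{hi:g}"] = (base["age"] >= lo) & (base["age"] < hi)

    results = {}
    for name, mask in strata.items():
        sub = base[mask.to_numpy()]
        if sub.empty:
            logger.warning("stratum %s is empty; skipped", name)
            continue
        results[name] = run_phenotyping(sub, config)
    return results


@dataclass
class TransitionResult:
    matrix: np.ndarray  # (k, k) counts, rows = baseline cluster
    retention_fraction: float
    n_pairs: int
    distance_summary: dict  # stayers/movers mean distance at both timepoints
    table: pd.DataFrame = field(repr=False, default=None)


def run_transitions(table: pd.DataFrame, transform: FeatureTransform,
                    model: engines.ClusterModel,
                    config: RunConfig | None = None) -> TransitionResult:
    """Cluster membership transitions over the configured follow-up window.

    Follow-up rows are transformed with the baseline-fitted feature
    transform and assigned by the baseline model; reports the k x k
    transition count matrix, the diagonal retention fraction and mean
    distances to the assigned baseline centroid for stayers vs movers at
    both timepoints.
    """
    config = config or RunConfig()
    lo, hi = config.transition_window
    base = table[table["timepoint"] == 0].set_index("participant_id")
    follow = table[(table["timepoint"] > 0)
                   & (table["interval_years"] >= lo)
                   & (table["interval_years"] <= hi)]
    follow = (follow.sort_values("interval_years")
              .drop_duplicates("participant_id", keep="first")
              .set_index("participant_id"))
    ids = base.index.intersection(follow.index)
    if len(ids) == 0:
        raise ValueError("no eligible baseline/follow-up pairs in the window")

    def feats_for(df):
        vols = df[list(REGION_COLUMNS)].to_numpy(dtype=float)
        props, keep = features.relative_distribution(vols)
        X, _ = features.apply_transform(transform, props)
        return X, keep

    # zero-total rows have undefined proportions; keep jointly usable pairs
    _, keep_b = feats_for(base.loc[ids])
    _, keep_f = feats_for(follow.loc[ids])
    sub_ids = np.asarray(ids)[keep_b & keep_f]
    if len(sub_ids) == 0:
        raise ValueError("no eligible pairs with nonzero lesion volume")
    Xb, _ = feats_for(base.loc[sub_ids])
    Xf, _ = feats_for(follow.loc[sub_ids])

    lb = engines.assign(model, Xb)
    lf = engines.assign(model, Xf)
    k = model.k
    matrix = np.zeros((k, k), dtype=np.int64)
    np.add.at(matrix, (lb, lf), 1)
    n_pairs = int(matrix.sum())
    retention = float(np.trace(matrix)) / n_pairs

    if model.subspace_V is not None:
        P = model.subspace_V[:, :model.subspace_m]
        proj_b, proj_f = Xb @ P, Xf @ P
        cent = model.centroids @ P
    else:
        proj_b, proj_f, cent = Xb, Xf, model.centroids
    d_base = np.linalg.norm(proj_b - cent[lb], axis=1)
    d_follow = np.linalg.norm(proj_f - cent[lb], axis=1)
    stay = lb == lf
    summary = {
        "stayers_baseline": float(d_base[stay].mean()) if stay.any() else np.nan,
        "movers_baseline": float(d_base[~stay].mean()) if (~stay).any() else np.nan,
        "stayers_followup": float(d_follow[stay].mean()) if stay.any() else np.nan,
        "movers_followup": float(d_follow[~stay].mean()) if (~stay).any() else np.nan,
    }
    detail = pd.DataFrame({
        "participant_id": sub_ids,
        "cluster_baseline": lb + 1,
        "cluster_followup": lf + 1,
        "stayed": stay,
        "distance_baseline": d_base,
        "distance_followup": d_follow,
    })
    return TransitionResult(matrix=matrix, retention_fraction=retention,
                            n_pairs=n_pairs, distance_summary=summary,
                            table=detail)
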