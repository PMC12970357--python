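"""Synthetic cohorts and geometric phantoms for end-to-end pipeline testing.

Cross-sectional cohorts are drawn from a K-component spatial mixture: each
component has a Dirichlet distribution over the 36 bullseye regions, a
log-normal total lesion burden parameterised by its median, and additive /
log-odds shifts on risk factors. Longitudinal follow-ups add a second
timepoint with annualised volume change and a small spatial drift toward the
component mean. Phantoms are concentric-shell label volumes for exercising
the bullseye mapper against analytic geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import LOBES, N_LAYERS, N_LOBES, N_REGIONS, REGION_COLUMNS, region_index

__all__ = [
    "ClusterProfileSpec",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cross_sectional",
    "generate_longitudinal",
    "generate_phantom",
    "validate_cohort_table",
    "CONTINUOUS_RISK_FACTORS",
    "BINARY_RISK_FACTORS",
    "RISK_FACTOR_COLUMNS",
]

# Baseline marginal distributions for risk factors (continuous: mean, sd).
CONTINUOUS_RISK_FACTORS: dict[str, tuple[float, float]] = {
    "age": (66.0, 8.0),
    "sbp": (135.0, 18.0),
    "dbp": (81.0, 10.0),
    "glucose": (3.6, 0.7),
    "hba1c": (34.6, 4.0),
    "hdl": (1.3, 0.35),
    "ldl": (1.7, 0.4),
    "triglycerides": (1.2, 0.6),
    "wbcc": (6.4, 1.6),
    "creatinine": (66.0, 13.0),
}

# Binary yes/no factors with baseline prevalence (probability of "yes").
BINARY_RISK_FACTORS: dict[str, float] = {
    "diabetes": 0.043,
    "hypertension": 0.304,
    "med_bp": 0.254,
    "med_chol": 0.257,
    "med_dm": 0.010,
}

_SMOKING_LEVELS = ("never", "ever", "current")
_SMOKING_PROBS = (0.627, 0.339, 0.034)
_ETHNICITY_LEVELS = ("white", "asian", "black", "mixed", "other")
_ETHNICITY_PROBS = (0.960, 0.018, 0.011, 0.005, 0.006)
_APOE4_PROBS = (0.725, 0.253, 0.022)
_FEMALE_PROB = 0.528

RISK_FACTOR_COLUMNS: tuple[str, ...] = tuple(CONTINUOUS_RISK_FACTORS) + tuple(
    BINARY_RISK_FACTORS
) + ("sex", "smoking", "ethnicity", "apoe4")

#: Dirichlet concentration sums above this are treated as point masses at the
#: mean (numerically degenerate draws; used to realise zero-variance profiles).
_DEGENERATE_ALPHA0 = 1e12


@dataclass
class ClusterProfileSpec:
    """One mixture component: spatial pattern, burden and risk-factor shifts."""

    label: int
    mixing_weight: float
    region_concentration: np.ndarray
    burden_median_mL: float
    burden_log_sd: float
    riskfactor_shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_concentration = np.asarray(self.region_concentration, dtype=float)
        if self.region_concentration.shape != (N_REGIONS,):
            raise ValueError(
                f"profile {self.label}: region_concentration must have shape "
                f"({N_REGIONS},), got {self.region_concentration.shape}"
            )
        if not np.all(self.region_concentration > 0):
            raise ValueError(
                f"profile {self.label}: all concentration parameters must be > 0"
            )
        if not 0 <= self.mixing_weight <= 1:
            raise ValueError(f"profile {self.label}: mixing_weight outside [0,1]")
        if self.burden_median_mL <= 0:
            raise ValueError(f"profile {self.label}: burden_median_mL must be > 0")
        if self.burden_log_sd < 0:
            raise ValueError(f"profile {self.label}: burden_log_sd must be >= 0")

    @property
    def mean_proportions(self) -> np.ndarray:
        a = self.region_concentration
        return a / a.sum()


@dataclass
class CohortSpec:
    """Full generative description of a synthetic cohort."""

    n_participants: int
    profiles: list[ClusterProfileSpec]
    icv_mean_mm3: float = 1.5e6
    icv_sd_mm3: float = 1.4e5
    followup_fraction: float = 0.6
    interval_range_years: tuple[float, float] = (1.0, 3.0)
    #: per-cluster (mean, sd) of annualised total-volume change, mm^3/year
    progression_model: dict[int, tuple[float, float]] = field(default_factory=dict)
    drift_per_year: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.profiles)
        if k == 0:
            raise ValueError("at least one profile required")
        if self.n_participants < k:
            raise ValueError(
                f"n_participants ({self.n_participants}) must be >= number of "
                f"profiles ({k})"
            )
        w = sum(p.mixing_weight for p in self.profiles)
        if abs(w - 1.0) > 1e-12:
            raise ValueError(f"mixing weights sum to {w}, expected 1")
        lo, hi = self.interval_range_years
        if lo <= 0 or hi < lo:
            raise ValueError("interval_range_years must satisfy 0 < min <= max")
        if not 0 <= self.followup_fraction <= 1:
            raise ValueError("followup_fraction outside [0,1]")


def _emphasis_concentration(cells: dict[tuple[str, int], float], base: float,
                            scale: float) -> np.ndarray:
    """Concentration vector with `base` everywhere and extra mass on `cells`."""
    conc = np.full(N_REGIONS, base)
    for (lobe, layer), weight in cells.items():
        conc[region_index(lobe, layer)] += weight
    return conc * scale / conc.sum()


def default_cohort_spec(n_participants: int = 2000, seed: int = 0,
                        separation: float = 220.0) -> CohortSpec:
    """Five-component cohort mimicking the qualitative spatial patterns.

    Components (ordered by increasing median burden): deep grey/internal
    capsule emphasis; occipital posterior; symmetric periventricular;
    frontal extending juxtacortically; widespread frontal-parietal in the
    inner layers. ``separation`` is the total Dirichlet concentration per
    component — larger values give tighter, better-separated clusters.
    """
    base = 0.25

    c1 = {(lobe, layer): 4.0 for lobe in ["bgit"] for layer in (1, 2, 3, 4)}
    c2 = {(lobe, layer): 3.0
          for lobe in ("occipital_l", "occipital_r") for layer in (1, 2)}
    c3 = {(lobe, 1): 2.0
          for lobe in ("frontal_l", "frontal_r", "parietal_l", "parietal_r",
                       "occipital_l", "occipital_r", "temporal_l", "temporal_r")}
    c4 = {(lobe, layer): w
          for lobe in ("frontal_l", "frontal_r")
          for layer, w in zip((1, 2, 3, 4), (1.5, 2.0, 2.5, 2.5))}
    c5 = {(lobe, layer): 1.8
          for lobe in ("frontal_l", "frontal_r", "parietal_l", "parietal_r")
          for layer in (1, 2, 3)}

    patterns = [c1, c2, c3, c4, c5]
    medians = [0.9, 1.5, 1.9, 4.4, 6.4]
    # risk gradient across burden strata: higher SBP / diabetes odds at the top
    shifts: list[dict[str, float]] = [
        {},
        {"sbp": -2.0},
        {"age": 1.0},
        {"age": 3.0, "sbp": 6.0, "hypertension": 0.5},
        {"age": 5.0, "sbp": 10.0, "diabetes": 1.0, "hypertension": 0.9,
         "smoking": 0.6},
    ]
    profiles = [
        ClusterProfileSpec(
            label=i + 1,
            mixing_weight=0.2,
            region_concentration=_emphasis_concentration(patterns[i], base,
                                                         separation),
            burden_median_mL=medians[i],
            burden_log_sd=0.35,
            riskfactor_shifts=shifts[i],
        )
        for i in range(5)
    ]
    progression = {1: (100.0, 120.0), 2: (150.0, 120.0), 3: (200.0, 150.0),
                   4: (400.0, 180.0), 5: (600.0, 220.0)}
    return CohortSpec(
        n_participants=n_participants,
        profiles=profiles,
        progression_model=progression,
        seed=seed,
    )


def _draw_proportions(rng: np.random.Generator, conc: np.ndarray,
                      n: int) -> np.ndarray:
    if conc.sum() > _DEGENERATE_ALPHA0:
        return np.tile(conc / conc.sum(), (n, 1))
    return rng.dirichlet(conc, size=n)


def _draw_risk_factors(rng: np.random.Generator, n: int,
                       shifts: dict[str, float]) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd) in CONTINUOUS_RISK_FACTORS.items():
        cols[name] = rng.normal(mean + shifts.get(name, 0.0), sd, size=n)
    for name, p in BINARY_RISK_FACTORS.items():
        logit = math.log(p / (1 - p)) + shifts.get(name, 0.0)
        prob = 1 / (1 + math.exp(-logit))
        cols[name] = np.where(rng.random(n) < prob, "yes", "no")
    cols["sex"] = np.where(rng.random(n) < _FEMALE_PROB, "female", "male")

    smoke_logits = np.log(np.asarray(_SMOKING_PROBS))
    # shift moves log-odds mass from "never" onto "ever"/"current"
    smoke_logits[1:] += shifts.get("smoking", 0.0)
    smoke_p = np.exp(smoke_logits) / np.exp(smoke_logits).sum()
    cols["smoking"] = rng.choice(_SMOKING_LEVELS, size=n, p=smoke_p)

    cols["ethnicity"] = rng.choice(_ETHNICITY_LEVELS, size=n, p=_ETHNICITY_PROBS)
    apoe_logits = np.log(np.asarray(_APOE4_PROBS))
    apoe_logits[1:] += shifts.get("apoe4", 0.0)
    apoe_p = np.exp(apoe_logits) / np.exp(apoe_logits).sum()
    cols["apoe4"] = rng.choice([0, 1, 2], size=n, p=apoe_p)
    return pd.DataFrame(cols)


def generate_cross_sectional(spec: CohortSpec) -> pd.DataFrame:
    """Draw a baseline cohort table (one timepoint-0 row per participant)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    k = len(spec.profiles)

    weights = np.asarray([p.mixing_weight for p in spec.profiles])
    cluster_idx = rng.choice(k, size=n, p=weights)

    proportions = np.empty((n, N_REGIONS))
    totals = np.empty(n)
    rf_frames = []
    order = []
    for ci, profile in enumerate(spec.profiles):
        mask = cluster_idx == ci
        m = int(mask.sum())
        if m == 0:
            continue
        proportions[mask] = _draw_proportions(rng, profile.region_concentration, m)
        mu = math.log(profile.burden_median_mL * 1000.0)
        totals[mask] = np.exp(rng.normal(mu, profile.burden_log_sd, size=m))
        rf_frames.append(_draw_risk_factors(rng, m, profile.riskfactor_shifts))
        order.append(np.nonzero(mask)[0])

    rf = pd.concat(rf_frames, ignore_index=True)
    rf.index = np.concatenate(order)
    rf = rf.sort_index()

    if spec.icv_sd_mm3 == 0:
        icv = np.full(n, spec.icv_mean_mm3)
    else:
        icv = rng.normal(spec.icv_mean_mm3, spec.icv_sd_mm3, size=n)
        while np.any(icv <= 0):  # truncate at > 0
            bad = icv <= 0
            icv[bad] = rng.normal(spec.icv_mean_mm3, spec.icv_sd_mm3,
                                  size=int(bad.sum()))

    regional = proportions * totals[:, None]
    df = pd.DataFrame(regional, columns=list(REGION_COLUMNS))
    df.insert(0, "participant_id", [f"P{i:06d}" for i in range(n)])
    df.insert(1, "timepoint", 0)
    df["total_wmh_mm3"] = regional.sum(axis=1)
    df["icv_mm3"] = icv
    df["true_cluster"] = cluster_idx + 1
    df["interval_years"] = 0.0
    df = pd.concat([df, rf], axis=1)
    return df


def generate_longitudinal(base: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Append follow-up rows to a cross-sectional table.

    A seeded fraction of participants gets one timepoint-1 row: the total
    volume changes by ``interval x Normal(mean, sd)`` from the cluster's
    progression model (floored at 0) and regional proportions drift toward
    the cluster mean by ``drift_per_year x interval`` (capped at 1).
    """
    if not 0 <= spec.followup_fraction <= 1:
        raise ValueError("followup_fraction outside [0,1]")
    if (base["timepoint"] != 0).any():
        raise ValueError("base table must contain only timepoint-0 rows")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = len(base)
    n_follow = int(round(spec.followup_fraction * n))
    chosen = np.sort(rng.choice(n, size=n_follow, replace=False))

    follow = base.iloc[chosen].copy().reset_index(drop=True)
    lo, hi = spec.interval_range_years
    intervals = rng.uniform(lo, hi, size=n_follow) if hi > lo else np.full(
        n_follow, lo)

    clusters = follow["true_cluster"].to_numpy()
    means = np.zeros(n_follow)  # clusters absent from the model: no change
    sds = np.zeros(n_follow)
    for ci, (mu, sd) in spec.progression_model.items():
        mask = clusters == ci
        means[mask], sds[mask] = mu, sd
    change = rng.normal(means, sds) if np.any(sds > 0) else means
    new_total = np.maximum(
        0.0, follow["total_wmh_mm3"].to_numpy() + intervals * change)

    props = follow[list(REGION_COLUMNS)].to_numpy()
    row_tot = props.sum(axis=1)
    safe = row_tot > 0
    props[safe] /= row_tot[safe, None]
    centroids = np.stack([p.mean_proportions for p in spec.profiles])
    target = centroids[clusters - 1]
    w = np.minimum(1.0, spec.drift_per_year * intervals)[:, None]
    new_props = np.where(safe[:, None], (1 - w) * props + w * target, target)
    new_props /= new_props.sum(axis=1, keepdims=True)

    follow[list(REGION_COLUMNS)] = new_props * new_total[:, None]
    follow["total_wmh_mm3"] = new_total
    follow["timepoint"] = 1
    follow["interval_years"] = intervals
    follow["age"] = follow["age"] + intervals
    return pd.concat([base, follow], ignore_index=True)


def validate_cohort_table(df: pd.DataFrame) -> None:
    """Check the cohort-table invariants; raise ValueError on violation."""
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing region columns: {missing[:3]}...")
    vols = df[list(REGION_COLUMNS)].to_numpy()
    if (vols < 0).any():
        raise ValueError("negative regional volumes")
    tot = df["total_wmh_mm3"].to_numpy()
    if not np.allclose(vols.sum(axis=1), tot, rtol=1e-6, atol=1e-9):
        raise ValueError("total_wmh_mm3 does not equal the sum of regions")
    base_counts = df[df["timepoint"] == 0].groupby("participant_id").size()
    ids = df["participant_id"].unique()
    if len(base_counts) != len(ids) or (base_counts != 1).any():
        raise ValueError("every participant needs exactly one timepoint-0 row")


# ---------------------------------------------------------------------------
# Geometric phantoms


def generate_phantom(geometry: dict, lesion_spec=None) -> dict:
    """Concentric-shell phantom label volumes for the bullseye mapper.

    ``geometry`` needs ``inner_radius`` and ``outer_radius`` (mm),
    ``grid_shape`` (2- or 3-tuple) and ``voxel_dims`` (mm per axis). The
    white-matter domain is the annulus/shell ``inner <= r < outer`` around
    the grid centre; inside it, 9 equal angular sectors (in the first two
    axes) carry the lobe labels 1..9.

    ``lesion_spec`` is either ``"full"`` (lesion = whole domain) or a list of
    ``{"radius_mm", "angle_rad", "extent_mm"}`` blobs; ``extent_mm = 0``
    marks the single in-domain voxel nearest the stated polar position.

    Returns a dict of :class:`~wmhpheno.bullseye.LabelVolume`:
    ``wm_mask, inner_mask, outer_mask, lobe_labels, wmh_mask``.
    """
    from .bullseye import LabelVolume

    a = float(geometry["inner_radius"])
    b = float(geometry["outer_radius"])
    shape = tuple(geometry["grid_shape"])
    voxel_dims = tuple(float(v) for v in geometry["voxel_dims"])
    if not 0 < a < b:
        raise ValueError(f"need 0 < inner_radius < outer_radius, got {a}, {b}")
    if len(shape) != len(voxel_dims):
        raise ValueError("grid_shape and voxel_dims must have equal length")
    half_extent = min(s * d / 2 for s, d in zip(shape, voxel_dims))
    if b >= half_extent:
        raise ValueError(
            f"outer_radius {b} does not fit in grid (half extent {half_extent})")

    centre = [(s - 1) / 2 * d for s, d in zip(shape, voxel_dims)]
    axes = [np.arange(s) * d - c for s, d, c in zip(shape, voxel_dims, centre)]
    grids = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))

    wm = (r >= a) & (r < b)
    inner = r < a
    rim = 2.0 * max(voxel_dims)
    outer = (r >= b) & (r < b + rim)

    theta = np.arctan2(grids[1], grids[0])  # sectors in the first two axes
    sector = np.minimum(
        (np.floor((theta + np.pi) / (2 * np.pi) * N_LOBES)).astype(int),
        N_LOBES - 1)
    lobe_labels = np.where(wm, sector + 1, 0)

    wmh = np.zeros(shape, dtype=np.int8)
    if lesion_spec == "full":
        wmh[wm] = 1
    elif lesion_spec:
        for blob in lesion_spec:
            rr = float(blob["radius_mm"])
            ang = float(blob.get("angle_rad", 0.0))
            ext = float(blob.get("extent_mm", 0.0))
            point = np.zeros(len(shape))
            point[0] = rr * math.cos(ang)
            point[1] = rr * math.sin(ang)
            dist = np.sqrt(sum((g - p)**2 for g, p in zip(grids, point)))
            if ext <= 0:
                masked = np.where(wm, dist, np.inf)
                idx = np.unravel_index(np.argmin(masked), shape)
                wmh[idx] = 1
            else:
                wmh[(dist <= ext) & wm] = 1

    def vol(arr, dtype=np.int8):
        return LabelVolume(grid=arr.astype(dtype), voxel_dims=voxel_dims)

    return {
        "wm_mask": vol(wm),
        "inner_mask": vol(inner),
        "outer_mask": vol(outer),
        "lobe_labels": vol(lobe_labels, np.int16),
        "wmh_mask": vol(wmh),
    }
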