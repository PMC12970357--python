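"""Volume normalisation and the clustering feature transform.

Regional volumes are normalised by each participant's baseline intracranial
volume and, for reporting, rescaled to the fitting set's median baseline
ICV. Clustering operates on relative regional distributions (proportions of
total lesion volume) after square-root transformation and per-feature
min-max scaling; the fitted extrema are stored so follow-up and external
data are transformed with the training-derived parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import N_REGIONS, REGION_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTransform",
    "normalize_by_icv",
    "rescale_to_reference",
    "relative_distribution",
    "fit_transform_features",
    "apply_transform",
]


@dataclass
class FeatureTransform:
    """Train-fitted parameters for the clustering feature space."""

    reference_icv_mm3: float = 0.0
    feature_min: np.ndarray | None = None
    feature_max: np.ndarray | None = None
    fitted: bool = False
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.fitted:
            raise ValueError("transform is not fitted")
        if self.reference_icv_mm3 <= 0:
            raise ValueError("reference_icv_mm3 must be > 0")
        if np.any(self.feature_max < self.feature_min):
            raise ValueError("feature_max < feature_min")

    def to_json(self, path=None) -> str:
        payload = {
            "reference_icv_mm3": self.reference_icv_mm3,
            "feature_min": None if self.feature_min is None
            else self.feature_min.tolist(),
            "feature_max": None if self.feature_max is None
            else self.feature_max.tolist(),
            "fitted": self.fitted,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FeatureTransform":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            reference_icv_mm3=payload["reference_icv_mm3"],
            feature_min=None if payload["feature_min"] is None
            else np.asarray(payload["feature_min"]),
            feature_max=None if payload["feature_max"] is None
            else np.asarray(payload["feature_max"]),
            fitted=payload["fitted"],
            metadata=payload.get("metadata", {}),
        )


def normalize_by_icv(volumes, icv_mm3: float):
    """Divide volumes by the participant's baseline ICV (dimensionless)."""
    if icv_mm3 <= 0:
        raise ValueError(f"icv must be > 0, got {icv_mm3}")
    return np.asarray(volumes, dtype=float) / float(icv_mm3)


def rescale_to_reference(normalized, transform: FeatureTransform):
    """Map ICV-normalised volumes onto the common reference-ICV mm^3 scale."""
    transform.validate()
    return np.asarray(normalized, dtype=float) * transform.reference_icv_mm3


def relative_distribution(volumes):
    """Regional proportions of total lesion volume (sum to 1).

    For a 2D input (rows = observations), zero-total rows are dropped and
    the surviving row indexer is returned alongside the proportions; the
    exclusion is logged. A zero-total 1D input raises.
    """
    arr = np.asarray(volumes, dtype=float)
    if arr.ndim == 1:
        total = arr.sum()
        if total <= 0:
            raise ValueError("total lesion volume is 0; proportions undefined")
        return arr / total
    totals = arr.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.info("relative_distribution: excluded %d zero-total rows",
                    int((~keep).sum()))
    return arr[keep] / totals[keep, None], keep


def fit_transform_features(proportions, reference_icv_mm3: float = 1.0
                           ) -> tuple[FeatureTransform, np.ndarray]:
    """Fit sqrt + per-feature min-max scaling and return the feature matrix.

    Constant features scale to 0 (with a warning in metadata). The stored
    extrema let :func:`apply_transform` place out-of-sample data in the same
    [0,1] space.
    """
    X = np.asarray(proportions, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D proportions array with >= 2 rows")
    root = np.sqrt(X)
    fmin = root.min(axis=0)
    fmax = root.max(axis=0)
    n_constant = int((fmax == fmin).sum())
    if n_constant:
        logger.warning("fit_transform_features: %d constant features scaled "
                       "to 0", n_constant)
    transform = FeatureTransform(
        reference_icv_mm3=float(reference_icv_mm3),
        feature_min=fmin, feature_max=fmax, fitted=True,
        metadata={"n_constant_features": n_constant,
                  "n_fit_rows": int(X.shape[0])},
    )
    features, _ = apply_transform(transform, X)
    return transform, features


def apply_transform(transform: FeatureTransform, proportions
                    ) -> tuple[np.ndarray, int]:
    """Transform proportions with fitted parameters; clip out-of-range.

    Returns the feature matrix and the count of clipped entries (also
    recorded in ``transform.metadata['last_clip_count']``) so extrapolation
    beyond the fitting range is never silent.
    """
    transform.validate()
    X = np.asarray(proportions, dtype=float)
    root = np.sqrt(X)
    span = transform.feature_max - transform.feature_min
    safe = np.where(span > 0, span, 1.0)
    scaled = (root - transform.feature_min) / safe
    scaled[:, span == 0] = 0.0
    clipped = np.clip(scaled, 0.0, 1.0)
    n_clipped = int((scaled != clipped).sum())
    transform.metadata["last_clip_count"] = n_clipped
    return clipped, n_clipped


def cohort_feature_matrix(df: pd.DataFrame, transform: FeatureTransform | None
                          = None) -> tuple[FeatureTransform, np.ndarray,
                                           np.ndarray]:
    """Convenience: cohort rows -> clustering features.

    Computes regional proportions (excluding zero-total rows), then either
    fits a new transform on them (``transform=None``; the reference ICV is
    the median baseline ICV of the included rows) or applies a fitted one.
    Returns ``(transform, features, keep_mask)`` where ``keep_mask`` aligns
    feature rows with ``df`` rows.
    """
    vols = df[list(REGION_COLUMNS)].to_numpy(dtype=float)
    props, keep = relative_distribution(vols)
    if transform is None:
        ref = float(np.median(df.loc[keep, "icv_mm3"]))
        transform, feats = fit_transform_features(props, reference_icv_mm3=ref)
    else:
        feats, _ = apply_transform(transform, props)
    return transform, feats, keep
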