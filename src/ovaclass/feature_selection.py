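"""Correlation-distance ranking of extracted features against the class label.

Two distance variants are provided.  ``pearson_distance`` is d = 1 - |r|
with r the Pearson correlation (the absolute value makes anti-correlated
features count as relevant).  ``distance_correlation`` is 1 - dCor(x, y)
with dCor the Szekely distance correlation, dCor = dCov / sqrt(dVar_X
dVar_Y), computed from double-centered pairwise distance matrices; unlike
Pearson correlation it also captures non-linear association.

Features with the *smallest* distance to the label vector are the most
label-associated and are the ones kept (default k = 45, the study's
selected feature count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .feature_extraction import FeatureMatrix

__all__ = [
    "SelectedFeatureSet",
    "correlation_distance",
    "select_by_correlation_distance",
    "DEFAULT_K",
]

DEFAULT_K = 45

DistanceMethod = Literal["pearson_distance", "distance_correlation"]


@dataclass
class SelectedFeatureSet:
    """Result of correlation-distance feature selection.

    ``kept_idx`` is ordered by ascending distance, ties broken by lower
    feature index.  ``distances`` covers every candidate feature.
    """

    kept_idx: np.ndarray
    distances: np.ndarray
    method: str

    @property
    def k(self) -> int:
        return self.kept_idx.size


def _dcor(x: np.ndarray, y: np.ndarray) -> float:
    """Szekely distance correlation via double-centered distance matrices."""
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = float((A * B).mean())
    dvar_x = float((A * A).mean())
    dvar_y = float((B * B).mean())
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def correlation_distance(
    x: np.ndarray, y: np.ndarray, method: DistanceMethod = "pearson_distance"
) -> float:
    """Distance d = 1 - a between two vectors, a being their correlation.

    ``pearson_distance`` uses |Pearson r| (range [0, 1]); a constant ``x``
    has distance 1 by convention.  ``distance_correlation`` uses the Szekely
    distance correlation.  Vectors must have equal length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError(
            f"length mismatch: x has {x.size} elements, y has {y.size}"
        )
    if x.size < 3:
        raise ConfigurationError("correlation distance needs vectors of length >= 3")
    if method == "pearson_distance":
        if np.std(x) == 0 or np.std(y) == 0:
            return 1.0
        r = float(stats.pearsonr(x, y)[0])
        return float(np.clip(1.0 - abs(r), 0.0, 1.0))
    if method == "distance_correlation":
        return float(np.clip(1.0 - _dcor(x, y), 0.0, 1.0))
    raise ConfigurationError(f"unknown correlation-distance method {method!r}")


def select_by_correlation_distance(
    f: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    k: int = DEFAULT_K,
    method: DistanceMethod = "pearson_distance",
) -> SelectedFeatureSet:
    """Keep the k features closest (in correlation distance) to the label.

    Distances are computed feature-vs-label across the provided (training)
    samples only; ties are broken by lower feature index.
    """
    values = f.values if isinstance(f, FeatureMatrix) else np.asarray(f, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_samples, n_features = values.shape
    if labels.shape != (n_samples,):
        raise ConfigurationError("labels length must equal the number of samples")
    if not 1 <= k <= n_features:
        raise ConfigurationError(f"k={k} out of range [1, {n_features}]")

    if method == "pearson_distance":
        # vectorized 1 - |r| over all features
        xc = values - values.mean(axis=0)
        yc = labels - labels.mean()
        sx = np.sqrt((xc**2).sum(axis=0))
        sy = float(np.sqrt((yc**2).sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc.T @ yc) / (sx * sy)
        distances = np.where(
            (sx == 0) | (sy == 0), 1.0, np.clip(1.0 - np.abs(r), 0.0, 1.0)
        )
    else:
        distances = np.array(
            [correlation_distance(values[:, j], labels, method) for j in range(n_features)]
        )

    order = np.lexsort((np.arange(n_features), distances))
    return SelectedFeatureSet(
        kept_idx=order[:k], distances=distances, method=method
    )
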