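"""Weighted pairwise dissimilarities between methylation profiles.

The plain Euclidean distance between two profiles treats every condition
equally; the weighted variant rescales each squared (or absolute)
coordinate difference by a per-pair reliability weight derived from read
coverage:

    d_w(i, j) = sqrt( sum_s w_{s,i,j} (m_{i,s} - m_{j,s})^2 )

with w >= 0 summing to 1 per pair.  With uniform weights (scheme kind
'none') this is the classic Euclidean distance divided by sqrt(S) — a
monotone transform, so clustering results are unchanged.  Squared
Euclidean and city-block variants are exposed as separate metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import MethylationMatrix
from .weighting import WeightingScheme, weights_for_pairs

__all__ = ["DistanceMatrix", "weighted_distance", "pairwise_matrix"]

METRICS = ("euclidean", "squared_euclidean", "cityblock")

#: refuse dense matrices beyond this many entities unless overridden
MAX_DENSE_ENTITIES = 20000


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with entity labels."""

    labels: np.ndarray
    values: np.ndarray
    metric: str = "euclidean"
    scheme: WeightingScheme | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square and match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be non-negative and finite")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle condensed form (scipy linkage input)."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]


def _metric_reduce(delta: np.ndarray, w: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.sqrt((w * delta**2).sum(axis=-1))
    if metric == "squared_euclidean":
        return (w * delta**2).sum(axis=-1)
    if metric == "cityblock":
        return (w * np.abs(delta)).sum(axis=-1)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def weighted_distance(x_i, x_j, w, metric: str = "euclidean") -> float:
    """Weighted dissimilarity between two profiles under normalized weights."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x_i.shape == x_j.shape == w.shape):
        raise ValueError("profiles and weights must have equal length")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be non-negative and sum to 1")
    return float(_metric_reduce(x_i - x_j, w, metric))


def pairwise_matrix(
    mat: MethylationMatrix,
    scheme: WeightingScheme | None = None,
    metric: str = "euclidean",
    axis: str = "sites",
    max_entities: int = MAX_DENSE_ENTITIES,
) -> DistanceMatrix:
    """Full symmetric pairwise distance matrix between sites or samples.

    For ``axis='sites'`` the entities are sites and each pair's weights are
    driven by the combined per-condition coverage of the two sites.  For
    ``axis='samples'`` values and coverage are transposed: entities are
    samples, and each pair's weights are driven per site-dimension by the
    combined coverage of the two samples at that site.

    An unresolved threshold scheme is resolved against this matrix's
    coverage (and the resolved threshold is recorded on the result).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if axis == "sites":
        X, C, labels = mat.values, mat.coverage, mat.site_ids
    elif axis == "samples":
        X, C, labels = mat.values.T, mat.coverage.T, np.asarray(mat.samples, dtype=object)
    else:
        raise ValueError("axis must be 'sites' or 'samples'")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 entities for pairwise distances")
    if n > max_entities:
        raise ValueError(
            f"{n} entities exceed the dense-matrix cap of {max_entities}; "
            "raise max_entities explicitly if this is intended"
        )
    if scheme is None:
        scheme = WeightingScheme(kind="none")
    scheme = scheme.resolve(C)

    D = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        v = C[i] + C[i + 1 :]                     # (n-i-1, S) pair coverage
        w = weights_for_pairs(v, scheme)
        d = _metric_reduce(X[i] - X[i + 1 :], w, metric)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return DistanceMatrix(labels=labels, values=D, metric=metric, scheme=scheme)
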