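"""Reliability weights for pairwise profile comparisons.

A methylation level estimated from few reads is noisy; one estimated from
many reads is precise.  When comparing two sites (or two samples), each
coordinate of the difference should therefore count in proportion to how
reliably both endpoints were measured there.  The combined coverage of a
pair in condition s,

    v_s = t_{i,s} + c_{i,s} + t_{j,s} + c_{j,s},

drives two weighting schemes:

* logarithm: raw weight log(v_s + 1), so reliability saturates — the jump
  from 2 to 200 reads matters far more than from 1002 to 1202;
* threshold: raw weight 1 when v_s reaches a count threshold, otherwise a
  reduced weight beta.  The threshold is parameterized as a quantile alpha
  of the empirical pairwise-coverage distribution, so alpha = 0.45 penalizes
  roughly the least-covered 45% of measurements.  beta > 1 is permitted as
  a negative control (it up-weights the unreliable measurements).

Raw weights are always normalized to sum to 1 per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "WeightingScheme",
    "pair_coverage",
    "log_weights",
    "threshold_weights",
    "resolve_alpha",
]

KINDS = ("none", "logarithm", "threshold")


@dataclass(frozen=True)
class WeightingScheme:
    """A weighting scheme descriptor.

    kind : 'none' | 'logarithm' | 'threshold'
    alpha_quantile : quantile in [0, 1) of the pairwise-coverage
        distribution defining the count threshold (threshold kind only).
    beta : weight (>= 0) given to below-threshold measurements; values > 1
        are allowed as a negative control.
    pair_sample_size, seed : control the subsampling used to resolve the
        quantile on large datasets.
    resolved_count_threshold : the count threshold after resolution against
        a dataset; ``None`` until :meth:`resolve` is called.
    """

    kind: str = "none"
    alpha_quantile: float = 0.45
    beta: float = 0.09
    pair_sample_size: int = 100_000
    seed: int = 0
    resolved_count_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "threshold":
            if not (0 <= self.alpha_quantile < 1):
                raise ValueError("alpha_quantile must lie in [0, 1)")
            if self.beta < 0:
                raise ValueError("beta must be non-negative")

    @property
    def is_resolved(self) -> bool:
        return self.kind != "threshold" or self.resolved_count_threshold is not None

    def resolve(self, coverage: np.ndarray) -> "WeightingScheme":
        """Resolve the alpha quantile into a count threshold for a dataset.

        ``coverage`` is the per-entity, per-condition coverage matrix
        (rows are the entities being clustered).  No-op for non-threshold
        kinds or already-resolved schemes.
        """
        if self.kind != "threshold" or self.resolved_count_threshold is not None:
            return self
        thr = resolve_alpha(
            self.alpha_quantile,
            coverage,
            n_pairs_sampled=self.pair_sample_size,
            seed=self.seed,
        )
        return replace(self, resolved_count_threshold=thr)


def pair_coverage(coverage_i: np.ndarray, coverage_j: np.ndarray) -> np.ndarray:
    """Combined per-condition coverage of a pair of entities."""
    vi = np.asarray(coverage_i)
    vj = np.asarray(coverage_j)
    if vi.shape != vj.shape:
        raise ValueError("coverage vectors must have equal length")
    if np.any(vi < 0) or np.any(vj < 0):
        raise ValueError("coverage must be non-negative")
    return vi + vj


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Normalize raw weights to sum to 1 along the last axis.

    An all-zero raw vector (no information anywhere) falls back to uniform
    weights so a pair always has a defined distance.
    """
    raw = np.asarray(raw, dtype=float)
    total = raw.sum(axis=-1, keepdims=True)
    S = raw.shape[-1]
    uniform = np.full(S, 1.0 / S)
    safe = np.where(total > 0, total, 1.0)
    # force C order so downstream reductions sum in a fixed order and
    # equal weights give bit-identical distances across schemes
    return np.ascontiguousarray(np.where(total > 0, raw / safe, uniform))


def log_weights(v: np.ndarray) -> np.ndarray:
    """Logarithm-scheme weights: w_s proportional to log(v_s + 1).

    The normalized result is independent of the logarithm base.  A pair
    with zero coverage everywhere gets uniform weights.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("coverage must be non-negative")
    return _normalize(np.log(v + 1.0))


def threshold_weights(v: np.ndarray, count_threshold: float, beta: float) -> np.ndarray:
    """Threshold-scheme weights: raw 1 at or above the threshold, beta below."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("coverage must be non-negative")
    raw = np.where(v >= count_threshold, 1.0, float(beta))
    return _normalize(raw)


def resolve_alpha(
    alpha_quantile: float,
    coverage: np.ndarray,
    n_pairs_sampled: int = 100_000,
    seed: int = 0,
    exact_max_n: int = 2000,
) -> float:
    """Resolve a quantile parameter into a pairwise-coverage count threshold.

    The threshold is the empirical ``alpha_quantile`` of the distribution
    of pairwise coverage sums v_{s,i,j} over all unordered entity pairs
    (i, j) and all conditions s — computed exactly when the number of
    entities is at most ``exact_max_n``, otherwise over ``n_pairs_sampled``
    seeded random pairs.  The quantile uses linear interpolation between
    order statistics (numpy's default), pinned for reproducibility.

    alpha_quantile = 0 resolves to 0, so no measurement is ever penalized.
    """
    if not (0 <= alpha_quantile < 1):
        raise ValueError("alpha_quantile must lie in [0, 1)")
    cov = np.atleast_2d(np.asarray(coverage))
    n = cov.shape[0]
    if cov.size == 0 or n < 2:
        raise ValueError("need at least two entities to form pairs")
    if alpha_quantile == 0:
        return 0.0
    if n <= exact_max_n:
        iu, ju = np.triu_indices(n, k=1)
        sums = cov[iu] + cov[ju]
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=n_pairs_sampled)
        j = rng.integers(0, n - 1, size=n_pairs_sampled)
        j = np.where(j >= i, j + 1, j)  # exclude self-pairs
        sums = cov[i] + cov[j]
    return float(np.quantile(sums.ravel(), alpha_quantile))


def weights_for_pairs(
    v: np.ndarray, scheme: WeightingScheme
) -> np.ndarray:
    """Normalized weights for an array of pairwise coverage vectors.

    ``v`` has shape (..., S); the result has the same shape and sums to 1
    along the last axis.  The scheme must be resolved for the threshold
    kind.
    """
    if scheme.kind == "none":
        S = v.shape[-1]
        ones = np.ones(v.shape, dtype=float)
        return _normalize(ones)
    if scheme.kind == "logarithm":
        return log_weights(v)
    if not scheme.is_resolved:
        raise ValueError("threshold scheme must be resolved against a dataset first")
    return threshold_weights(v, scheme.resolved_count_threshold, scheme.beta)
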