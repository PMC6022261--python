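"""Methylation-level quantification and matrix preprocessing.

The methylation level of a site under one condition is the depth-corrected
IP fraction

    m = (t / d_t) / (t / d_t + c / d_c)

which lies in [0, 1] (a beta value); an M-value log-ratio alternative is
also provided.  The preprocessing pipeline mirrors standard practice for
clustering methylation profiles: quantile normalization across samples,
selection of sites with strong signal and strong dynamics, and per-site
standardization so every site contributes equally to distances.

Coverage (t + c) is carried alongside the values at every stage: the
reliability-weighting layer needs it, and subsetting must keep the two
aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .counts import MeripCountSet, estimate_size_factors, merge_replicates

__all__ = [
    "MethylationMatrix",
    "methylation_level",
    "m_value",
    "quantile_normalize",
    "select_dynamic_sites",
    "standardize_rows",
    "quantify_counts",
    "preprocess",
]


@dataclass
class MethylationMatrix:
    """A site-by-condition methylation matrix with aligned coverage.

    ``values`` are on the beta scale in [0, 1] (``scale='beta'``), the
    M-value scale (``scale='m'``) or standardized z-scale (``scale='z'``).
    ``stage`` records how far through the pipeline the matrix is:
    raw | quantile_normalized | selected | standardized.
    """

    site_ids: np.ndarray
    gene_ids: np.ndarray
    samples: list[str]
    values: np.ndarray
    coverage: np.ndarray
    stage: str = "raw"
    scale: str = "beta"

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.coverage = np.asarray(self.coverage)
        if self.values.shape != self.coverage.shape:
            raise ValueError("values and coverage must be aligned")
        if self.values.shape[0] != len(self.site_ids):
            raise ValueError("site_ids length must match values rows")
        if self.values.shape[1] != len(self.samples):
            raise ValueError("samples length must match values columns")
        if self.scale == "beta" and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValueError("beta-scale values must lie in [0, 1]")
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, row_idx: np.ndarray) -> "MethylationMatrix":
        return replace(
            self,
            site_ids=self.site_ids[row_idx],
            gene_ids=self.gene_ids[row_idx],
            values=self.values[row_idx],
            coverage=self.coverage[row_idx],
        )


def methylation_level(t, c, d_t=1.0, d_c=1.0):
    """Depth-corrected methylation level m = (t d_c) / (t d_c + c d_t).

    With equal size factors this reduces to the familiar beta value
    t / (t + c).  A measurement with zero coverage (t = c = 0) carries no
    signal at all; the uninformative midpoint 0.5 is returned for it, and
    callers are expected to let the weighting layer suppress it via its
    zero coverage rather than drop the site.

    Accepts scalars or broadcastable arrays.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    d_t = np.asarray(d_t, dtype=float)
    d_c = np.asarray(d_c, dtype=float)
    if np.any(t < 0) or np.any(c < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(d_t <= 0) or np.any(d_c <= 0):
        raise ValueError("size factors must be positive")
    num = t * d_c
    den = t * d_c + c * d_t
    with np.errstate(invalid="ignore"):
        m = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    return m if m.ndim else float(m)


def m_value(t, c, d_t=1.0, d_c=1.0, eps: float = 0.5):
    """Log2-ratio methylation status M = log2((t/d_t + eps) / (c/d_c + eps)).

    The additive offset ``eps`` keeps zero counts finite.  M is unbounded
    and antisymmetric under swapping the IP and input roles.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    d_t = np.asarray(d_t, dtype=float)
    d_c = np.asarray(d_c, dtype=float)
    if np.any(t < 0) or np.any(c < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(d_t <= 0) or np.any(d_c <= 0):
        raise ValueError("size factors must be positive")
    out = np.log2((t / d_t + eps) / (c / d_c + eps))
    return out if out.ndim else float(out)


def quantify_counts(counts: MeripCountSet, scale: str = "beta", eps: float = 0.5) -> MethylationMatrix:
    """Turn a (merged, size-factored) count set into a raw methylation matrix."""
    if counts.d_t is None or counts.d_c is None:
        counts = estimate_size_factors(counts)
    if scale == "beta":
        vals = methylation_level(counts.t, counts.c, counts.d_t, counts.d_c)
    elif scale == "m":
        vals = m_value(counts.t, counts.c, counts.d_t, counts.d_c, eps=eps)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return MethylationMatrix(
        site_ids=counts.site_ids,
        gene_ids=counts.gene_ids,
        samples=list(counts.samples),
        values=vals,
        coverage=counts.coverage,
        stage="raw",
        scale=scale,
    )


def quantile_normalize(mat: MethylationMatrix) -> MethylationMatrix:
    """Force every sample column onto a common empirical distribution.

    The reference distribution is the mean of the column-sorted values;
    each column's values are replaced by the reference value at their rank,
    tied observations receiving the mean reference value of the tied ranks.
    Removes sample-level batch/depth effects while preserving within-column
    rank order.
    """
    X = mat.values
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        # average ranks; half-integer ranks land exactly on the mean of the
        # two adjacent reference values via linear interpolation
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, X.shape[0] + 1), reference)
    return replace(mat, values=out, stage="quantile_normalized",
                   scale="beta" if mat.scale == "beta" else mat.scale)


def select_dynamic_sites(
    mat: MethylationMatrix, n_by_mean: int = 20000, n_by_variance: int = 10000
) -> MethylationMatrix:
    """Two-stage selection of sites with strong signal and strong dynamics.

    Stage 1 keeps the ``n_by_mean`` sites with the largest row mean
    (strong methylation signal); stage 2 keeps, among those, the
    ``n_by_variance`` sites with the largest row variance (strong dynamics
    across conditions).  Ties are broken by input order and the retained
    sites keep their original order.
    """
    if n_by_mean <= 0:
        raise ValueError("n_by_mean must be positive")
    if n_by_variance > n_by_mean:
        raise ValueError("n_by_variance must not exceed n_by_mean")
    X = mat.values
    means = X.mean(axis=1)
    # stable sort on -means keeps input order among ties
    stage1 = np.argsort(-means, kind="stable")[: min(n_by_mean, len(means))]
    stage1 = np.sort(stage1)
    variances = X[stage1].var(axis=1, ddof=1)
    stage2 = np.argsort(-variances, kind="stable")[: min(n_by_variance, len(stage1))]
    keep = np.sort(stage1[stage2])
    out = mat.subset(keep)
    return replace(out, stage="selected")


def standardize_rows(mat: MethylationMatrix) -> MethylationMatrix:
    """Per-site z-scores: subtract the row mean, divide by the row sample sd.

    Every site then contributes equally to profile distances.  A constant
    row has no dynamics to standardize and is an error; callers that expect
    degenerate rows (tiny simulated datasets) should drop them first.
    """
    X = mat.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = ", ".join(map(str, mat.site_ids[flat[:5]]))
        raise ValueError(f"constant methylation profile for site(s): {names}")
    return replace(mat, values=(X - mu) / sd, stage="standardized", scale="z")


def drop_constant_rows(mat: MethylationMatrix) -> MethylationMatrix:
    """Remove sites whose profile is constant across samples."""
    sd = mat.values.std(axis=1, ddof=1)
    return mat.subset(np.flatnonzero(sd > 0))


def preprocess(
    raw: MeripCountSet,
    n_by_mean: int = 20000,
    n_by_variance: int = 10000,
    scale: str = "beta",
    merge: bool = True,
    drop_constant: bool = False,
) -> MethylationMatrix:
    """Full pipeline: merge replicates, estimate size factors, quantify,
    quantile normalize, select dynamic sites, standardize.

    ``merge=False`` skips replicate merging (used when the raw samples are
    themselves the entities, e.g. the sample-label benchmark).
    ``drop_constant=True`` silently removes zero-variance profiles before
    standardization instead of raising.
    """
    counts = merge_replicates(raw) if merge else raw
    counts = estimate_size_factors(counts)
    mat = quantify_counts(counts, scale=scale)
    mat = quantile_normalize(mat)
    mat = select_dynamic_sites(mat, n_by_mean=n_by_mean, n_by_variance=n_by_variance)
    if drop_constant:
        mat = drop_constant_rows(mat)
    return standardize_rows(mat)
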