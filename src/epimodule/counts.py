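"""Containers for MeRIP-seq site-level read counts.

A MeRIP-seq (m6A-seq) experiment yields, for every methylation site and
every library, an IP read count (immunoprecipitated, methylation-enriched
fragments) and an input read count (background RNA).  The per-site,
per-condition pair (t, c) is the raw substrate from which methylation
levels are estimated; per-library size factors correct for sequencing
depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["MeripCountSet", "merge_replicates", "estimate_size_factors"]


@dataclass
class MeripCountSet:
    """Per-site IP/input read counts across samples.

    Parameters
    ----------
    site_ids : array of str
        Unique ordered site identifiers.
    gene_ids : array of str
        Per-site gene label (carried for enrichment analysis; never
        computed here).
    samples : list of str
        Column labels.  Before replicate merging these are raw sample
        names; after merging they are condition names.
    t, c : int arrays, shape (n_sites, n_samples)
        IP and input read counts.
    condition_of_replicate : mapping, optional
        Raw sample name -> condition name.  Consumed by
        :func:`merge_replicates`.
    d_t, d_c : float arrays, optional
        Per-sample size factors for the IP and input libraries.  ``None``
        until estimated.
    """

    site_ids: np.ndarray
    gene_ids: np.ndarray
    samples: list[str]
    t: np.ndarray
    c: np.ndarray
    condition_of_replicate: dict[str, str] | None = None
    d_t: np.ndarray | None = None
    d_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.samples = list(self.samples)
        self.t = np.asarray(self.t)
        self.c = np.asarray(self.c)
        n, s = self.t.shape
        if self.c.shape != (n, s):
            raise ValueError("t and c must have identical shapes")
        if len(self.site_ids) != n or len(self.gene_ids) != n:
            raise ValueError("site_ids/gene_ids length must match rows of t")
        if len(self.samples) != s:
            raise ValueError("samples length must match columns of t")
        if len(set(self.site_ids)) != n:
            raise ValueError("duplicate site_ids")
        for name, arr in (("t", self.t), ("c", self.c)):
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.equal(np.mod(arr, 1), 0)):
                    raise ValueError(f"{name} must contain integers")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
        self.t = self.t.astype(np.int64)
        self.c = self.c.astype(np.int64)
        for name, d in (("d_t", self.d_t), ("d_c", self.d_c)):
            if d is not None:
                d = np.asarray(d, dtype=float)
                if d.shape != (s,):
                    raise ValueError(f"{name} must have one entry per sample")
                if np.any(d <= 0):
                    raise ValueError(f"{name} must be positive")
                setattr(self, name, d)

    @property
    def n_sites(self) -> int:
        return self.t.shape[0]

    @property
    def n_samples(self) -> int:
        return self.t.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        """Per-measurement read coverage v = t + c."""
        return self.t + self.c


def merge_replicates(
    counts: MeripCountSet, conditions: Sequence[str] | None = None
) -> MeripCountSet:
    """Sum IP and input counts over biological replicates of each condition.

    Replicate columns mapping to the same condition (via
    ``counts.condition_of_replicate``) are added element-wise, yielding one
    IP and one input column per condition.

    Parameters
    ----------
    counts : MeripCountSet
        Count set whose columns are raw replicate samples.
    conditions : sequence of str, optional
        Output condition order.  Defaults to first-appearance order in the
        replicate map.  A listed condition with no replicate column is an
        error.
    """
    cmap = counts.condition_of_replicate
    if cmap is None:
        raise ValueError("condition_of_replicate map is required for merging")
    missing = [s for s in counts.samples if s not in cmap]
    if missing:
        raise ValueError(f"samples with no condition assignment: {missing}")
    unknown = [s for s in cmap if s not in counts.samples]
    if unknown:
        raise ValueError(f"condition map references unknown samples: {unknown}")
    if conditions is None:
        seen: dict[str, None] = {}
        for s in counts.samples:
            seen.setdefault(cmap[s], None)
        conditions = list(seen)
    cols: dict[str, list[int]] = {cond: [] for cond in conditions}
    for j, s in enumerate(counts.samples):
        cond = cmap[s]
        if cond not in cols:
            raise ValueError(f"sample {s!r} maps to unlisted condition {cond!r}")
        cols[cond].append(j)
    empty = [cond for cond, js in cols.items() if not js]
    if empty:
        raise ValueError(f"conditions with zero replicates: {empty}")
    t = np.column_stack([counts.t[:, cols[cond]].sum(axis=1) for cond in conditions])
    c = np.column_stack([counts.c[:, cols[cond]].sum(axis=1) for cond in conditions])
    return MeripCountSet(
        site_ids=counts.site_ids,
        gene_ids=counts.gene_ids,
        samples=list(conditions),
        t=t,
        c=c,
    )


def estimate_size_factors(counts: MeripCountSet) -> MeripCountSet:
    """Estimate per-sample size factors from library totals.

    The factor for a library is its total read count divided by the mean
    total over libraries of the same kind (IP or input), so factors are
    dimensionless and average to 1.

    Returns a copy of `counts` with ``d_t`` and ``d_c`` set.
    """
    d_t = _totals_to_factors(counts.t, "IP")
    d_c = _totals_to_factors(counts.c, "input")
    return replace(counts, d_t=d_t, d_c=d_c)


def _totals_to_factors(mat: np.ndarray, kind: str) -> np.ndarray:
    totals = mat.sum(axis=0).astype(float)
    if np.any(totals == 0):
        bad = np.flatnonzero(totals == 0).tolist()
        raise ValueError(f"all-zero {kind} column(s) at index {bad}: cannot size-normalize")
    return totals / totals.mean()
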