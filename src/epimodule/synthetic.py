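"""Seeded simulation of MeRIP-seq-like count data with planted structure.

The generator emulates the statistical features of real m6A-seq count
data that matter for coverage-weighted clustering:

* sites fall into modules sharing a condition-specific methylation
  profile pi[k, s] (the co-regulation signature a clustering method
  should recover);
* read coverage is strongly heterogeneous — a log-normal spread of
  per-site expression plus a sizable fraction of sites with only a
  handful of reads, whose estimated methylation level is essentially
  noise;
* for each measurement, a total read count T is drawn Poisson and split
  binomially between IP and input with probability equal to the site's
  methylation level, so the estimator m = t/(t+c) is unbiased with
  variance shrinking as 1/T — exactly the reliability structure the
  weighting schemes presuppose;
* a benchmark mode produces 6-sample (two conditions, three replicates
  each) datasets with a planted group shift, mirroring a
  treatment-versus-control MeRIP-seq design with known sample labels.

All randomness flows from one root seed through named substreams, so
counts, jitter and annotations are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .counts import MeripCountSet
from .enrichment import AnnotationTable
from .quantify import MethylationMatrix, preprocess

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "simulate_counts",
    "make_sample_benchmark",
    "benchmark_dataset",
    "make_annotation",
]

_STREAMS = {"profiles": 1, "jitter": 2, "expression": 3, "counts": 4, "annotation": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SyntheticSpec:
    """Parameters of the site-module simulation.

    n_sites, n_conditions, n_modules set the dimensions; module_sizes
    (default: near-equal split) must sum to n_sites.  module_profiles is
    a (K, S) matrix of methylation levels in (0, 1); by default profiles
    are drawn uniformly from (0.1, 0.9) per seed.  Per-site mean coverage
    lambda is log-normal(mu_log, sigma_log) (default median 100 reads).
    Gene expression is context-specific: a ``low_coverage_fraction`` of
    individual measurements (site-condition cells, chosen uniformly)
    instead get coverage around ``low_coverage_lambda`` reads, and those
    weak measurements additionally scatter around the true methylation
    level with a Beta perturbation of concentration
    ``artifact_concentration`` — the background-dominated artifacts that
    make lowly covered estimates unreliable.  ``jitter_concentration``
    controls the per-site Beta perturbation around the module profile
    (larger = tighter).
    """

    n_sites: int = 2000
    n_conditions: int = 9
    n_modules: int = 5
    module_sizes: Sequence[int] | None = None
    module_profiles: np.ndarray | None = None
    mu_log: float = float(np.log(100.0))
    sigma_log: float = 1.0
    depth: Sequence[float] | None = None
    low_coverage_fraction: float = 0.45
    low_coverage_lambda: float = 2.0
    low_coverage_sigma: float = 0.5
    artifact_concentration: float = 2.0
    jitter_concentration: float = 150.0
    min_profile_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_conditions < 2 or self.n_modules < 1:
            raise ValueError("need n_sites >= 2, n_conditions >= 2, n_modules >= 1")
        if self.module_sizes is None:
            base = self.n_sites // self.n_modules
            sizes = [base] * self.n_modules
            for i in range(self.n_sites - base * self.n_modules):
                sizes[i] += 1
            self.module_sizes = sizes
        self.module_sizes = list(self.module_sizes)
        if sum(self.module_sizes) != self.n_sites:
            raise ValueError("module_sizes must sum to n_sites")
        if self.module_profiles is not None:
            self.module_profiles = np.asarray(self.module_profiles, dtype=float)
            if self.module_profiles.shape != (self.n_modules, self.n_conditions):
                raise ValueError("module_profiles must be (n_modules, n_conditions)")
            if np.any(self.module_profiles <= 0) or np.any(self.module_profiles >= 1):
                raise ValueError("module_profiles must lie in (0, 1)")
        if not (0 <= self.low_coverage_fraction <= 1):
            raise ValueError("low_coverage_fraction must lie in [0, 1]")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if self.depth.shape != (self.n_conditions,) or np.any(self.depth <= 0):
                raise ValueError("depth must be positive, one entry per condition")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated count set."""

    site_modules: np.ndarray | None = None
    sample_groups: np.ndarray | None = None
    module_profiles: np.ndarray | None = None
    low_coverage_mask: np.ndarray | None = None


def _jittered_profiles(
    pi: np.ndarray, assignment: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-site Beta perturbation around the module profile (same mean)."""
    mean = pi[assignment]  # (N, S)
    a = np.clip(mean * concentration, 1e-6, None)
    b = np.clip((1.0 - mean) * concentration, 1e-6, None)
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def _draw_separated_profiles(
    rng: np.random.Generator, K: int, S: int, min_sep: float, max_tries: int = 1000
) -> np.ndarray:
    """Draw K module profiles in (0.1, 0.9)^S with pairwise Euclidean
    separation >= min_sep.

    Modules model distinct regulatory programs; profiles closer than the
    within-module noise would not be distinct modules in any meaningful
    sense.  Offending profiles are redrawn one at a time.
    """
    pi = rng.uniform(0.1, 0.9, size=(K, S))
    for _ in range(max_tries):
        d = np.sqrt(((pi[:, None, :] - pi[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        bad = np.flatnonzero(d.min(axis=1) < min_sep)
        if bad.size == 0:
            return pi
        pi[bad[0]] = rng.uniform(0.1, 0.9, size=S)
    raise RuntimeError(
        f"could not place {K} module profiles with separation {min_sep} "
        f"in {S} dimensions; lower min_profile_separation"
    )


def simulate_counts(spec: SyntheticSpec) -> tuple[MeripCountSet, SyntheticTruth]:
    """Simulate a site-by-condition IP/input count set with planted modules."""
    K, N, S = spec.n_modules, spec.n_sites, spec.n_conditions
    pi = spec.module_profiles
    if pi is None:
        min_sep = spec.min_profile_separation
        if min_sep is None:
            # scale with sqrt(S) so the constraint is equally demanding
            # per condition regardless of dimensionality
            min_sep = 0.25 * np.sqrt(S)
        pi = _draw_separated_profiles(_rng(spec.seed, "profiles"), K, S, min_sep)
    assignment = np.repeat(np.arange(K), spec.module_sizes)

    rng_expr = _rng(spec.seed, "expression")
    lam = np.broadcast_to(
        rng_expr.lognormal(spec.mu_log, spec.sigma_log, size=N)[:, None], (N, S)
    ).copy()
    # context-specific expression: a fraction of individual measurements
    # fall on conditions where the gene is lowly expressed
    n_low = int(round(spec.low_coverage_fraction * N * S))
    flat = rng_expr.choice(N * S, size=n_low, replace=False)
    low_mask = np.zeros(N * S, dtype=bool)
    low_mask[flat] = True
    low_mask = low_mask.reshape(N, S)
    lam[low_mask] = rng_expr.lognormal(
        np.log(spec.low_coverage_lambda), spec.low_coverage_sigma, size=n_low
    )

    rng_jitter = _rng(spec.seed, "jitter")
    p = _jittered_profiles(pi, assignment, spec.jitter_concentration, rng_jitter)
    # weak measurements are artifact-dominated beyond sampling noise
    a = np.clip(p[low_mask] * spec.artifact_concentration, 1e-6, None)
    b = np.clip((1 - p[low_mask]) * spec.artifact_concentration, 1e-6, None)
    p[low_mask] = np.clip(rng_jitter.beta(a, b), 1e-6, 1 - 1e-6)

    depth = spec.depth if spec.depth is not None else np.ones(S)
    rng_counts = _rng(spec.seed, "counts")
    T = rng_counts.poisson(lam * depth[None, :])
    t = rng_counts.binomial(T, p)
    c = T - t

    counts = MeripCountSet(
        site_ids=np.array([f"site{i:05d}" for i in range(N)], dtype=object),
        gene_ids=np.array([f"gene{i:05d}" for i in range(N)], dtype=object),
        samples=[f"cond{s + 1}" for s in range(S)],
        t=t,
        c=c,
    )
    truth = SyntheticTruth(
        site_modules=assignment,
        module_profiles=pi,
        low_coverage_mask=low_mask,
    )
    return counts, truth


def make_sample_benchmark(
    n_sites: int = 30,
    n_replicates_per_group: int = 3,
    low_coverage_fraction: float = 0.45,
    effect_size: float = 0.17,
    shift_fraction: float = 0.75,
    mu_log: float = float(np.log(30.0)),
    sigma_log: float = 0.25,
    low_coverage_lambda: float = 6.0,
    low_coverage_sigma: float = 0.5,
    artifact_concentration: float = 2.0,
    seed: int = 0,
) -> tuple[MeripCountSet, SyntheticTruth]:
    """Simulate a two-group replicate design with known sample labels.

    Two condition groups (e.g. treatment vs control) with
    ``n_replicates_per_group`` samples each; a random ``shift_fraction``
    of sites shift their methylation level between groups by
    ``effect_size`` (half up, half down, flipped where the level would
    leave (0, 1)).  A ``low_coverage_fraction`` of sites sit on lowly
    expressed genes: their coverage is drawn around
    ``low_coverage_lambda`` reads and — because weak signal is swamped by
    nonspecific background — each of their measurements scatters around
    the true level with a Beta perturbation of concentration
    ``artifact_concentration``, far beyond binomial sampling noise.
    Defaults produce the 30-site, 6-sample datasets of the exact-match
    sample-clustering benchmark.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if not (0 <= effect_size < 1):
        raise ValueError("effect_size must lie in [0, 1)")
    if not (0 <= low_coverage_fraction <= 1):
        raise ValueError("low_coverage_fraction must lie in [0, 1]")
    G = 2
    R = n_replicates_per_group
    n_samples = G * R

    rng_prof = _rng(seed, "profiles")
    base = rng_prof.uniform(0.2, 0.8, size=n_sites)
    n_shift = int(round(shift_fraction * n_sites))
    shift_idx = rng_prof.choice(n_sites, size=n_shift, replace=False)
    # hyper- and hypomethylation responses in equal proportion, so the
    # marginal value distribution is preserved across groups (quantile
    # normalization must not be able to erase the signal)
    direction = rng_prof.choice([-1.0, 1.0], size=n_shift)
    shifted = base[shift_idx] + direction * effect_size
    out_of_range = (shifted < 0.02) | (shifted > 0.98)
    shifted[out_of_range] = base[shift_idx][out_of_range] - (
        direction[out_of_range] * effect_size
    )
    pi = np.tile(base[:, None], (1, G))  # (N, 2) group-level methylation
    pi[shift_idx, 1] = np.clip(shifted, 0.02, 0.98)

    rng_expr = _rng(seed, "expression")
    lam = rng_expr.lognormal(mu_log, sigma_log, size=n_sites)
    n_low = int(round(low_coverage_fraction * n_sites))
    low_idx = rng_expr.choice(n_sites, size=n_low, replace=False)
    # lowly expressed genes span a continuum from near-zero to moderate
    # coverage; their methylation estimates range from pure noise to
    # misleadingly plausible
    lam[low_idx] = rng_expr.lognormal(
        np.log(low_coverage_lambda), low_coverage_sigma, size=n_low
    )

    groups = np.repeat(np.arange(G), R)
    rng_counts = _rng(seed, "counts")
    T = rng_counts.poisson(lam[:, None] * np.ones(n_samples)[None, :])
    p = pi[:, groups].copy()
    # measurements on lowly expressed genes are artifact-dominated: the
    # IP fraction scatters around the true level far beyond binomial
    # sampling noise (nonspecific background swamps the weak signal), so
    # even moderately covered low-expression sites are unreliable
    jitter = _rng(seed, "jitter")
    a = np.clip(p[low_idx] * artifact_concentration, 1e-6, None)
    b = np.clip((1 - p[low_idx]) * artifact_concentration, 1e-6, None)
    p[low_idx] = np.clip(jitter.beta(a, b), 1e-6, 1 - 1e-6)
    t = rng_counts.binomial(T, p)
    c = T - t

    samples = [f"g{g + 1}_rep{r + 1}" for g in range(G) for r in range(R)]
    counts = MeripCountSet(
        site_ids=np.array([f"site{i:05d}" for i in range(n_sites)], dtype=object),
        gene_ids=np.array([f"gene{i:05d}" for i in range(n_sites)], dtype=object),
        samples=samples,
        t=t,
        c=c,
        condition_of_replicate={s: s.split("_")[0] for s in samples},
    )
    low_mask = np.zeros(n_sites, dtype=bool)
    low_mask[low_idx] = True
    truth = SyntheticTruth(
        sample_groups=groups, module_profiles=pi.T, low_coverage_mask=low_mask
    )
    return counts, truth


def benchmark_dataset(
    n_sites: int = 30, seed: int = 0, **kwargs
) -> tuple[MethylationMatrix, np.ndarray]:
    """A ready-to-cluster benchmark dataset: preprocessed matrix + labels.

    Runs the standard preprocessing (size factors, methylation levels,
    quantile normalization, per-site standardization; no replicate
    merging — the raw samples are the entities to cluster, and no site
    selection — the dataset is already small) on a simulated two-group
    design.  Zero-variance profiles are dropped rather than raised on,
    since tiny simulated datasets can produce them.
    """
    counts, truth = make_sample_benchmark(n_sites=n_sites, seed=seed, **kwargs)
    mat = preprocess(
        counts,
        n_by_mean=counts.n_sites,
        n_by_variance=counts.n_sites,
        merge=False,
        drop_constant=True,
    )
    return mat, truth.sample_groups


def make_annotation(
    genes: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 100),
    seed: int = 0,
    planted_genes: Sequence[str] | None = None,
    planted_size: int | None = None,
    planted_frac: float = 1.0,
    planted_term_id: str = "TERM_PLANTED",
) -> AnnotationTable:
    """Random term↔gene annotation, optionally with one planted term.

    Each of ``n_terms`` terms draws a uniform-size gene set from
    ``genes``, independent of any module structure (a null annotation).
    If ``planted_genes`` is given, an extra term of ``planted_size``
    (default: the planted set's size) is built with a ``planted_frac``
    share drawn from the planted genes and the rest from the background,
    making that term genuinely over-represented in the planted set.
    """
    genes = list(dict.fromkeys(map(str, genes)))
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(genes)):
        raise ValueError("term_size_range must satisfy 1 <= lo <= hi <= n_genes")
    rng = _rng(seed, "annotation")
    terms: dict[str, frozenset] = {}
    width = len(str(max(n_terms, 1)))
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        draw = rng.choice(len(genes), size=size, replace=False)
        terms[f"TERM{i:0{width}d}"] = frozenset(genes[j] for j in draw)
    if planted_genes is not None:
        planted = list(dict.fromkeys(map(str, planted_genes)))
        missing = set(planted) - set(genes)
        if missing:
            raise ValueError("planted genes must come from the gene universe")
        size = planted_size if planted_size is not None else len(planted)
        n_in = min(int(round(planted_frac * size)), len(planted))
        inside = [planted[j] for j in rng.choice(len(planted), size=n_in, replace=False)]
        outside_pool = [g for g in genes if g not in planted]
        n_out = size - n_in
        if n_out > len(outside_pool):
            raise ValueError("planted term size exceeds available background genes")
        outside = [
            outside_pool[j]
            for j in rng.choice(len(outside_pool), size=n_out, replace=False)
        ]
        terms[planted_term_id] = frozenset(inside + outside)
    return AnnotationTable(terms=terms)
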