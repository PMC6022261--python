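"""Biological-significance scoring of modules by term over-representation.

A module is scored against a gene↔term annotation by a one-sided
hypergeometric test per term (is the term's gene set over-represented
among the module's genes relative to the background?), summing
-log10(p) over the 20 most significant terms.  Very broad terms (more
than ``max_term_count`` background genes) are discarded before ranking —
they are enriched almost anywhere and say little.  Because a raw score is
hard to read, a module is also compared against uniformly random site
sets of the same size: the fraction of random draws it beats is the
significance statement.  A 2x2 Fisher exact test covers the complementary
question of overlap with an externally defined target-site list (e.g.,
sites dependent on a particular methyltransferase subunit such as WTAP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

__all__ = [
    "AnnotationTable",
    "EnrichmentScore",
    "hypergeom_overrep_p",
    "module_significance",
    "compare_random_modules",
    "overlap_odds_ratio",
]


@dataclass
class AnnotationTable:
    """Term -> gene-set annotation (e.g., GO terms), file-supplied.

    ``terms`` maps term_id to a non-empty frozenset of gene ids;
    ``names`` and ``categories`` (BP/CC/MF tags) are optional metadata.
    """

    terms: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {
            str(t): frozenset(map(str, gs)) for t, gs in self.terms.items()
        }
        empty = [t for t, gs in self.terms.items() if not gs]
        if empty:
            raise ValueError(f"terms with empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        """Build from a long table with columns term_id, gene_id
        (optional term_name, category)."""
        if not {"term_id", "gene_id"}.issubset(df.columns):
            raise ValueError("annotation table needs term_id and gene_id columns")
        terms: dict[str, set] = {}
        names: dict[str, str] = {}
        categories: dict[str, str] = {}
        for row in df.itertuples(index=False):
            t = str(row.term_id)
            terms.setdefault(t, set()).add(str(row.gene_id))
            if hasattr(row, "term_name") and pd.notna(row.term_name):
                names[t] = str(row.term_name)
            if hasattr(row, "category") and pd.notna(row.category):
                categories[t] = str(row.category)
        return cls(
            terms={t: frozenset(g) for t, g in terms.items()},
            names=names, categories=categories,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self.terms):
            for g in sorted(self.terms[t]):
                rows.append(
                    dict(term_id=t, gene_id=g,
                         term_name=self.names.get(t, ""),
                         category=self.categories.get(t, ""))
                )
        return pd.DataFrame(rows)


@dataclass
class EnrichmentScore:
    """Per-term over-representation results plus the top-m summary score."""

    table: pd.DataFrame  # columns: term_id, k, K, n, N_bg, p, rank
    score: float
    top_m: int
    max_term_count: int


def hypergeom_overrep_p(k: int, K: int, n: int, N_bg: int) -> float:
    """One-sided over-representation p-value P(X >= k), X ~ Hypergeom.

    Drawing ``n`` genes (the module) without replacement from a background
    of ``N_bg`` genes of which ``K`` carry the term, the p-value is the
    probability of seeing ``k`` or more term genes in the draw.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N_bg or n > N_bg:
        raise ValueError("K and n cannot exceed the background size")
    return float(hypergeom.sf(k - 1, N_bg, K, n))


def module_significance(
    module_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation: AnnotationTable,
    top_m: int = 20,
    max_term_count: int = 1000,
) -> EnrichmentScore:
    """Score a module's biological significance against an annotation.

    Per surviving term (background count K <= ``max_term_count``) a
    one-sided hypergeometric p is computed; the score is the sum of
    -log10(p) over the ``top_m`` smallest p-values (ties broken by
    term_id).  A module identical to its background scores 0: nothing can
    be over-represented.
    """
    module = frozenset(map(str, module_genes))
    background = frozenset(map(str, background_genes))
    if not background:
        raise ValueError("background gene set is empty")
    if not module <= background:
        raise ValueError("module genes must be a subset of the background")
    N_bg, n = len(background), len(module)
    rows = []
    for term_id in sorted(annotation.terms):
        K = len(annotation.terms[term_id] & background)
        if K == 0 or K > max_term_count:
            continue
        k = len(annotation.terms[term_id] & module)
        p = hypergeom_overrep_p(k, K, n, N_bg)
        rows.append(dict(term_id=term_id, k=k, K=K, n=n, N_bg=N_bg, p=p))
    table = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N_bg", "p"])
    if len(table):
        table = table.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        score = float(-np.log10(table["p"].head(top_m)).sum())
    else:
        table["rank"] = pd.Series(dtype=int)
        score = 0.0
    return EnrichmentScore(table=table, score=score,
                           top_m=top_m, max_term_count=max_term_count)


def compare_random_modules(
    module_sites: Sequence[str],
    site_universe: Sequence[str],
    site_genes: Mapping[str, str],
    annotation: AnnotationTable,
    reps: int = 100,
    seed: int = 0,
    top_m: int = 20,
    max_term_count: int = 1000,
) -> float:
    """Fraction of random same-size site sets the module out-scores.

    For each repetition a uniform random set of sites of the module's size
    is drawn from the universe, both sets are mapped to (deduplicated)
    genes, and the two significance scores are compared; the return value
    is the fraction of repetitions where the module's score strictly
    exceeds the random module's.  Values well above 0.5 say the module is
    more biologically coherent than chance.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    module_sites = list(dict.fromkeys(map(str, module_sites)))
    universe = list(dict.fromkeys(map(str, site_universe)))
    if len(module_sites) > len(universe):
        raise ValueError("module cannot exceed the site universe")
    background = {str(site_genes[s]) for s in universe}
    module_genes = {str(site_genes[s]) for s in module_sites}
    mod_score = module_significance(
        module_genes, background, annotation, top_m, max_term_count
    ).score
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(reps):
        draw = rng.choice(len(universe), size=len(module_sites), replace=False)
        rand_genes = {str(site_genes[universe[i]]) for i in draw}
        rand_score = module_significance(
            rand_genes, background, annotation, top_m, max_term_count
        ).score
        wins += mod_score > rand_score
    return wins / reps


def overlap_odds_ratio(
    module_sites: Iterable[str],
    target_sites: Iterable[str],
    site_universe: Iterable[str],
) -> tuple[float, float]:
    """Odds ratio and one-sided Fisher p for module/target site overlap.

    The 2x2 table crosses membership in the module with membership in the
    target list over the site universe.  The odds ratio is ad/bc, with a
    Haldane 0.5 continuity correction applied only when a cell is zero;
    the p-value is the one-sided ('greater') Fisher exact test on the
    uncorrected table.
    """
    universe = frozenset(map(str, site_universe))
    if not universe:
        raise ValueError("site universe is empty")
    module = frozenset(map(str, module_sites))
    target = frozenset(map(str, target_sites))
    if not module <= universe or not target <= universe:
        raise ValueError("module and target sites must lie in the universe")
    a = len(module & target)
    b = len(module - target)
    c = len(target - module)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    _, p = fisher_exact(table, alternative="greater")
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds), float(p)
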