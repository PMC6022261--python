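"""Model/Results front end for epitranscriptome module detection.

`ModuleDetection` packages the whole procedure — replicate merging, size
factors, methylation levels, quantile normalization, dynamic-site
selection, standardization, coverage-weighted distances and hierarchical
clustering — behind a statsmodels-style interface: build the model from a
count set (or a counts DataFrame), call :meth:`fit` with the desired
number of modules, and read the estimates off the returned
:class:`ModuleDetectionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusteringResult, hierarchical_cluster, silhouette_mean
from .counts import MeripCountSet
from .distance import DistanceMatrix, pairwise_matrix
from .enrichment import AnnotationTable, EnrichmentScore, module_significance
from .quantify import MethylationMatrix, preprocess
from .weighting import WeightingScheme

__all__ = ["ModuleDetection", "ModuleDetectionResults"]


class ModuleDetection:
    """Coverage-weighted hierarchical module detection model.

    Parameters
    ----------
    counts : MeripCountSet
        Raw (replicate-level) or merged IP/input counts.
    scheme : WeightingScheme, optional
        Reliability-weighting scheme; defaults to the tuned threshold
        scheme (alpha = 0.45, beta = 0.09).
    metric, linkage : str
        Distance metric and agglomeration rule.
    n_by_mean, n_by_variance : int
        Two-stage dynamic-site selection sizes (top sites by mean
        methylation, then by variance).
    merge : bool
        Merge replicate columns by condition before quantification.
    """

    def __init__(
        self,
        counts: MeripCountSet,
        scheme: WeightingScheme | None = None,
        metric: str = "euclidean",
        linkage: str = "ward",
        n_by_mean: int = 20000,
        n_by_variance: int = 10000,
        scale: str = "beta",
        merge: bool = True,
        drop_constant: bool = False,
    ) -> None:
        self.counts = counts
        self.scheme = scheme if scheme is not None else WeightingScheme(
            kind="threshold", alpha_quantile=0.45, beta=0.09
        )
        self.metric = metric
        self.linkage = linkage
        self.n_by_mean = n_by_mean
        self.n_by_variance = n_by_variance
        self.scale = scale
        self.merge = merge
        self.drop_constant = drop_constant

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        condition_map: dict[str, str] | None = None,
        **kwargs,
    ) -> "ModuleDetection":
        """Build from a counts table with columns ``site_id``, ``gene_id``
        and paired ``IP_<sample>`` / ``INPUT_<sample>`` columns."""
        from .io import counts_from_frame

        return cls(counts_from_frame(df, condition_map), **kwargs)

    def fit(self, k: int = 5) -> "ModuleDetectionResults":
        """Run the pipeline and cut the dendrogram into ``k`` modules."""
        mat = preprocess(
            self.counts,
            n_by_mean=self.n_by_mean,
            n_by_variance=self.n_by_variance,
            scale=self.scale,
            merge=self.merge,
            drop_constant=self.drop_constant,
        )
        if not (2 <= k <= mat.n_sites):
            raise ValueError(f"k must lie in [2, {mat.n_sites}]")
        dist = pairwise_matrix(mat, scheme=self.scheme, metric=self.metric)
        tree = hierarchical_cluster(dist, linkage=self.linkage)
        labels = tree.labels(k)
        sil = silhouette_mean(dist, labels)
        return ModuleDetectionResults(
            model=self, matrix=mat, distance=dist, tree=tree,
            k=k, labels=labels, silhouette=sil,
        )


@dataclass
class ModuleDetectionResults:
    """Fitted module assignment with diagnostics.

    Attributes
    ----------
    matrix : the preprocessed (standardized) methylation matrix.
    distance : the weighted distance matrix actually clustered, whose
        ``scheme`` records the resolved count threshold.
    labels : flat module label per retained site (1..k).
    silhouette : mean silhouette coefficient of the k-cut; small values
        (the real-data regime is around 0.15) flag weak cluster structure.
    """

    model: ModuleDetection
    matrix: MethylationMatrix
    distance: DistanceMatrix
    tree: ClusteringResult
    k: int
    labels: np.ndarray
    silhouette: float
    _enrichment: dict = field(default_factory=dict, repr=False)

    @property
    def module_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def module_sites(self, module: int) -> np.ndarray:
        return self.matrix.site_ids[self.labels == module]

    def module_genes(self, module: int) -> list[str]:
        return sorted(set(self.matrix.gene_ids[self.labels == module]))

    def silhouette_profile(self, ks: range | list) -> pd.DataFrame:
        """Mean silhouette for alternative numbers of modules (model
        selection diagnostic)."""
        rows = []
        for k in ks:
            lab = self.tree.labels(int(k))
            rows.append(dict(k=int(k), silhouette=silhouette_mean(self.distance, lab)))
        return pd.DataFrame(rows)

    def enrich(
        self,
        annotation: AnnotationTable,
        module: int,
        top_m: int = 20,
        max_term_count: int = 1000,
    ) -> EnrichmentScore:
        """Hypergeometric significance score of one module against the
        background of all retained sites' genes."""
        background = set(self.matrix.gene_ids)
        return module_significance(
            self.module_genes(module), background, annotation,
            top_m=top_m, max_term_count=max_term_count,
        )

    def to_frame(self) -> pd.DataFrame:
        """site_id, gene_id, module label per retained site."""
        return pd.DataFrame(
            dict(
                site_id=self.matrix.site_ids,
                gene_id=self.matrix.gene_ids,
                module=self.labels,
            )
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        scheme = self.distance.scheme
        lines = [
            "Epitranscriptome module detection",
            "=" * 46,
            f"sites retained        {self.matrix.n_sites}",
            f"conditions            {self.matrix.n_samples}",
            f"modules (k)           {self.k}",
            f"metric / linkage      {self.model.metric} / {self.model.linkage}",
            f"weighting             {scheme.kind}",
        ]
        if scheme.kind == "threshold":
            lines += [
                f"  alpha (quantile)    {scheme.alpha_quantile}",
                f"  beta                {scheme.beta}",
                f"  count threshold     {scheme.resolved_count_threshold:.6g}",
            ]
        lines += [
            f"mean silhouette       {self.silhouette:.4f}",
            "-" * 46,
            "module   n_sites   n_genes",
        ]
        for m in self.module_ids:
            sites = self.labels == m
            lines.append(
                f"{m:>6}   {sites.sum():>7}   {len(set(self.matrix.gene_ids[sites])):>7}"
            )
        return "\n".join(lines)
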