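"""File formats, run configuration and the end-to-end pipeline driver.

Everything is plain TSV/YAML/JSON so runs round-trip between languages:

* counts TSV — one row per site: ``site_id``, ``gene_id``, then paired
  ``IP_<sample>`` / ``INPUT_<sample>`` integer columns; the sample ->
  condition map lives in the config, not the file;
* optional BED (0-based, half-open) site coordinates joined on site_id
  and carried through, never computed on;
* methylation-matrix TSV with ``#``-prefixed header lines recording the
  pipeline stage, scale and config hash, plus per-condition coverage
  columns so the weighting layer can be re-run from the file;
* annotation TSV (``term_id``, ``gene_id``, optional ``term_name``,
  ``category``); module/target site lists as one id per line;
* a machine-readable JSON run log (parameters, seeds, resolved count
  threshold, library versions).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import MeripCountSet
from .enrichment import AnnotationTable
from .model import ModuleDetection
from .quantify import MethylationMatrix
from .weighting import WeightingScheme

__all__ = [
    "RunConfig",
    "read_counts_tsv",
    "write_counts_tsv",
    "counts_from_frame",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_annotation_tsv",
    "read_site_list",
    "run_pipeline",
    "verify_artifacts",
]


# ---------------------------------------------------------------- counts TSV

def counts_from_frame(
    df: pd.DataFrame, condition_map: dict[str, str] | None = None
) -> MeripCountSet:
    """Validate and convert a counts table to a :class:`MeripCountSet`."""
    if list(df.columns[:2]) != ["site_id", "gene_id"]:
        raise ValueError(
            "malformed header: first two columns must be site_id, gene_id "
            f"(got {list(df.columns[:2])})"
        )
    ip_cols = [c for c in df.columns if c.startswith("IP_")]
    in_cols = [c for c in df.columns if c.startswith("INPUT_")]
    samples = [c[3:] for c in ip_cols]
    missing_in = [s for s in samples if f"INPUT_{s}" not in in_cols]
    if not samples:
        raise ValueError("malformed header: no IP_<sample> columns found")
    if missing_in:
        raise ValueError(f"missing INPUT column for sample(s): {missing_in}")
    extra_in = [c[6:] for c in in_cols if c[6:] not in samples]
    if extra_in:
        raise ValueError(f"missing IP column for sample(s): {extra_in}")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].unique()[:5]
        raise ValueError(f"duplicate site_ids: {list(dups)}")
    for col in ip_cols + [f"INPUT_{s}" for s in samples]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (np.mod(vals.fillna(0), 1) != 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-integer count in column {col!r}, row {row} "
                f"(site_id={df['site_id'].iloc[row]!r}): {df[col].iloc[row]!r}"
            )
    t = df[ip_cols].to_numpy(dtype=np.int64)
    c = df[[f"INPUT_{s}" for s in samples]].to_numpy(dtype=np.int64)
    return MeripCountSet(
        site_ids=df["site_id"].astype(str).to_numpy(dtype=object),
        gene_ids=df["gene_id"].astype(str).to_numpy(dtype=object),
        samples=samples,
        t=t,
        c=c,
        condition_of_replicate=dict(condition_map) if condition_map else None,
    )


def read_counts_tsv(
    path: str | Path, condition_map: dict[str, str] | None = None
) -> MeripCountSet:
    """Read and validate a counts TSV (schema in the module docstring)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return counts_from_frame(df, condition_map)


def write_counts_tsv(counts: MeripCountSet, path: str | Path) -> None:
    df = pd.DataFrame({"site_id": counts.site_ids, "gene_id": counts.gene_ids})
    for j, s in enumerate(counts.samples):
        df[f"IP_{s}"] = counts.t[:, j]
    for j, s in enumerate(counts.samples):
        df[f"INPUT_{s}"] = counts.c[:, j]
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- matrix TSV

def write_matrix_tsv(
    mat: MethylationMatrix, path: str | Path, config_hash: str | None = None
) -> None:
    header = [f"# stage={mat.stage} scale={mat.scale}"]
    if config_hash:
        header.append(f"# config_hash={config_hash}")
    df = pd.DataFrame({"site_id": mat.site_ids, "gene_id": mat.gene_ids})
    for j, s in enumerate(mat.samples):
        df[s] = mat.values[:, j]
    for j, s in enumerate(mat.samples):
        df[f"cov_{s}"] = mat.coverage[:, j]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> MethylationMatrix:
    stage, scale = "raw", "beta"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if tok.startswith("stage="):
                    stage = tok.split("=", 1)[1]
                elif tok.startswith("scale="):
                    scale = tok.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    samples = [c for c in df.columns if c not in ("site_id", "gene_id")
               and not c.startswith("cov_")]
    values = df[samples].to_numpy(dtype=float)
    cov_cols = [f"cov_{s}" for s in samples]
    coverage = (df[cov_cols].to_numpy(dtype=np.int64)
                if all(c in df.columns for c in cov_cols)
                else np.zeros_like(values, dtype=np.int64))
    return MethylationMatrix(
        site_ids=df["site_id"].astype(str).to_numpy(dtype=object),
        gene_ids=df["gene_id"].astype(str).to_numpy(dtype=object),
        samples=samples, values=values, coverage=coverage,
        stage=stage, scale=scale,
    )


# ------------------------------------------------------- annotation / lists

def read_annotation_tsv(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return AnnotationTable.from_frame(df)


def read_site_list(path: str | Path) -> list[str]:
    """One site id per line; blank lines and # comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Site coordinates: chrom, start (0-based), end (half-open), site_id."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "site_id"],
        usecols=[0, 1, 2, 3], dtype={0: str, 1: np.int64, 2: np.int64, 3: str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


# ----------------------------------------------------------------- config

@dataclass
class RunConfig:
    """End-to-end run configuration with tuned defaults.

    Defaults follow the tuned operating point of the method: dynamic-site
    selection of the top 20000 sites by mean then 10000 by variance,
    threshold weighting with alpha = 0.45 (coverage quantile) and
    beta = 0.09, Ward-linkage weighted-Euclidean clustering with k = 5
    modules.
    """

    counts: str = ""
    output_dir: str = "epimodule_out"
    condition_map: dict[str, str] = field(default_factory=dict)
    bed: str | None = None
    annotation: str | None = None
    n_by_mean: int = 20000
    n_by_variance: int = 10000
    scale: str = "beta"
    weighting_kind: str = "threshold"
    alpha_quantile: float = 0.45
    beta: float = 0.09
    pair_sample_size: int = 100_000
    metric: str = "euclidean"
    linkage: str = "ward"
    k: int = 5
    top_m: int = 20
    max_term_count: int = 1000
    seed: int = 0
    write_distance: bool = False
    merge_replicates: bool = True
    drop_constant: bool = False
    version: str = "0.1.0"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def scheme(self) -> WeightingScheme:
        return WeightingScheme(
            kind=self.weighting_kind,
            alpha_quantile=self.alpha_quantile,
            beta=self.beta,
            pair_sample_size=self.pair_sample_size,
            seed=self.seed,
        )


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full module-detection pipeline and write its artifacts.

    Writes the preprocessed methylation matrix, module labels, per-module
    gene lists, the optional distance matrix, the enrichment report (when
    an annotation is supplied) and a JSON run log.  Each TSV embeds the
    config hash; :func:`verify_artifacts` checks them later.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: dict[str, Path] = {}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"[stage: {name}] {exc}") from exc

    counts = _stage("read_counts", read_counts_tsv, config.counts, config.condition_map)
    zero_frac = float((counts.coverage == 0).mean())
    if zero_frac > 0.5:
        warnings.warn(
            f"{zero_frac:.0%} of measurements have zero coverage; "
            "estimated methylation levels there are uninformative",
            stacklevel=2,
        )
    model = ModuleDetection(
        counts,
        scheme=config.scheme(),
        metric=config.metric,
        linkage=config.linkage,
        n_by_mean=config.n_by_mean,
        n_by_variance=config.n_by_variance,
        scale=config.scale,
        merge=config.merge_replicates,
        drop_constant=config.drop_constant,
    )
    res = _stage("fit", model.fit, config.k)

    p = outdir / "methylation_matrix.tsv"
    write_matrix_tsv(res.matrix, p, config_hash=chash)
    artifacts["matrix"] = p

    p = outdir / "modules.tsv"
    with open(p, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        res.to_frame().to_csv(fh, sep="\t", index=False)
    artifacts["modules"] = p

    p = outdir / "module_genes.tsv"
    rows = [
        dict(module=m, gene_id=g)
        for m in res.module_ids
        for g in res.module_genes(m)
    ]
    with open(p, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    artifacts["module_genes"] = p

    if config.write_distance:
        p = outdir / "distance.tsv"
        dd = pd.DataFrame(res.distance.values,
                          index=res.distance.labels, columns=res.distance.labels)
        with open(p, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            dd.to_csv(fh, sep="\t")
        artifacts["distance"] = p

    if config.annotation:
        annotation = _stage("read_annotation", read_annotation_tsv, config.annotation)
        tables = []
        for m in res.module_ids:
            score = _stage(
                "enrichment", res.enrich, annotation, int(m),
                config.top_m, config.max_term_count,
            )
            tab = score.table.copy()
            tab.insert(0, "module", m)
            tab["module_score"] = score.score
            tables.append(tab)
        p = outdir / "enrichment.tsv"
        with open(p, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            pd.concat(tables, ignore_index=True).to_csv(fh, sep="\t", index=False)
        artifacts["enrichment"] = p

    import scipy
    import sklearn

    scheme = res.distance.scheme
    log = dict(
        config=asdict(config),
        config_hash=chash,
        resolved_count_threshold=scheme.resolved_count_threshold,
        n_sites_retained=int(res.matrix.n_sites),
        silhouette=res.silhouette,
        module_sizes={int(m): int((res.labels == m).sum()) for m in res.module_ids},
        versions=dict(numpy=np.__version__, scipy=scipy.__version__,
                      pandas=pd.__version__, sklearn=sklearn.__version__),
    )
    p = outdir / "run_log.json"
    p.write_text(json.dumps(log, indent=2))
    artifacts["run_log"] = p
    return artifacts


def verify_artifacts(config: RunConfig) -> bool:
    """Check that every artifact in the output dir embeds this config's hash."""
    chash = config.config_hash()
    outdir = Path(config.output_dir)
    ok = True
    for p in sorted(outdir.glob("*.tsv")):
        with open(p) as fh:
            head = "".join(line for line in fh if line.startswith("#"))
        if f"config_hash={chash}" not in head:
            ok = False
    log = outdir / "run_log.json"
    if log.exists():
        ok = ok and json.loads(log.read_text()).get("config_hash") == chash
    else:
        ok = False
    return ok
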