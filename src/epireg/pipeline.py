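"""End-to-end orchestration: read -> harmonize -> normalize -> reduce ->
associate -> rank, with reproducible seeding and tabular run artifacts.

A single run seed deterministically derives per-region k-means seeds and
per-association permutation seeds (stable hash of the association id), so
results are independent of iteration order and identical across reruns.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .association import DEFAULT_WINDOW_BP, associate
from .datatypes import Association, FitResult, Panel, RankedGene
from .dimreduction import (
    DEFAULT_GAP_BP,
    DEFAULT_VARIANCE_TARGET,
    ReduceConfig,
    reduce,
)
from .ranking import (
    DEFAULT_ALPHA,
    DEFAULT_M_PERM,
    rank_genes,
    score_associations,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialized verbatim into the metadata."""

    meth_path: str
    expr_path: str
    outdir: str
    panel_path: str | None = None
    gap_bp: int = DEFAULT_GAP_BP
    variance_target: float = DEFAULT_VARIANCE_TARGET
    sigma_grid_size: int = 8
    k_max: int = 8
    window_bp: int = DEFAULT_WINDOW_BP
    m_perm: int = DEFAULT_M_PERM
    alpha: float = DEFAULT_ALPHA
    log_base: float = 2.0
    add_one_pvalue: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gap_bp", "variance_target", "sigma_grid_size", "k_max",
                     "m_perm", "alpha", "log_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_bp < 0:
            raise ValueError("window_bp must be nonnegative")


@dataclass
class RunResult:
    config: RunConfig
    panel: Panel
    n_sites: int
    n_sites_dropped: int
    n_regions: int
    n_clusters: int
    n_associations: int
    n_skipped: int
    ranked: list[RankedGene]
    scored: list[tuple[Association, FitResult, float]] = field(repr=False)
    pca_components: int | None = None
    outputs: dict[str, str] = field(default_factory=dict)


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e


def _count_data_rows(path: str | Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all three stages and write the run artifacts.

    Outputs under ``config.outdir``: ``clusters.tsv`` (per-site cluster
    table), ``associations.tsv``, ``ranked_genes.tsv``,
    ``qc_associations.tsv`` and ``run_metadata.json``.  Idempotent given
    the seed: two runs with identical config produce byte-identical files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        if config.panel_path:
            file_panel = eio.read_panel(config.panel_path)
        else:
            file_panel = None
        meth_cols = pd.read_csv(config.meth_path, sep="\t", nrows=0).columns
        expr_cols = pd.read_csv(config.expr_path, sep="\t", nrows=0).columns
        meth_panel = Panel(tuple(meth_cols[len(eio.METH_META_COLS):]))
        expr_panel = Panel(tuple(expr_cols[len(eio.EXPR_META_COLS):]))

    with _stage("harmonize"):
        panel = eio.harmonize(meth_panel, expr_panel)
        if file_panel is not None:
            panel = eio.harmonize(panel, file_panel)

    with _stage("read"):
        sites = eio.read_methylation(config.meth_path, panel)
        probesets = eio.read_expression(config.expr_path, panel)
        n_dropped = _count_data_rows(config.meth_path) - len(sites)

    with _stage("normalize"):
        probesets = eio.normalize_expression(probesets, config.log_base)

    with _stage("reduce"):
        rcfg = ReduceConfig(
            gap_bp=config.gap_bp,
            variance_target=config.variance_target,
            sigma_grid_size=config.sigma_grid_size,
            k_max=config.k_max,
            seed=config.seed,
        )
        models, pca, regions = reduce(sites, panel, rcfg)
        n_clusters = sum(m.k for m in models)

    with _stage("associate"):
        associations = associate(models, probesets, config.window_bp)

    with _stage("rank"):
        scored, skipped = score_associations(
            associations, M_perm=config.m_perm, seed=config.seed,
            add_one=config.add_one_pvalue,
        )
        ranked = rank_genes(scored, config.alpha)

    with _stage("write"):
        outputs = _write_artifacts(
            outdir, config, panel, sites, models, associations,
            scored, skipped, ranked, pca, n_dropped,
        )

    logger.info(
        "pipeline: %d sites -> %d regions -> %d clusters -> %d associations -> %d genes",
        len(sites), len(regions), n_clusters, len(associations), len(ranked),
    )
    return RunResult(
        config=config,
        panel=panel,
        n_sites=len(sites),
        n_sites_dropped=n_dropped,
        n_regions=len(regions),
        n_clusters=n_clusters,
        n_associations=len(associations),
        n_skipped=len(skipped),
        ranked=ranked,
        scored=scored,
        pca_components=None if pca is None else pca.n_kept,
        outputs=outputs,
    )


def _write_artifacts(outdir, config, panel, sites, models, associations,
                     scored, skipped, ranked, pca, n_dropped) -> dict[str, str]:
    paths: dict[str, str] = {}

    rows = []
    for m in models:
        for site_id, cluster in sorted(m.assignments.items()):
            rows.append(dict(
                region_id=m.region_id, site_id=site_id, cluster=cluster,
                sigma="" if m.sigma is None else m.sigma,
                k=m.k,
                compactness="" if m.compactness is None else m.compactness,
            ))
    p = outdir / "clusters.tsv"
    pd.DataFrame(rows, columns=["region_id", "site_id", "cluster", "sigma", "k",
                                "compactness"]).to_csv(p, sep="\t", index=False,
                                                       float_format="%.10g")
    paths["clusters"] = str(p)

    rows = [dict(
        assoc_id=a.assoc_id, region_id=a.region_id, cluster=a.cluster,
        anchor_chrom=a.anchor_chrom, anchor_pos=a.anchor_pos,
        probeset_id=a.probeset_id, gene=a.gene,
        distance_to_probeset=a.distance_to_probeset,
    ) for a in associations]
    p = outdir / "associations.tsv"
    pd.DataFrame(rows, columns=["assoc_id", "region_id", "cluster", "anchor_chrom",
                                "anchor_pos", "probeset_id", "gene",
                                "distance_to_probeset"]).to_csv(p, sep="\t", index=False)
    paths["associations"] = str(p)

    p = outdir / "ranked_genes.tsv"
    eio.write_ranked_genes(p, ranked, len(panel))
    paths["ranked_genes"] = str(p)

    rows = [dict(assoc_id=a.assoc_id, gene=a.gene, n_pairs=f.n_pairs, R=f.R,
                 p_value=pv, status="ok") for a, f, pv in scored]
    rows += [dict(assoc_id=a.assoc_id, gene=a.gene, n_pairs="", R="", p_value="",
                  status=f"skipped: {reason}") for a, reason in skipped]
    p = outdir / "qc_associations.tsv"
    pd.DataFrame(rows, columns=["assoc_id", "gene", "n_pairs", "R", "p_value",
                                "status"]).sort_values("assoc_id").to_csv(
        p, sep="\t", index=False, float_format="%.10g")
    paths["qc"] = str(p)

    meta = dict(
        config=asdict(config),
        panel=list(panel.cell_lines),
        n_sites=len(sites),
        n_sites_dropped=n_dropped,
        n_regions=len({m.region_id for m in models}),
        n_clusters=sum(m.k for m in models),
        compression_pct=round(
            100.0 * (1 - sum(m.k for m in models) / max(len(sites), 1)), 3),
        pca_components=None if pca is None else pca.n_kept,
        pca_variance_fraction=None if pca is None else round(pca.variance_fraction, 6),
        n_associations=len(associations),
        n_associations_skipped=len(skipped),
        n_ranked_genes=len(ranked),
    )
    p = outdir / "run_metadata.json"
    eio.write_metadata(p, meta)
    paths["metadata"] = str(p)
    return paths


def report(result: RunResult) -> pd.DataFrame:
    """Per-gene scatter data for the ranked genes: one row per cell line with
    methylation, normalized expression and the fitted curve value; a subtype
    column is included when the panel carries labels (for stratified plots).

    Empty ranking returns an empty frame (with a logged notice).
    """
    if not result.ranked:
        logger.warning("report: no significant genes; empty report")
        cols = ["gene", "cell_line", "M", "E", "E_fit"]
        if result.panel.subtypes is not None:
            cols.insert(2, "subtype")
        return pd.DataFrame(columns=cols)
    by_id = {a.assoc_id: (a, f) for a, f, _ in result.scored}
    rows = []
    for rg in result.ranked:
        a, f = by_id[rg.assoc_id]
        finite = np.isfinite(a.M_profile) & np.isfinite(a.E_profile)
        fit_vals = iter(f.E_fit)
        for i, line in enumerate(result.panel.cell_lines):
            row = dict(gene=rg.gene, cell_line=line,
                       M=a.M_profile[i], E=a.E_profile[i],
                       E_fit=next(fit_vals) if finite[i] else np.nan)
            if result.panel.subtypes is not None:
                row["subtype"] = result.panel.subtypes[i]
            rows.append(row)
    df = pd.DataFrame(rows)
    if result.panel.subtypes is not None:
        df = df[["gene", "cell_line", "subtype", "M", "E", "E_fit"]]
    return df
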