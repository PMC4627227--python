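"""End-to-end orchestration of the four-condition analysis.

Runs, in order: spike-in QC, CPM filtering, anchor-gene normalization,
the two IL-2 contrasts (within self-renewing and within senescent cells),
cross-condition classification, condition clustering, and — when a gene-set
collection is supplied — per-block enrichment and the shared-gene pathway
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as sio
from .classify import (
    DECategories,
    classify_de_genes,
    cluster_conditions,
    condition_distance_matrix,
    Dendrogram,
    heatmap_groups,
)
from .config import RunConfig
from .containers import CountMatrix, GeneAnnotation, NormalizedMatrix
from .enrich import build_pathway_network, enrich_gene_sets, network_summary
from .gfold import Contrast, call_contrast
from .preprocess import (
    compute_actb_scaling,
    ercc_qc,
    filter_low_expression,
    normalize_expression,
)

__all__ = ["PipelineResult", "run_pipeline", "SR_CONTRAST", "SEN_CONTRAST"]

logger = logging.getLogger("solodiff")

SR_CONTRAST = Contrast("SR_IL2minus", "SR_IL2plus", label="SR: IL-2+ vs IL-2-")
SEN_CONTRAST = Contrast("SEN_IL2minus", "SEN_IL2plus", label="SEN: IL-2+ vs IL-2-")


@dataclass
class PipelineResult:
    """Everything one pipeline run computes."""

    qc: pd.DataFrame | None
    removed_genes: list[str]
    filtered: CountMatrix
    scaling: pd.DataFrame
    normalized: NormalizedMatrix
    de_sr: pd.DataFrame
    de_sen: pd.DataFrame
    categories: DECategories
    distances: pd.DataFrame
    dendrogram: Dendrogram
    heatmap: pd.DataFrame
    enrichments: dict[str, pd.DataFrame] = field(default_factory=dict)
    network: nx.Graph | None = None


def run_pipeline(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    config: RunConfig,
    spikein: pd.DataFrame | None = None,
    gene_sets: dict[str, frozenset[str]] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on one four-library count matrix."""
    qc = None
    if spikein is not None and len(counts.spikein_ids) >= 3:
        qc = ercc_qc(counts, spikein, r_floor=config.qc_r_floor)
        for lib, row in qc.iterrows():
            if row["flagged"]:
                logger.warning("library %s flagged by spike-in QC (r=%.3f)", lib, row["pearson_r"])

    filtered, removed = filter_low_expression(
        counts, config.cpm_threshold, config.filter_scope
    )
    logger.info("CPM filter removed %d of %d genes", len(removed), len(counts.endogenous_ids))

    scaling = compute_actb_scaling(filtered, config.actb_gene_id)
    endo = filtered.subset_genes(filtered.endogenous_ids)
    normalized = normalize_expression(endo, annotation, scaling)

    de_sr = call_contrast(filtered, SR_CONTRAST, config)
    de_sen = call_contrast(filtered, SEN_CONTRAST, config)
    categories = classify_de_genes(de_sr, de_sen)

    distances = condition_distance_matrix(
        normalized, metric=config.distance_metric, pseudo=config.pseudo_expression
    )
    dendrogram = cluster_conditions(distances, method=config.linkage_method)
    heatmap = heatmap_groups(categories, normalized)

    enrichments: dict[str, pd.DataFrame] = {}
    network = None
    if gene_sets:
        universe = set(normalized.values.index)
        cat_sets = categories.as_dict()
        frames = []
        for name, members in cat_sets.items():
            direction, _, scope = name.partition("_")
            scope = scope or "both"
            enr = enrich_gene_sets(
                set(members) & universe, universe, gene_sets,
                direction=direction, state_scope=scope,
            )
            enrichments[name] = enr
            frames.append(enr)
        combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        # The network pools every enriched pathway across blocks; a pathway
        # enriched in several blocks keeps its strongest (smallest-q) entry.
        if len(combined):
            best = (
                combined.sort_values("q_value", kind="mergesort")
                .drop_duplicates("set_name")
                .reset_index(drop=True)
            )
            network = build_pathway_network(
                best, q_threshold=config.fdr_threshold,
                min_shared_genes=config.min_shared_genes,
            )

    result = PipelineResult(
        qc=qc,
        removed_genes=removed,
        filtered=filtered,
        scaling=scaling,
        normalized=normalized,
        de_sr=de_sr,
        de_sen=de_sen,
        categories=categories,
        distances=distances,
        dendrogram=dendrogram,
        heatmap=heatmap,
        enrichments=enrichments,
        network=network,
    )
    if out_dir is not None:
        write_outputs(result, config, Path(out_dir))
    return result


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index_label=None) -> None:
    with open(path, "w") as fh:
        for line in config.header_lines():
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def write_outputs(result: PipelineResult, config: RunConfig, out_dir: Path) -> None:
    """Write every pipeline product as headered TSV (+ Newick, network files)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.qc is not None:
        _write_tsv(result.qc, out_dir / "ercc_qc.tsv", config)
    _write_tsv(result.scaling, out_dir / "actb_scaling.tsv", config)
    _write_tsv(
        result.normalized.values, out_dir / "normalized_expression.tsv", config,
        index_label="gene_id",
    )
    _write_tsv(result.de_sr, out_dir / "de_SR.tsv", config, index_label="gene_id")
    _write_tsv(result.de_sen, out_dir / "de_SEN.tsv", config, index_label="gene_id")
    venn = pd.DataFrame(
        {"count": result.categories.counts(), "proportion": result.categories.proportions()}
    )
    _write_tsv(venn, out_dir / "venn_counts.tsv", config, index_label="category")
    cats = pd.DataFrame(
        [
            (g, name)
            for name, members in result.categories.as_dict().items()
            for g in sorted(members)
        ],
        columns=["gene_id", "category"],
    )
    _write_tsv(cats.set_index("gene_id"), out_dir / "de_categories.tsv", config)
    _write_tsv(result.distances, out_dir / "condition_distances.tsv", config)
    (out_dir / "condition_dendrogram.nwk").write_text(result.dendrogram.newick + "\n")
    _write_tsv(result.heatmap, out_dir / "heatmap_table.tsv", config, index_label="gene_id")
    for name, enr in result.enrichments.items():
        out = enr.copy()
        if len(out):
            out["overlap_genes"] = out["overlap_genes"].map(";".join)
        _write_tsv(out.set_index("set_name"), out_dir / f"enrichment_{name}.tsv", config)
    if result.network is not None:
        sio.write_network(result.network, out_dir / "pathway_network.tsv", config=config)
        sio.write_network(result.network, out_dir / "pathway_network.graphml", fmt="graphml")
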