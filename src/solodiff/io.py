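"""Readers and writers for every external format the pipeline touches.

All tables are plain TSV; gene sets are GMT; networks go out as a TSV edge
list plus node table, or GraphML via networkx. Readers reject malformed
input with errors naming the offending row/column instead of coercing.
Writers embed the effective run configuration as ``#`` comment lines, which
all readers here skip.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import CountMatrix, DataError, GeneAnnotation

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_gene_lengths",
    "write_gene_lengths",
    "exon_union_lengths_from_gtf",
    "read_spikein_table",
    "write_spikein_table",
    "read_gene_sets",
    "write_gene_sets",
    "write_network",
    "read_network_edge_list",
    "FormatError",
]

logger = logging.getLogger("solodiff")


class FormatError(ValueError):
    """Malformed external file."""


def _header(config: RunConfig | None) -> str:
    return "".join(line + "\n" for line in config.header_lines()) if config else ""


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a genes × libraries TSV of raw integer counts.

    First column holds gene ids, header row holds library ids. Cells must
    be non-negative integers; NA is not allowed.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    if df.columns.size == 0:
        raise FormatError(f"{path}: no library columns found")
    parsed = {}
    for col in df.columns:
        vals = df[col]
        ok = vals.str.fullmatch(r"\d+")
        if ok.isna().any() or not ok.all():
            bad = vals.index[~ok.fillna(False)][0]
            raise FormatError(
                f"{path}: non-integer count at gene {bad!r}, library {col!r}: "
                f"{vals.loc[bad]!r}"
            )
        parsed[col] = vals.astype(np.int64)
    counts = pd.DataFrame(parsed, index=df.index)
    spikeins = frozenset(g for g in counts.index if str(g).startswith("ERCC-"))
    return CountMatrix(counts, spikein_ids=spikeins)


def write_count_table(
    matrix: CountMatrix, path: str | Path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        matrix.counts.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_gene_lengths(path: str | Path) -> GeneAnnotation:
    """Read a (gene_id, total_exon_length_bp) TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expected gene_id and length columns")
    lengths = df.iloc[:, 0]
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()][0]
        raise FormatError(f"{path}: missing length for gene {bad!r}")
    return GeneAnnotation(lengths)


def write_gene_lengths(
    annotation: GeneAnnotation, path: str | Path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        annotation.lengths.astype(int).rename("total_exon_length_bp").rename_axis(
            "gene_id"
        ).to_csv(fh, sep="\t")


def exon_union_lengths_from_gtf(path: str | Path) -> GeneAnnotation:
    """Total exon length per gene from a GTF: union of exon intervals."""
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    exons = gr[gr.Feature == "exon"]
    if len(exons) == 0:
        raise FormatError(f"{path}: no exon features in GTF")
    merged = exons.merge(by="gene_id", strand=False).df
    merged["width"] = merged.End - merged.Start
    lengths = merged.groupby("gene_id")["width"].sum()
    return GeneAnnotation(lengths)


def read_spikein_table(path: str | Path) -> pd.DataFrame:
    """Read a spike-in table (species_id, length, expected_concentration)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    required = {"length", "expected_concentration"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: spike-in table needs columns {sorted(required)}")
    if (df["expected_concentration"] <= 0).any():
        raise FormatError(f"{path}: expected concentrations must be positive")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate spike-in species ids")
    return df


def write_spikein_table(
    table: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        table.rename_axis("species_id").to_csv(fh, sep="\t")


def read_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file into named gene sets.

    Each line is ``name<TAB>description<TAB>member...``; duplicate members
    within a line collapse (set semantics) and empty sets are dropped with
    a logged warning.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description, members"
                )
            name = fields[0]
            if not name:
                raise FormatError(f"{path}:{lineno}: empty gene-set name")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                logger.warning("%s:%d: dropping empty gene set %r", path, lineno, name)
                continue
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + sorted(members)) + "\n")


def write_network(
    network: nx.Graph,
    path: str | Path,
    fmt: str = "edge_list_tsv",
    config: RunConfig | None = None,
) -> None:
    """Write a pathway network as a TSV edge list + node table, or GraphML.

    For ``edge_list_tsv`` two files are produced: ``<path>`` with columns
    (pathway_a, pathway_b, shared_gene_count, shared_gene_ids) and
    ``<path stem>.nodes.tsv`` with (pathway, de_gene_count, q_value).
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for node, attrs in network.nodes(data=True):
            g.add_node(
                node,
                de_gene_count=int(attrs.get("de_gene_count", 0)),
                q_value=float(attrs.get("q_value", float("nan"))),
            )
        for a, b, attrs in network.edges(data=True):
            g.add_edge(
                a,
                b,
                shared_gene_count=int(attrs.get("shared_gene_count", 0)),
                shared_gene_ids=";".join(sorted(attrs.get("shared_gene_ids", ()))),
            )
        nx.write_graphml(g, path)
        return
    if fmt != "edge_list_tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("pathway_a\tpathway_b\tshared_gene_count\tshared_gene_ids\n")
        for a, b, attrs in sorted(network.edges(data=True)):
            shared = ";".join(sorted(attrs.get("shared_gene_ids", ())))
            fh.write(f"{a}\t{b}\t{attrs.get('shared_gene_count', 0)}\t{shared}\n")
    nodes_path = path.with_suffix(".nodes.tsv")
    with open(nodes_path, "w") as fh:
        fh.write(_header(config))
        fh.write("pathway\tde_gene_count\tq_value\n")
        for node, attrs in sorted(network.nodes(data=True)):
            fh.write(
                f"{node}\t{attrs.get('de_gene_count', 0)}\t"
                f"{attrs.get('q_value', float('nan'))}\n"
            )


def read_network_edge_list(path: str | Path) -> nx.Graph:
    """Re-read an edge list written by :func:`write_network`."""
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t", comment="#")
    for row in df.itertuples(index=False):
        shared = frozenset(str(row.shared_gene_ids).split(";")) if isinstance(
            row.shared_gene_ids, str
        ) and row.shared_gene_ids else frozenset()
        g.add_edge(
            row.pathway_a,
            row.pathway_b,
            shared_gene_count=int(row.shared_gene_count),
            shared_gene_ids=shared,
        )
    return g
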