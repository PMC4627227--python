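"""Gene-set over-representation and the shared-gene pathway network.

Enrichment of an up- or down-regulated gene list against a pathway
collection uses the one-sided hypergeometric upper tail: with a universe of
N testable genes, K of them in the pathway and an n-gene DE list, the
p-value is P(X ≥ k) for the observed overlap k. q-values are
Benjamini–Hochberg adjusted within one (direction, state-scope) block.
Pathways passing the q threshold become nodes of a network weighted by
their DE-gene count, with edges weighted by the number of DE genes two
pathways share.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentError",
    "enrich_gene_sets",
    "build_pathway_network",
    "network_summary",
]


class EnrichmentError(ValueError):
    """Invalid enrichment inputs."""


def enrich_gene_sets(
    de_genes: set[str],
    universe: set[str],
    gene_sets: dict[str, frozenset[str]],
    direction: str = "up",
    state_scope: str = "both",
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each gene set.

    Sets are intersected with the universe first; sets with fewer than
    ``min_set_size`` testable members are skipped (a pathway must contain
    multiple genes). Returns a frame sorted by p-value with columns
    set_name, direction, state_scope, k, K, n, N, p_value, q_value,
    overlap_genes.
    """
    de_genes = set(de_genes)
    universe = set(universe)
    if not de_genes <= universe:
        stray = sorted(de_genes - universe)
        raise EnrichmentError(f"DE genes outside the universe: {stray[:5]}")
    N, n = len(universe), len(de_genes)
    rows = []
    for name, members in gene_sets.items():
        testable = frozenset(members) & universe
        K = len(testable)
        if K < min_set_size:
            continue
        overlap = testable & de_genes
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "direction": direction,
                "state_scope": state_scope,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(p, 1.0),
                "overlap_genes": tuple(sorted(overlap)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "direction",
            "state_scope",
            "k",
            "K",
            "n",
            "N",
            "p_value",
            "overlap_genes",
        ],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def build_pathway_network(
    enrichments: pd.DataFrame,
    q_threshold: float = 0.25,
    min_shared_genes: int = 1,
) -> nx.Graph:
    """Shared-DE-gene network over pathways with q ≤ ``q_threshold``.

    Nodes carry ``de_gene_count`` (the pathway's DE overlap k) and
    ``q_value``; an edge joins two pathways whose DE overlap gene sets
    share at least ``min_shared_genes`` genes, with the shared count as
    weight and the shared ids attached.
    """
    g = nx.Graph()
    if len(enrichments) == 0:
        return g
    passing = enrichments[enrichments["q_value"] <= q_threshold]
    overlaps: dict[str, frozenset[str]] = {}
    for row in passing.itertuples(index=False):
        g.add_node(
            row.set_name,
            de_gene_count=int(row.k),
            q_value=float(row.q_value),
        )
        overlaps[row.set_name] = frozenset(row.overlap_genes)
    names = sorted(overlaps)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = overlaps[a] & overlaps[b]
            if len(shared) >= min_shared_genes:
                g.add_edge(
                    a, b, shared_gene_count=len(shared), shared_gene_ids=shared
                )
    return g


def network_summary(network: nx.Graph) -> dict:
    """Node/edge counts, degree distribution, and connected components."""
    degrees = dict(network.degree())
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "degrees": degrees,
        "degree_distribution": dict(
            pd.Series(list(degrees.values()), dtype=int).value_counts().sort_index()
        ),
        "n_components": nx.number_connected_components(network),
    }
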