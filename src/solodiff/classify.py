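"""Cross-condition classification of DE calls and condition clustering.

Genes called up or down in response to IL-2 priming are partitioned by the
cell state(s) in which the response occurs — self-renewing only, senescent
only, or both — the same reading a Venn diagram of the two contrasts gives.
Condition profiles are compared by rank correlation of log expression and
clustered agglomeratively to reveal which library is the outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import NormalizedMatrix
from .simulate import DE_CATEGORIES

__all__ = [
    "DECategories",
    "ClassifyError",
    "classify_de_genes",
    "condition_distance_matrix",
    "cluster_conditions",
    "Dendrogram",
    "heatmap_groups",
]


class ClassifyError(ValueError):
    """Inconsistent classification inputs."""


@dataclass
class DECategories:
    """Six state-scope regulation categories plus discordant genes.

    The three up sets are pairwise disjoint and union to all genes called
    up in at least one contrast; likewise down. A gene up in one state and
    down in the other lands in one up set and one down set and is flagged
    in ``discordant``.
    """

    up_both: frozenset[str]
    up_SR_only: frozenset[str]
    up_SEN_only: frozenset[str]
    down_both: frozenset[str]
    down_SR_only: frozenset[str]
    down_SEN_only: frozenset[str]
    discordant: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {name: getattr(self, name) for name in DE_CATEGORIES}

    def counts(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.as_dict().items()}

    def proportions(self) -> dict[str, float]:
        """Category share of all genes called DE in at least one contrast."""
        total = len(frozenset().union(*self.as_dict().values()))
        if total == 0:
            return {name: 0.0 for name in DE_CATEGORIES}
        return {name: len(s) / total for name, s in self.as_dict().items()}


def classify_de_genes(sr: pd.DataFrame, sen: pd.DataFrame) -> DECategories:
    """Partition DE calls from the SR and SEN contrasts into categories.

    Both inputs are per-gene call frames over the same gene universe (as
    produced by :func:`solodiff.gfold.call_contrast`).
    """
    if set(sr.index) != set(sen.index):
        raise ClassifyError("SR and SEN contrasts cover different gene universes")
    sr_up = frozenset(sr.index[sr["call"] == "up"])
    sr_down = frozenset(sr.index[sr["call"] == "down"])
    sen_up = frozenset(sen.index[sen["call"] == "up"])
    sen_down = frozenset(sen.index[sen["call"] == "down"])
    return DECategories(
        up_both=sr_up & sen_up,
        up_SR_only=sr_up - sen_up,
        up_SEN_only=sen_up - sr_up,
        down_both=sr_down & sen_down,
        down_SR_only=sr_down - sen_down,
        down_SEN_only=sen_down - sr_down,
        discordant=(sr_up & sen_down) | (sr_down & sen_up),
    )


def condition_distance_matrix(
    expr: NormalizedMatrix,
    metric: str = "spearman",
    pseudo: float = 1e-6,
) -> pd.DataFrame:
    """Pairwise distances between condition expression profiles.

    Default distance is 1 − Spearman correlation of log2(e + pseudo)
    profiles (robust to the heavy-tailed normalized values and invariant to
    per-library monotone transformations); Pearson and Euclidean variants
    are available.
    """
    if expr.values.shape[0] < 2:
        raise ClassifyError("need at least 2 genes to compare condition profiles")
    logx = np.log2(expr.values.to_numpy(float) + pseudo)
    libs = list(expr.values.columns)
    constant = [lib for lib, col in zip(libs, logx.T) if np.allclose(col, col[0])]
    if constant and metric in ("spearman", "pearson"):
        raise ClassifyError(f"constant expression profile in libraries {constant}")
    if metric == "spearman":
        rho = stats.spearmanr(logx).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-library case to a scalar
            rho = np.array([[1.0, rho], [rho, 1.0]])
        d = 1.0 - rho
    elif metric == "pearson":
        d = 1.0 - np.corrcoef(logx, rowvar=False)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        d = squareform(pdist(logx.T))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=libs, columns=libs)


@dataclass
class Dendrogram:
    """Agglomerative clustering result for the four conditions."""

    labels: list[str]  # leaf labels in the (lexicographic) linkage input order
    linkage: np.ndarray
    newick: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def outlier_leaf(self) -> str | None:
        """The single leaf on one side of the root, if the root is leaf-vs-rest."""
        tree = hierarchy.to_tree(self.linkage)
        for side, other in ((tree.left, tree.right), (tree.right, tree.left)):
            if side is not None and side.is_leaf() and other is not None:
                return self.labels[side.id]
        return None


def _to_newick(node, labels: list[str], parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def cluster_conditions(distances: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of the condition distance matrix.

    Leaf order is deterministic: libraries enter the linkage in
    lexicographic id order, which fixes tie-breaking.
    """
    d = distances.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ClassifyError("distance matrix must be square and symmetric")
    labels = sorted(distances.index)
    d = distances.loc[labels, labels].to_numpy(float)
    z = hierarchy.linkage(squareform(d, checks=False), method=method)
    root = hierarchy.to_tree(z)
    newick = f"({_to_newick(root.left, labels, root.dist)},{_to_newick(root.right, labels, root.dist)});"
    return Dendrogram(labels=labels, linkage=z, newick=newick)


def heatmap_groups(
    categories: DECategories, expr: NormalizedMatrix
) -> pd.DataFrame:
    """Plotting-ready table: genes ordered by category then mean expression.

    Within each category genes are sorted by decreasing mean normalized
    expression (ties by gene id); the ``group`` column carries the category.
    """
    blocks = []
    for name, members in categories.as_dict().items():
        present = [g for g in members if g in expr.values.index]
        if not present:
            continue
        block = expr.values.loc[present].copy()
        means = block.mean(axis=1)
        block = block.loc[sorted(present, key=lambda g: (-means[g], g))]
        block["group"] = name
        blocks.append(block)
    if not blocks:
        return pd.DataFrame(columns=list(expr.values.columns) + ["group"])
    return pd.concat(blocks)
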