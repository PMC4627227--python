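"""In-memory containers for the pipeline's core data.

Counts are raw non-negative integers everywhere; normalized expression
values appear only in :class:`NormalizedMatrix`, the product of the
anchor-gene normalization. Spike-in rows live inside the count matrix but
are tracked by id so that filtering and library totals can exempt them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LibraryDescriptor

__all__ = ["CountMatrix", "GeneAnnotation", "NormalizedMatrix", "DataError"]


class DataError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass
class CountMatrix:
    """Integer gene × library read counts plus library metadata.

    ``counts`` has gene ids as the index and library ids as columns.
    ``spikein_ids`` marks rows that are synthetic spike-in species rather
    than endogenous genes.
    """

    counts: pd.DataFrame
    libraries: tuple[LibraryDescriptor, ...] = ()
    spikein_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dupes[:5]}")
        if df.columns.duplicated().any():
            raise DataError("duplicate library ids")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise DataError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        self.spikein_ids = frozenset(self.spikein_ids) & frozenset(df.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def endogenous_ids(self) -> pd.Index:
        """Gene ids excluding spike-in species."""
        return self.counts.index[~self.counts.index.isin(self.spikein_ids)]

    def endogenous_totals(self) -> pd.Series:
        """Per-library totals over endogenous genes (spike-ins excluded)."""
        return self.counts.loc[self.endogenous_ids].sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[list(gene_ids)], self.libraries, self.spikein_ids
        )

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts)


@dataclass
class GeneAnnotation:
    """Per-gene total exon length in bp, indexed by gene id."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        s = self.lengths
        if s.index.duplicated().any():
            raise DataError("duplicate gene ids in annotation")
        if (s <= 0).any():
            bad = s.index[s <= 0].tolist()
            raise DataError(f"non-positive gene lengths: {bad[:5]}")
        self.lengths = s.astype(float)

    def length_of(self, gene_id: str) -> float:
        try:
            return float(self.lengths.loc[gene_id])
        except KeyError:
            raise DataError(f"gene {gene_id!r} missing from annotation") from None


@dataclass
class NormalizedMatrix:
    """Length- and anchor-normalized expression e_ij with lengths alongside."""

    values: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise DataError("normalized expression must be non-negative")
        missing = self.values.index.difference(self.lengths.index)
        if len(missing):
            raise DataError(f"lengths missing for genes: {missing[:5].tolist()}")
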