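"""Run configuration and library metadata.

A run of the pipeline is parameterized by a single flat :class:`RunConfig`
whose defaults mirror the printed analysis parameters (counts-per-million
threshold of 1, generalized-fold-change cutoff of ±0.01). Every output file
embeds the effective configuration as a comment header so results are
traceable to the parameters and seed that produced them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "CellState",
    "Treatment",
    "FilterScope",
    "LibraryDescriptor",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


class CellState(str, Enum):
    """Proliferative state of the profiled mesenchymal stem cells."""

    SR = "SR"  # self-renewing (early passage)
    SEN = "SEN"  # replicatively senescent (late passage)


class Treatment(str, Enum):
    """Interleukin-2 priming status of a library."""

    IL2_MINUS = "IL2_minus"
    IL2_PLUS = "IL2_plus"


class FilterScope(str, Enum):
    """How the CPM filter combines evidence across libraries.

    ``ANY_LIBRARY`` keeps a gene expressed above threshold in at least one
    library (the permissive reading, which preserves state-specific genes);
    ``ALL_LIBRARIES`` requires the threshold in every library.
    """

    ANY_LIBRARY = "any_library"
    ALL_LIBRARIES = "all_libraries"


@dataclass(frozen=True)
class LibraryDescriptor:
    """One sequencing library: a (cell state, treatment) condition."""

    library_id: str
    state: CellState
    treatment: Treatment
    total_mapped_counts: int = 0

    def __post_init__(self) -> None:
        if self.total_mapped_counts < 0:
            raise ConfigError(
                f"library {self.library_id!r}: total_mapped_counts must be >= 0"
            )


#: Canonical library ids for the four-condition design, in fixed order.
CONDITION_ORDER = ("SR_IL2minus", "SR_IL2plus", "SEN_IL2minus", "SEN_IL2plus")


def default_libraries(totals: dict[str, int] | None = None) -> list[LibraryDescriptor]:
    """The four (state, treatment) conditions of the replicate-free design."""
    combos = {
        "SR_IL2minus": (CellState.SR, Treatment.IL2_MINUS),
        "SR_IL2plus": (CellState.SR, Treatment.IL2_PLUS),
        "SEN_IL2minus": (CellState.SEN, Treatment.IL2_MINUS),
        "SEN_IL2plus": (CellState.SEN, Treatment.IL2_PLUS),
    }
    totals = totals or {}
    return [
        LibraryDescriptor(lib_id, state, treat, totals.get(lib_id, 0))
        for lib_id, (state, treat) in combos.items()
    ]


@dataclass
class RunConfig:
    """Flat pipeline configuration with explicit defaults.

    Parameters
    ----------
    seed
        Base seed for every stochastic step; recorded in all outputs.
    actb_gene_id
        Identifier of the beta-actin anchor gene used for normalization
        and (by default) for effective library sizing.
    cpm_threshold
        Counts-per-million below which a gene is removed (strict ``<``).
    gfold_cutoff
        Generalized-fold-change score magnitude at or above which a gene
        is called differentially expressed.
    gfold_quantile
        Posterior tail probability defining the conservative quantile.
    mc_draws
        Monte-Carlo draws for the sampling path of the posterior.
    fdr_threshold
        q-value cutoff for admitting a pathway into the network.
    min_shared_genes
        Minimum shared differentially expressed genes for a network edge.
    filter_scope
        Cross-library combination rule for the CPM filter.
    size_method
        Effective library size for fold-change scoring: ``"actb"`` (the
        anchor-gene count, consistent with the normalization philosophy)
        or ``"total"`` (total non-spike-in counts).
    qc_r_floor
        Minimum spike-in log-log Pearson r before a library is flagged.
    """

    seed: int = 0
    actb_gene_id: str = "ACTB"
    cpm_threshold: float = 1.0
    gfold_cutoff: float = 0.01
    gfold_quantile: float = 0.01
    mc_draws: int = 100_000
    fdr_threshold: float = 0.25
    min_shared_genes: int = 1
    filter_scope: FilterScope = FilterScope.ANY_LIBRARY
    size_method: str = "actb"
    qc_r_floor: float = 0.9
    distance_metric: str = "spearman"
    linkage_method: str = "average"
    pseudo_expression: float = 1e-6

    def __post_init__(self) -> None:
        self.filter_scope = FilterScope(self.filter_scope)
        if not (0.0 < self.gfold_quantile < 0.5):
            raise ConfigError("gfold_quantile must lie in (0, 0.5)")
        if self.cpm_threshold < 0:
            raise ConfigError("cpm_threshold must be >= 0")
        if self.mc_draws < 1:
            raise ConfigError("mc_draws must be >= 1")
        if self.size_method not in ("actb", "total"):
            raise ConfigError("size_method must be 'actb' or 'total'")
        if self.distance_metric not in ("spearman", "pearson", "euclidean"):
            raise ConfigError("unknown distance_metric")
        if self.linkage_method not in ("average", "complete", "single"):
            raise ConfigError("unknown linkage_method")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_scope"] = self.filter_scope.value
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def header_lines(self) -> list[str]:
        """Comment lines embedding the effective configuration in outputs."""
        items = ", ".join(f"{k}={v}" for k, v in self.to_dict().items())
        return [f"# solodiff run config: {items}"]
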