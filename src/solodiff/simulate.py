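"""Synthetic four-condition, replicate-free count experiments with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: one library per condition (self-renewing / senescent cells, each
with and without interleukin-2 priming), a designated highly expressed
beta-actin anchor gene that carries no treatment effect, 92 external
spike-in species on a log-uniform concentration ladder, and programmed
up/down regulation partitioned into state-specific and shared categories.

Counts follow a mean model: each gene's expected count in library *j* is
the library depth times the gene's relative abundance (baseline expression
per unit length × exon length, log-normal across genes), multiplied by
2^log2FC in the IL-2-primed library of the states where the gene carries an
effect. Sampling is Poisson, or Gamma–Poisson when ``dispersion > 0``
(variance m + dispersion·m²), reducing exactly to Poisson at dispersion 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONDITION_ORDER, LibraryDescriptor, default_libraries
from .containers import CountMatrix, GeneAnnotation

__all__ = [
    "CategoryEffect",
    "SimulationDesign",
    "DesignError",
    "DE_CATEGORIES",
    "spikein_table",
    "generate_experiment",
]

#: The six programmed regulation categories (plus implicit "null").
DE_CATEGORIES = (
    "up_both",
    "up_SR_only",
    "up_SEN_only",
    "down_both",
    "down_SR_only",
    "down_SEN_only",
)


class DesignError(ValueError):
    """Invalid simulation design."""


@dataclass(frozen=True)
class CategoryEffect:
    """Number of genes in a category and their log2 fold changes per state."""

    n: int
    log2fc_sr: float = 0.0
    log2fc_sen: float = 0.0


def _default_de_spec() -> dict[str, CategoryEffect]:
    # SEN effects are larger in magnitude so the SEN IL-2+ library is the
    # most divergent condition, mirroring the senescent cells' stronger
    # transcriptional response to IL-2 priming.
    return {
        "up_both": CategoryEffect(200, +2.0, +4.0),
        "up_SR_only": CategoryEffect(100, +2.0, 0.0),
        "up_SEN_only": CategoryEffect(100, 0.0, +4.0),
        "down_both": CategoryEffect(100, -2.0, -4.0),
        "down_SR_only": CategoryEffect(50, -2.0, 0.0),
        "down_SEN_only": CategoryEffect(50, 0.0, -4.0),
    }


@dataclass
class SimulationDesign:
    """Parameters of one synthetic four-library experiment.

    ``library_depths`` are expected endogenous read totals in the fixed
    condition order (SR IL-2−, SR IL-2+, SEN IL-2−, SEN IL-2+);
    ``actb_fraction`` is the share of each library's depth carried by the
    anchor gene; ``baseline_sigma`` is the log-normal spread (natural-log
    scale) of baseline expression per unit length across genes.
    """

    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (500, 10_000)
    library_depths: tuple[float, float, float, float] = (2e6, 2e6, 2e6, 2e6)
    actb_fraction: float = 0.02
    de_spec: dict[str, CategoryEffect] = field(default_factory=_default_de_spec)
    dispersion: float = 0.0
    n_spikein: int = 92
    spikein_length_range: tuple[int, int] = (250, 2000)
    spikein_fraction: float = 0.02
    baseline_sigma: float = 1.5
    actb_gene_id: str = "ACTB"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise DesignError("need at least 2 genes (anchor + one more)")
        unknown = set(self.de_spec) - set(DE_CATEGORIES)
        if unknown:
            raise DesignError(f"unknown DE categories: {sorted(unknown)}")
        n_de = sum(c.n for c in self.de_spec.values())
        if n_de > self.n_genes - 1:  # anchor gene never carries an effect
            raise DesignError(
                f"de_spec assigns {n_de} genes but only {self.n_genes - 1} are "
                "available (the anchor gene is exempt)"
            )
        for name, c in self.de_spec.items():
            if not (np.isfinite(c.log2fc_sr) and np.isfinite(c.log2fc_sen)):
                raise DesignError(f"{name}: effect sizes must be finite")
        if self.n_spikein < 1:
            raise DesignError("n_spikein must be >= 1")
        for lo, hi in (self.gene_length_range, self.spikein_length_range):
            if not (0 < lo <= hi):
                raise DesignError("length ranges must satisfy 0 < lo <= hi")
        if not (0 < self.actb_fraction < 1):
            raise DesignError("actb_fraction must lie in (0, 1)")
        if self.dispersion < 0:
            raise DesignError("dispersion must be >= 0")


def spikein_table(
    n_spikein: int = 92,
    length_range: tuple[int, int] = (250, 2000),
    seed: int = 0,
    log10_span: float = 6.0,
) -> pd.DataFrame:
    """Synthetic external spike-in table emulating the 92-species ERCC mix.

    Expected concentrations form a log-uniform ladder spanning
    ``log10_span`` orders of magnitude (so log-concentration is affine in
    rank); lengths are drawn uniformly within ``length_range``.
    """
    if n_spikein < 1:
        raise DesignError("n_spikein must be >= 1")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise DesignError("empty spike-in length range")
    rng = np.random.default_rng(seed)
    ids = [f"ERCC-{i:05d}" for i in range(1, n_spikein + 1)]
    lengths = rng.integers(lo, hi + 1, size=n_spikein)
    if n_spikein == 1:
        conc = np.array([1.0])
    else:
        conc = 10.0 ** np.linspace(-log10_span / 2, log10_span / 2, n_spikein)
    return pd.DataFrame(
        {"length": lengths, "expected_concentration": conc},
        index=pd.Index(ids, name="species_id"),
    )


def expected_counts(design: SimulationDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic per-gene expected counts and the truth table.

    Returns ``(means, truth)`` where ``means`` is genes+spike-ins ×
    libraries and ``truth`` records each endogenous gene's programmed
    per-state log2 fold change and category. Separated from the sampling
    step so the mean model can be tested directly.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    width = len(str(n))
    gene_ids = [design.actb_gene_id] + [f"G{i:0{width}d}" for i in range(1, n)]

    lo, hi = design.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n).astype(float)
    baseline = rng.lognormal(mean=0.0, sigma=design.baseline_sigma, size=n)

    # Programmed effects: draw category members from non-anchor genes.
    truth = pd.DataFrame(
        {
            "true_log2fc_SR": np.zeros(n),
            "true_log2fc_SEN": np.zeros(n),
            "category": ["null"] * n,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    assignable = rng.permutation(np.arange(1, n))
    pos = 0
    for cat in DE_CATEGORIES:
        eff = design.de_spec.get(cat)
        if eff is None or eff.n == 0:
            continue
        idx = assignable[pos : pos + eff.n]
        pos += eff.n
        truth.iloc[idx, truth.columns.get_loc("true_log2fc_SR")] = eff.log2fc_sr
        truth.iloc[idx, truth.columns.get_loc("true_log2fc_SEN")] = eff.log2fc_sen
        truth.iloc[idx, truth.columns.get_loc("category")] = cat

    # Relative abundance from baseline only; treatment effects multiply on
    # top, so doubling depth doubles every expected count exactly.
    abundance = baseline * lengths
    abundance[0] = 0.0  # anchor handled via actb_fraction
    share = (1.0 - design.actb_fraction) * abundance / abundance.sum()
    share[0] = design.actb_fraction

    fc = np.ones((n, 4))
    fc[:, CONDITION_ORDER.index("SR_IL2plus")] = 2.0 ** truth["true_log2fc_SR"]
    fc[:, CONDITION_ORDER.index("SEN_IL2plus")] = 2.0 ** truth["true_log2fc_SEN"]
    depths = np.asarray(design.library_depths, dtype=float)
    means = share[:, None] * depths[None, :] * fc

    spikes = spikein_table(
        design.n_spikein, design.spikein_length_range, seed=design.seed
    )
    spike_share = (
        design.spikein_fraction
        * spikes["expected_concentration"].to_numpy()
        / spikes["expected_concentration"].sum()
    )
    spike_means = spike_share[:, None] * depths[None, :]

    all_means = pd.DataFrame(
        np.vstack([means, spike_means]),
        index=pd.Index(gene_ids + spikes.index.tolist(), name="gene_id"),
        columns=list(CONDITION_ORDER),
    )
    all_lengths = pd.Series(
        np.concatenate([lengths, spikes["length"].to_numpy(dtype=float)]),
        index=all_means.index,
        name="total_exon_length_bp",
    )
    truth.attrs["lengths"] = all_lengths
    return all_means, truth


def generate_experiment(
    design: SimulationDesign,
    sampling_seed: int | None = None,
) -> tuple[CountMatrix, GeneAnnotation, pd.DataFrame, pd.DataFrame]:
    """Sample one four-library experiment.

    Returns ``(counts, annotation, spikein, truth)``; fully reproducible
    from ``design.seed``. ``sampling_seed`` re-seeds only the count
    sampling stage, giving replicate draws over a fixed mean model.
    """
    means, truth = expected_counts(design)
    entropy = design.seed if sampling_seed is None else sampling_seed
    rng = np.random.default_rng(np.random.SeedSequence([entropy, 1]))
    m = means.to_numpy()
    if design.dispersion > 0:
        shape = 1.0 / design.dispersion
        lam = rng.gamma(shape, scale=m * design.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(m)
    spikes = spikein_table(
        design.n_spikein, design.spikein_length_range, seed=design.seed
    )
    libraries = tuple(default_libraries())
    cm = CountMatrix(
        pd.DataFrame(counts, index=means.index, columns=means.columns),
        libraries=libraries,
        spikein_ids=frozenset(spikes.index),
    )
    annotation = GeneAnnotation(truth.attrs["lengths"])
    return cm, annotation, spikes, truth
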