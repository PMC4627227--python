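"""Spike-in QC, low-expression filtering, and anchor-gene normalization.

The normalization deliberately avoids global size factors: scaling each
library by the cross-library mean of the beta-actin (ACTB) count divided by
its own ACTB count pins the anchor gene to a common level while letting
genuine global shifts in the rest of the transcriptome survive. Dividing by
total exon length then puts genes of different sizes on a common scale:

    s_j = (1/n) Σ_k c_ACTB,k / c_ACTB,j        e_ij = c_ij × s_j / l_i

Filtering precedes normalization and operates on raw counts-per-million
(CPM); genes below the threshold are removed, spike-in species are exempt,
and the per-library totals used for CPM exclude spike-ins (their content
tracks the dilution of the mix, not the biology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import FilterScope, RunConfig
from .containers import CountMatrix, DataError, GeneAnnotation, NormalizedMatrix

__all__ = [
    "QCError",
    "NormalizationError",
    "ercc_qc",
    "filter_low_expression",
    "compute_actb_scaling",
    "normalize_expression",
    "plot_ercc_qc",
]


class QCError(ValueError):
    """Spike-in QC cannot be computed."""


class NormalizationError(ValueError):
    """Anchor-gene normalization cannot be computed."""


def ercc_qc(
    counts: CountMatrix,
    spikein: pd.DataFrame,
    r_floor: float = 0.9,
) -> pd.DataFrame:
    """Observed-vs-expected spike-in regression per library.

    For each library, regress log2(observed count + 1) on log2(expected
    concentration) over the spike-in species present in the count matrix.
    Returns a frame (library_id × {n_species, pearson_r, slope, intercept,
    flagged}); a library is flagged when r falls below ``r_floor``.
    """
    species = [s for s in spikein.index if s in counts.counts.index]
    if len(species) < 3:
        raise QCError(
            f"need at least 3 spike-in species with observed counts, got {len(species)}"
        )
    expected = np.log2(spikein.loc[species, "expected_concentration"].to_numpy(float))
    rows = []
    for lib in counts.library_ids:
        observed = np.log2(counts.counts.loc[species, lib].to_numpy(float) + 1.0)
        if np.allclose(observed, observed[0]):
            raise QCError(f"library {lib!r}: all observed spike-in counts equal")
        fit = stats.linregress(expected, observed)
        rows.append(
            {
                "library_id": lib,
                "n_species": len(species),
                "pearson_r": fit.rvalue,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "flagged": bool(fit.rvalue < r_floor),
            }
        )
    return pd.DataFrame(rows).set_index("library_id")


def plot_ercc_qc(counts: CountMatrix, spikein: pd.DataFrame, path) -> None:
    """Scatter of observed vs expected spike-in counts, one panel per library."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    species = [s for s in spikein.index if s in counts.counts.index]
    expected = np.log2(spikein.loc[species, "expected_concentration"].to_numpy(float))
    libs = counts.library_ids
    fig, axes = plt.subplots(1, len(libs), figsize=(3.2 * len(libs), 3.2), squeeze=False)
    for ax, lib in zip(axes[0], libs):
        observed = np.log2(counts.counts.loc[species, lib].to_numpy(float) + 1.0)
        ax.plot(expected, observed, "o", ms=3, alpha=0.6)
        ax.set_title(lib, fontsize=9)
        ax.set_xlabel("log2 expected conc.")
    axes[0][0].set_ylabel("log2 (observed + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def counts_per_million(counts: CountMatrix) -> pd.DataFrame:
    """Raw CPM over endogenous genes; totals exclude spike-ins."""
    totals = counts.endogenous_totals().astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DataError(f"library totals must be positive; zero in {bad}")
    return counts.counts.loc[counts.endogenous_ids] / totals * 1e6


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    scope: FilterScope | str = FilterScope.ANY_LIBRARY,
) -> tuple[CountMatrix, list[str]]:
    """Remove lowly expressed genes (CPM strictly below threshold).

    With ``any_library`` scope a gene survives if its CPM reaches the
    threshold in at least one library; with ``all_libraries`` it must reach
    it everywhere. Spike-in species are exempt and always retained. A gene
    at exactly the threshold is retained (removal is strict ``<``).
    """
    scope = FilterScope(scope)
    cpm = counts_per_million(counts)
    at_or_above = cpm >= cpm_threshold
    keep = at_or_above.any(axis=1) if scope is FilterScope.ANY_LIBRARY else at_or_above.all(axis=1)
    removed = keep.index[~keep].tolist()
    kept_ids = [g for g in counts.counts.index if g not in set(removed)]
    return counts.subset_genes(kept_ids), removed


def compute_actb_scaling(counts: CountMatrix, actb_gene_id: str) -> pd.DataFrame:
    """Per-library anchor scaling factors s_j = mean_k(c_ACTB,k) / c_ACTB,j.

    Returns a frame (library_id × {actb_count, factor}). The product
    c_ACTB,j × s_j equals the cross-library mean anchor count for every j.
    """
    if actb_gene_id not in counts.counts.index:
        raise NormalizationError(f"anchor gene {actb_gene_id!r} not in count matrix")
    actb = counts.counts.loc[actb_gene_id].astype(float)
    zero = actb.index[actb <= 0].tolist()
    if zero:
        raise NormalizationError(
            f"anchor gene {actb_gene_id!r} has zero count in libraries {zero}"
        )
    factors = actb.mean() / actb
    return pd.DataFrame(
        {"actb_count": actb, "factor": factors},
        index=pd.Index(counts.library_ids, name="library_id"),
    )


def normalize_expression(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    scaling: pd.DataFrame,
) -> NormalizedMatrix:
    """Apply e_ij = c_ij × s_j / l_i cellwise."""
    missing = counts.counts.index.difference(annotation.lengths.index)
    if len(missing):
        raise NormalizationError(
            f"annotation missing lengths for genes: {missing[:5].tolist()}"
        )
    missing_libs = [l for l in counts.library_ids if l not in scaling.index]
    if missing_libs:
        raise NormalizationError(f"scaling missing libraries: {missing_libs}")
    s = scaling.loc[counts.library_ids, "factor"].to_numpy(float)
    l = annotation.lengths.loc[counts.counts.index].to_numpy(float)
    values = counts.counts.to_numpy(float) * s[None, :] / l[:, None]
    return NormalizedMatrix(
        pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns),
        annotation.lengths.loc[counts.counts.index],
    )
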