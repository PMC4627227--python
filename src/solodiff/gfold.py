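"""Replicate-free differential expression via a posterior fold-change score.

With a single library per condition there is no variance to estimate, so
each gene's expression level in a library is modeled as Poisson with a flat
prior, giving the rate a Gamma(c + 1, 1) posterior for an observed count
c. The generalized fold change (GFOLD-style) score for a gene is a
conservative posterior quantile of the log2 ratio of depth-adjusted rates
between the two libraries:

* if the central (q, 1−q) posterior interval of log2FC lies above zero,
  the score is the lower quantile (a lower bound on the fold change);
* if it lies below zero, the score is the upper quantile;
* if the interval covers zero, the score is 0.

A gene is called up/down when |score| reaches the cutoff (±0.01 by
convention), so a call requires the whole conservative interval to clear
zero — the cutoff is a significance device, not an effect-size floor.

Two computational paths are provided and must agree: an exact path using
the Beta representation of a Gamma ratio (λ_b/(λ_a+λ_b) ~ Beta(c_b+1,
c_a+1), so every quantile of the ratio is a transformed Beta quantile) and
a seeded Monte-Carlo sampling path.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .containers import CountMatrix

__all__ = [
    "Contrast",
    "ContrastError",
    "posterior_log2fc_quantiles",
    "gfold_score",
    "call_contrast",
    "effective_sizes",
]

logger = logging.getLogger("solodiff")


class ContrastError(ValueError):
    """Invalid contrast specification."""


@dataclass(frozen=True)
class Contrast:
    """An ordered pair of libraries: treated vs baseline."""

    baseline_library: str
    treated_library: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.baseline_library == self.treated_library:
            raise ContrastError("contrast requires two distinct libraries")


def _check_inputs(count_a, count_b, size_a, size_b) -> None:
    if np.any(np.asarray(size_a) <= 0) or np.any(np.asarray(size_b) <= 0):
        raise ValueError("library sizes must be positive")
    if np.any(np.asarray(count_a) < 0) or np.any(np.asarray(count_b) < 0):
        raise ValueError("counts must be non-negative")


def _exact_log2fc_quantile(count_a, count_b, size_a, size_b, q):
    """Exact posterior quantile(s) of log2((λ_b/size_b)/(λ_a/size_a)).

    λ_a ~ Gamma(count_a+1), λ_b ~ Gamma(count_b+1) independent, so
    B = λ_b/(λ_a+λ_b) ~ Beta(count_b+1, count_a+1) and the ratio
    λ_b/λ_a = B/(1−B) is a monotone transform of B: quantiles map through.
    Vectorized over all arguments.
    """
    bq = stats.beta.ppf(q, np.asarray(count_b) + 1.0, np.asarray(count_a) + 1.0)
    with np.errstate(divide="ignore"):
        log2_ratio = np.log2(bq) - np.log2(1.0 - bq)
    return log2_ratio + np.log2(np.asarray(size_a) / np.asarray(size_b))


def posterior_log2fc_quantiles(
    count_a: int,
    count_b: int,
    size_a: float,
    size_b: float,
    quantile: float = 0.01,
    n_draws: int = 100_000,
    seed: int = 0,
    method: str = "exact",
) -> tuple[float, float, float]:
    """(lower, upper, median) of the posterior log2 fold change b vs a.

    ``method="exact"`` uses the closed-form Beta quantile (deterministic);
    ``method="sampling"`` draws ``n_draws`` Gamma pairs with the given seed.
    """
    _check_inputs(count_a, count_b, size_a, size_b)
    if not (0.0 < quantile < 0.5):
        raise ValueError("quantile must lie in (0, 0.5)")
    if method == "exact":
        lo, up, med = (
            float(_exact_log2fc_quantile(count_a, count_b, size_a, size_b, q))
            for q in (quantile, 1.0 - quantile, 0.5)
        )
        return lo, up, med
    if method != "sampling":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    lam_a = rng.gamma(count_a + 1.0, size=n_draws)
    lam_b = rng.gamma(count_b + 1.0, size=n_draws)
    draws = np.log2(lam_b / size_b) - np.log2(lam_a / size_a)
    lo, med, up = np.quantile(draws, [quantile, 0.5, 1.0 - quantile])
    return float(lo), float(up), float(med)


def gfold_score(
    count_a: int,
    count_b: int,
    size_a: float,
    size_b: float,
    quantile: float = 0.01,
    n_draws: int = 100_000,
    seed: int = 0,
    method: str = "exact",
) -> float:
    """Signed conservative posterior quantile of the log2 fold change.

    Zero when the central (quantile, 1−quantile) interval contains zero.
    """
    lo, up, _ = posterior_log2fc_quantiles(
        count_a, count_b, size_a, size_b, quantile, n_draws, seed, method
    )
    if lo > 0.0:
        return lo
    if up < 0.0:
        return up
    return 0.0


def effective_sizes(counts: CountMatrix, config: RunConfig) -> pd.Series:
    """Per-library effective sizes for fold-change scoring.

    ``"actb"`` uses the anchor-gene count per library (proportional to the
    reciprocal of the anchor scaling factor); ``"total"`` uses total
    endogenous counts.
    """
    if config.size_method == "actb":
        if config.actb_gene_id not in counts.counts.index:
            raise ContrastError(
                f"anchor gene {config.actb_gene_id!r} absent; cannot size libraries"
            )
        sizes = counts.counts.loc[config.actb_gene_id].astype(float)
        if (sizes <= 0).any():
            bad = sizes.index[sizes <= 0].tolist()
            raise ContrastError(f"anchor gene count is zero in libraries {bad}")
    else:
        sizes = counts.endogenous_totals().astype(float)
        if (sizes <= 0).any():
            raise ContrastError("empty library; cannot size by totals")
    return sizes


def call_contrast(
    counts: CountMatrix,
    contrast: Contrast,
    config: RunConfig,
    method: str = "exact",
) -> pd.DataFrame:
    """Score and call every endogenous gene for one contrast.

    Returns a frame indexed by gene id with columns ``score`` (signed
    conservative posterior log2FC quantile), ``log2fc_point`` (log2 of the
    depth-adjusted (count+1) ratio) and ``call`` in {up, down, unchanged}.
    """
    for lib in (contrast.baseline_library, contrast.treated_library):
        if lib not in counts.counts.columns:
            raise ContrastError(f"library {lib!r} not in count matrix")
    sizes = effective_sizes(counts, config)
    size_a = float(sizes[contrast.baseline_library])
    size_b = float(sizes[contrast.treated_library])
    genes = counts.endogenous_ids
    ca = counts.counts.loc[genes, contrast.baseline_library].to_numpy(float)
    cb = counts.counts.loc[genes, contrast.treated_library].to_numpy(float)

    if method == "exact":
        lo = _exact_log2fc_quantile(ca, cb, size_a, size_b, config.gfold_quantile)
        up = _exact_log2fc_quantile(ca, cb, size_a, size_b, 1.0 - config.gfold_quantile)
    else:
        lo = np.empty(len(genes))
        up = np.empty(len(genes))
        # One stream per contrast; per-gene substreams keyed by position in
        # the sorted gene list so input order never changes results.
        order = np.argsort(np.asarray(genes))
        for rank, i in enumerate(order):
            lo[i], up[i], _ = posterior_log2fc_quantiles(
                int(ca[i]),
                int(cb[i]),
                size_a,
                size_b,
                config.gfold_quantile,
                config.mc_draws,
                seed=np.random.SeedSequence(
                    [config.seed, zlib.crc32(contrast.label.encode()), rank]
                ).generate_state(1)[0],
                method="sampling",
            )
    score = np.where(lo > 0.0, lo, np.where(up < 0.0, up, 0.0))
    log2fc_point = np.log2(((cb + 1.0) / size_b) / ((ca + 1.0) / size_a))
    call = np.where(
        score >= config.gfold_cutoff,
        "up",
        np.where(score <= -config.gfold_cutoff, "down", "unchanged"),
    )
    result = pd.DataFrame(
        {"score": score, "log2fc_point": log2fc_point, "call": call},
        index=pd.Index(genes, name="gene_id"),
    )
    n_up = int((result["call"] == "up").sum())
    n_down = int((result["call"] == "down").sum())
    logger.info(
        "contrast %s: %d up, %d down of %d genes",
        contrast.label or f"{contrast.treated_library} vs {contrast.baseline_library}",
        n_up,
        n_down,
        len(result),
    )
    return result
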