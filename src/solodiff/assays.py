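"""Culture-tracking and qPCR quantification utilities.

Population doubling uses PD = log10(N/N0) × 3.33; the constant is
1/log10(2) to two decimals, so PD counts doublings. Relative qPCR
expression uses the comparative-Ct method, fold change = 2^(−ΔΔCt), with
the reference (housekeeping) gene subtracted within each sample and
triplicate Ct values averaged on the Ct scale before differencing.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "AssayError",
    "population_doubling",
    "cumulative_population_doublings",
    "ddct_fold_change",
]

PD_CONSTANT = 3.33


class AssayError(ValueError):
    """Invalid assay measurement."""


def population_doubling(n0: float, n: float) -> float:
    """Population doublings for one passage: log10(N/N0) × 3.33."""
    if n0 <= 0 or n <= 0:
        raise AssayError("cell counts must be positive")
    return math.log10(n / n0) * PD_CONSTANT


def cumulative_population_doublings(passages) -> list[float]:
    """Running cumulative PD over serial passages of (N0, N) pairs."""
    total = 0.0
    out = []
    for n0, n in passages:
        total += population_doubling(n0, n)
        out.append(total)
    return out


def _mean_ct(value) -> float:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise AssayError("Ct values must be finite and positive")
    return float(arr.mean())


def ddct_fold_change(
    ct_target_test,
    ct_ref_test,
    ct_target_ctrl,
    ct_ref_ctrl,
) -> float:
    """Relative expression 2^(−ΔΔCt) of target vs reference gene.

    Each argument may be a scalar or a sequence of technical replicates;
    replicates are averaged on the Ct scale. ΔCt = Ct_target − Ct_ref in
    each sample and ΔΔCt = ΔCt_test − ΔCt_ctrl.
    """
    d_test = _mean_ct(ct_target_test) - _mean_ct(ct_ref_test)
    d_ctrl = _mean_ct(ct_target_ctrl) - _mean_ct(ct_ref_ctrl)
    return 2.0 ** (-(d_test - d_ctrl))
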