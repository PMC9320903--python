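"""Shared statistical utilities: BH step-up FDR and cohort arithmetic."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["bh_adjust", "round_half_up", "mean_per_proband", "percent_of_cohort"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, computed on the
    sorted p-values and mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (printed-table convention)."""
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quant, rounding=ROUND_HALF_UP))


def mean_per_proband(total: float, n_probands: int, ndigits: int = 2) -> float:
    """Cohort mean as total count divided by the number of probands."""
    if n_probands <= 0:
        raise ValueError("n_probands must be positive")
    return round_half_up(total / n_probands, ndigits)


def percent_of_cohort(count: int, n_probands: int, ndigits: int = 1) -> float:
    """Percentage of probands, rounded half-up to ``ndigits`` decimals."""
    if n_probands <= 0:
        raise ValueError("n_probands must be positive")
    return round_half_up(100.0 * count / n_probands, ndigits)
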