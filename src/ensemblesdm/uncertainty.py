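"""ANOVA-without-replication partitioning of forecast uncertainty.

Each grid cell holds a complete factorial table of forecast richness, one
value per (modelling method, climate model[, emission scenario])
combination and no replication.  The table is decomposed into main-effect
sums of squares (marginal means vs the grand mean) plus a residual that
absorbs all interactions.  The per-cell total SS, expressed as a percent
of the summed total over all cells, maps where forecasts disagree most;
pooling each factor's SS over cells attributes the disagreement to
methods, climate models and scenarios.
"""

from __future__ import annotations

import numpy as np

__all__ = ["anova_ss", "uncertainty_map", "factor_attribution"]


def anova_ss(table: np.ndarray, factor_names=None) -> dict[str, float]:
    """Main-effect / residual / total SS of a complete factorial table.

    ``table`` is an n-dimensional array with one axis per factor (>= 2
    levels each) and exactly one observation per combination.  Returns
    ``{factor: SS_factor, ..., "residual": SS, "total": SS}`` where
    SS_factor = (cells per level) * sum_l (mean_l - grand_mean)^2 and
    residual = total - sum of main effects.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim < 2:
        raise ValueError("need at least two factors (a 2-D or higher table)")
    if np.any(np.isnan(table)):
        raise ValueError("incomplete factorial: table contains missing values")
    if any(s < 2 for s in table.shape):
        raise ValueError("every factor needs at least 2 levels")
    if factor_names is None:
        factor_names = [f"factor{i + 1}" for i in range(table.ndim)]
    if len(factor_names) != table.ndim:
        raise ValueError("one factor name per table axis")
    grand = table.mean()
    total = float(((table - grand) ** 2).sum())
    out: dict[str, float] = {}
    n = table.size
    for axis, name in enumerate(factor_names):
        other = tuple(a for a in range(table.ndim) if a != axis)
        marg = table.mean(axis=other)
        out[name] = float((n // table.shape[axis]) * ((marg - grand) ** 2).sum())
    out["residual"] = total - sum(out[name] for name in factor_names)
    out["total"] = total
    return out


def uncertainty_map(ss_total: np.ndarray) -> np.ndarray:
    """Per-cell percent of the grand-total uncertainty.

    percent(cell) = 100 * SS_total(cell) / sum_cells SS_total; the surface
    sums to 100 over the domain.
    """
    ss_total = np.asarray(ss_total, dtype=float)
    if np.any(ss_total < 0):
        raise ValueError("sums of squares cannot be negative")
    grand = ss_total.sum()
    if grand <= 0:
        raise ValueError("all cells have zero SS: no uncertainty to map")
    return 100.0 * ss_total / grand


def factor_attribution(per_cell_ss: dict[str, np.ndarray]) -> dict[str, float]:
    """Pooled percent of variation per factor across all cells.

    ``per_cell_ss`` maps each component name (factors, "residual",
    "total") to its per-cell SS array; the pooled percent for a factor is
    100 * sum_cells SS_factor / sum_cells SS_total.  Percentages over
    factors plus residual sum to 100.
    """
    if "total" not in per_cell_ss:
        raise ValueError("per_cell_ss must include the 'total' component")
    grand = float(np.asarray(per_cell_ss["total"], dtype=float).sum())
    if grand <= 0:
        raise ValueError("all cells have zero SS: nothing to attribute")
    return {
        name: 100.0 * float(np.asarray(ss, dtype=float).sum()) / grand
        for name, ss in per_cell_ss.items()
        if name != "total"
    }
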