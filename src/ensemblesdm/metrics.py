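"""Assemblage-level change metrics from binary consensus maps.

Per cell, with SR the current richness, G the species gained and L the
species lost between timeframes:

* turnover T = (G + L) / (SR + G), in [0, 1], defined as 0 when SR+G = 0;
* retention = 100 * |current ∩ future| / |current| percent of the cell's
  current species keeping suitable climate (masked where SR = 0);
* per-species climate-space change: percent of currently suitable cells
  lost and newly gained, summarised across species by the median and the
  semi-interquartile range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "richness",
    "gains_losses",
    "turnover",
    "retention",
    "climate_space_change",
    "assemblage_maps",
    "AssemblageMaps",
    "RangeChangeSummary",
]


def _binary_matrix(maps_or_matrix) -> np.ndarray:
    """Accept a list of ConsensusMap or a (n_species, n_cells) binary array."""
    if isinstance(maps_or_matrix, np.ndarray):
        return maps_or_matrix.astype(np.uint8)
    maps = list(maps_or_matrix)
    grid = maps[0].grid
    for m in maps[1:]:
        if not grid.same_as(m.grid):
            raise ValueError("consensus maps on mismatched grids")
    return np.stack([m.presence for m in maps]).astype(np.uint8)


def richness(maps_or_matrix) -> np.ndarray:
    """Per-cell count of species whose binary consensus is presence."""
    return _binary_matrix(maps_or_matrix).sum(axis=0).astype(int)


def gains_losses(current, future) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell species gained (absent now, present later) and lost."""
    cur = _binary_matrix(current)
    fut = _binary_matrix(future)
    if cur.shape != fut.shape:
        raise ValueError("current and future matrices must align")
    G = ((fut == 1) & (cur == 0)).sum(axis=0).astype(int)
    L = ((cur == 1) & (fut == 0)).sum(axis=0).astype(int)
    return G, L


def turnover(SR, G, L):
    """Temporal turnover (G + L) / (SR + G); 0 where the cell has no
    community in either timeframe (SR + G = 0)."""
    SR, G, L = (np.asarray(a, dtype=float) for a in (SR, G, L))
    if np.any(SR < 0) or np.any(G < 0) or np.any(L < 0):
        raise ValueError("SR, G, L must be non-negative")
    if np.any(L > SR):
        raise ValueError("cannot lose more species than are present (L > SR)")
    denom = SR + G
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(denom > 0, (G + L) / np.where(denom > 0, denom, 1.0), 0.0)
    return T if T.ndim else float(T)


def retention(current, future, formula: str = "intersection") -> np.ndarray:
    """Percent of each cell's current species retaining suitability.

    The default formula is 100 * |current ∩ future| / |current|, bounded in
    [0, 100] and masked (NaN) where the cell currently holds no species.
    ``formula="additive"`` instead reports
    100 * (|current| + |current ∩ future|) / |current| — an alternative
    literal reading of the metric's verbal definition that is >= 100 by
    construction; it is exposed for comparison, not as the default.
    """
    cur = _binary_matrix(current)
    fut = _binary_matrix(future)
    if cur.shape != fut.shape:
        raise ValueError("current and future matrices must align")
    SR = cur.sum(axis=0).astype(float)
    remain = ((cur == 1) & (fut == 1)).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if formula == "intersection":
            out = 100.0 * remain / SR
        elif formula == "additive":
            out = 100.0 * (SR + remain) / SR
        else:
            raise ValueError("formula must be 'intersection' or 'additive'")
    return np.where(SR > 0, out, np.nan)


@dataclass
class AssemblageMaps:
    """Per-cell assemblage change surfaces between two timeframes."""

    current_richness: np.ndarray
    future_richness: np.ndarray
    gains: np.ndarray
    losses: np.ndarray
    turnover: np.ndarray
    retention_percent: np.ndarray  # NaN where no current species


def assemblage_maps(current, future, retention_formula: str = "intersection"):
    cur = _binary_matrix(current)
    fut = _binary_matrix(future)
    G, L = gains_losses(cur, fut)
    SR = cur.sum(axis=0).astype(int)
    return AssemblageMaps(
        current_richness=SR,
        future_richness=fut.sum(axis=0).astype(int),
        gains=G,
        losses=L,
        turnover=turnover(SR, G, L),
        retention_percent=retention(cur, fut, formula=retention_formula),
    )


@dataclass
class RangeChangeSummary:
    """Per-species range-size change and its across-species summary."""

    per_species: pd.DataFrame  # species, current_cells, future_cells,
    #   lost_pct, gained_pct, change_pct
    median_change_pct: float
    interquartile_deviation: float  # semi-interquartile range (Q3 - Q1) / 2
    mean_lost_pct: float
    mean_gained_pct: float


def climate_space_change(current, future, species: list[str] | None = None):
    """Per-species loss/gain of climatically suitable cells.

    lost% = 100 |current \\ future| / |current|;
    gained% = 100 |future \\ current| / |current|;
    change% = gained% - lost% = 100 (future - current) / current.
    Species summaries use the median and the semi-interquartile range
    (Q3 - Q1)/2 with linear-interpolation quartiles.
    """
    cur = _binary_matrix(current)
    fut = _binary_matrix(future)
    if cur.shape != fut.shape:
        raise ValueError("current and future matrices must align")
    if species is None and not isinstance(current, np.ndarray):
        species = [m.species for m in current]
    if species is None:
        species = [f"sp{i + 1:02d}" for i in range(cur.shape[0])]
    n_cur = cur.sum(axis=1).astype(float)
    if np.any(n_cur == 0):
        bad = species[int(np.argmax(n_cur == 0))]
        raise ValueError(f"species {bad!r} has an empty current range")
    lost = ((cur == 1) & (fut == 0)).sum(axis=1) / n_cur * 100.0
    gained = ((fut == 1) & (cur == 0)).sum(axis=1) / n_cur * 100.0
    change = gained - lost
    df = pd.DataFrame(
        {
            "species": species,
            "current_cells": cur.sum(axis=1).astype(int),
            "future_cells": fut.sum(axis=1).astype(int),
            "lost_pct": lost,
            "gained_pct": gained,
            "change_pct": change,
        }
    )
    q1, q3 = np.percentile(change, [25, 75])
    return RangeChangeSummary(
        per_species=df,
        median_change_pct=float(np.median(change)),
        interquartile_deviation=float((q3 - q1) / 2.0),
        mean_lost_pct=float(lost.mean()),
        mean_gained_pct=float(gained.mean()),
    )
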