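"""Projection stacks and TSS-weighted consensus maps.

For one species the calibrated models are projected onto every climate:
6 methods x 10 repeats = 60 binary layers for the current climate, and
6 methods x 4 climate models x 10 repeats = 240 layers per emission
scenario for the future.  The consensus is the frequency of layers
predicting presence, weighted by each layer's TSS (negative-skill layers
get weight zero), and a cell is a consensus presence when the weighted
frequency reaches 50% — the inclusive "50% or more" rule — while the
continuous frequency is retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .sdm import FittedRecord

__all__ = [
    "Layer",
    "ProjectionStack",
    "ConsensusMap",
    "project_stack",
    "weighted_frequency",
    "scenario_consensus",
]


@dataclass
class Layer:
    """One binary projection tagged by its provenance and skill."""

    method: str
    repeat: int
    values: np.ndarray  # (n_cells,) uint8
    tss: float
    climate_model: str = ""


@dataclass
class ProjectionStack:
    species: str
    timeframe: str  # "current" or "future"
    grid: Grid
    layers: list[Layer]
    scenario: str = ""

    def __post_init__(self):
        for lay in self.layers:
            v = np.asarray(lay.values)
            if v.shape != (self.grid.n_cells,):
                raise ValueError("layer length does not match grid")
            if not np.isin(v, (0, 1)).all():
                raise ValueError("projection layers must be binary")
            lay.values = v.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class ConsensusMap:
    """TSS-weighted projection frequency W in [0, 1] plus the binary call."""

    species: str
    timeframe: str
    grid: Grid
    frequency: np.ndarray  # (n_cells,) in [0, 1]
    scenario: str = ""
    threshold: float = 0.5

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.frequency.shape != (self.grid.n_cells,):
            raise ValueError("frequency length does not match grid")
        if np.any((self.frequency < -1e-9) | (self.frequency > 1 + 1e-9)):
            raise ValueError("consensus frequency must lie in [0, 1]")

    @property
    def presence(self) -> np.ndarray:
        """Binary consensus: presence iff W >= threshold (inclusive)."""
        return (self.frequency >= self.threshold).astype(np.uint8)

    @property
    def continuous_presence(self) -> np.ndarray:
        """The continuous frequency retained in presence cells, 0 elsewhere."""
        return np.where(self.presence == 1, self.frequency, 0.0)


def project_stack(
    records: list[FittedRecord],
    current_climate,
    future_climates=(),
) -> tuple[ProjectionStack, dict[str, ProjectionStack]]:
    """Project one species' calibrated models onto all climates.

    Each layer is ``indicator(score >= that model's threshold)`` and carries
    the model's validation TSS.  Returns the current stack and one future
    stack per scenario.
    """
    if not records:
        raise ValueError("no fitted records to project")
    species = records[0].species
    grid = current_climate.grid
    Xc = current_climate.matrix()
    current_layers = [
        Layer(
            method=r.method,
            repeat=r.repeat,
            values=(r.model.predict(Xc) >= r.threshold).astype(np.uint8),
            tss=r.tss,
        )
        for r in records
    ]
    current = ProjectionStack(
        species=species, timeframe="current", grid=grid, layers=current_layers
    )
    future: dict[str, ProjectionStack] = {}
    for clim in future_climates:
        if not clim.climate_model:
            raise ValueError("future climate lacks a climate-model label")
        if not grid.same_as(clim.grid):
            raise ValueError("future climate grid does not match the current grid")
        Xf = clim.matrix()
        scen = clim.scenario
        stack = future.setdefault(
            scen,
            ProjectionStack(
                species=species, timeframe="future", grid=grid, layers=[], scenario=scen
            ),
        )
        for r in records:
            stack.layers.append(
                Layer(
                    method=r.method,
                    repeat=r.repeat,
                    climate_model=clim.climate_model,
                    values=(r.model.predict(Xf) >= r.threshold).astype(np.uint8),
                    tss=r.tss,
                )
            )
    return current, future


def _layer_weights(stack: ProjectionStack, weight_mode: str) -> np.ndarray:
    if weight_mode == "per_layer":
        return np.array([max(lay.tss, 0.0) for lay in stack.layers])
    if weight_mode == "method_mean":
        by_method: dict[str, list[float]] = {}
        for lay in stack.layers:
            by_method.setdefault(lay.method, []).append(lay.tss)
        means = {m: max(float(np.mean(v)), 0.0) for m, v in by_method.items()}
        return np.array([means[lay.method] for lay in stack.layers])
    raise ValueError("weight_mode must be 'per_layer' or 'method_mean'")


def weighted_frequency(
    stack: ProjectionStack,
    threshold: float = 0.5,
    weight_mode: str = "per_layer",
    group_by_method: bool = False,
    on_zero_weights: str = "error",
) -> ConsensusMap:
    """TSS-weighted frequency of projections predicting presence.

    W(cell) = sum_j w_j b_j(cell) / sum_j w_j with w_j = max(TSS_j, 0).
    With ``group_by_method`` a consensus is built within each method first
    and the per-method frequencies are then averaged (weighted by the
    method's mean positive TSS).

    A stack whose layers are all worse than random has no usable weights;
    by default that is an explicit failure, but sub-ensembles assembled for
    bookkeeping (e.g. one method's repeats) may pass
    ``on_zero_weights="unweighted"`` to fall back to the plain frequency.
    """
    if not stack.layers:
        raise ValueError("empty projection stack")
    B = np.stack([lay.values for lay in stack.layers]).astype(float)
    if not group_by_method:
        w = _layer_weights(stack, weight_mode)
        if w.sum() <= 0:
            if on_zero_weights == "unweighted":
                w = np.ones(len(stack.layers))
            else:
                raise ValueError(
                    f"species {stack.species!r}: all layer weights are zero "
                    "(no model better than random)"
                )
        W = (w[:, None] * B).sum(axis=0) / w.sum()
    else:
        methods = sorted({lay.method for lay in stack.layers})
        freqs, mw = [], []
        for m in methods:
            idx = [i for i, lay in enumerate(stack.layers) if lay.method == m]
            w = np.array([max(stack.layers[i].tss, 0.0) for i in idx])
            if w.sum() <= 0:
                continue
            freqs.append((w[:, None] * B[idx]).sum(axis=0) / w.sum())
            mw.append(w.mean())
        if not freqs:
            raise ValueError(
                f"species {stack.species!r}: all layer weights are zero"
            )
        mw = np.asarray(mw)
        W = (mw[:, None] * np.stack(freqs)).sum(axis=0) / mw.sum()
    return ConsensusMap(
        species=stack.species,
        timeframe=stack.timeframe,
        grid=stack.grid,
        frequency=W,
        scenario=stack.scenario,
        threshold=threshold,
    )


def scenario_consensus(
    maps: list[ConsensusMap], statistic: str = "median"
) -> ConsensusMap:
    """Combine per-scenario consensus maps into one (default: per-cell
    median of the continuous frequencies, re-binarised at the threshold)."""
    if not maps:
        raise ValueError("need at least one scenario map")
    grid = maps[0].grid
    for m in maps[1:]:
        if not grid.same_as(m.grid):
            raise ValueError("scenario maps on mismatched grids")
    F = np.stack([m.frequency for m in maps])
    if statistic == "median":
        W = np.median(F, axis=0)
    elif statistic == "mean":
        W = F.mean(axis=0)
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    return ConsensusMap(
        species=maps[0].species,
        timeframe=maps[0].timeframe,
        grid=grid,
        frequency=W,
        scenario="consensus",
        threshold=maps[0].threshold,
    )
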