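"""Markov-chain land-conversion model and habitat filtering.

A transition-probability matrix between the native and anthropic classes
is estimated by comparing two categorical land-use rasters a few years
apart.  The quantity of future change per step comes from the Markov
chain (expected converted count = native count x P[native->anthropic]);
*where* that change lands is decided by a conversion-suitability model
fitted on covariates (elevation, precipitation, proximity layers) —
highest-suitability native cells convert first.  Finally, coarse-grid
consensus presences are filtered by the fraction of native habitat left
inside each coarse cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .ensemble import ConsensusMap
from .sdm import fit_model
from .synthetic import ANTHROPIC, NATIVE

__all__ = [
    "TransitionMatrix",
    "FineLandscape",
    "estimate_transition",
    "fit_conversion_suitability",
    "project_landuse",
    "habitat_filter",
    "native_fraction",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic class-transition probabilities over one interval."""

    classes: tuple[int, ...]
    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.classes)
        if self.P.shape != (k, k):
            raise ValueError("P must be square over the class set")
        if np.any((self.P < 0) | (self.P > 1)):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")

    def prob(self, i: int, j: int) -> float:
        return float(self.P[self.classes.index(i), self.classes.index(j)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.P, index=list(self.classes), columns=list(self.classes)).to_csv(
            path, index_label="from_class"
        )


@dataclass
class FineLandscape:
    """Fine-resolution land-use raster with covariates and the mapping from
    fine cells to the coarse modelling grid (block aggregation)."""

    landuse: np.ndarray  # (rows, cols) categorical
    covariates: dict[str, np.ndarray]
    block: int = 1  # fine cells per coarse cell side

    def covariate_matrix(self) -> np.ndarray:
        return np.column_stack([c.ravel() for c in self.covariates.values()])

    def coarse_cell_of(self, coarse_grid) -> np.ndarray:
        """Flat array mapping every fine cell to a coarse cell id (or -1
        when the coarse cell is outside the domain mask)."""
        rows, cols = self.landuse.shape
        if rows != coarse_grid.n_rows * self.block or cols != coarse_grid.n_cols * self.block:
            raise ValueError("fine dims must be coarse dims x block")
        rr, cc = np.meshgrid(
            np.arange(rows) // self.block, np.arange(cols) // self.block, indexing="ij"
        )
        flat_full = rr * coarse_grid.n_cols + cc
        id_of_full = np.full(coarse_grid.n_rows * coarse_grid.n_cols, -1, dtype=int)
        id_of_full[np.flatnonzero(coarse_grid.mask.ravel())] = coarse_grid.cell_ids()
        return id_of_full[flat_full.ravel()]


def estimate_transition(map_t0, map_t1, classes=(NATIVE, ANTHROPIC)) -> TransitionMatrix:
    """P[i->j] = count(cells i at t0 and j at t1) / count(i at t0); a class
    absent at t0 keeps an identity row."""
    t0 = np.asarray(map_t0).ravel()
    t1 = np.asarray(map_t1).ravel()
    if t0.shape != t1.shape:
        raise ValueError("maps have mismatched dimensions")
    k = len(classes)
    P = np.eye(k)
    for a, ci in enumerate(classes):
        at0 = t0 == ci
        n = int(at0.sum())
        if n == 0:
            continue
        P[a] = [np.count_nonzero(at0 & (t1 == cj)) / n for cj in classes]
    return TransitionMatrix(classes=tuple(classes), P=P)


def fit_conversion_suitability(
    landscape: FineLandscape,
    converted: np.ndarray,
    method: str = "GLM",
    seed: int = 0,
) -> np.ndarray:
    """Score every native-at-t0 cell's conversion propensity in [0, 1].

    Fits the shared probabilistic-classifier interface (default GLM) on
    native-at-t0 cells, labelled by whether they converted by t1, and
    returns scores over the full fine raster (NaN on non-native cells).
    """
    native = (np.asarray(landscape.landuse).ravel() == NATIVE)
    conv = np.asarray(converted).ravel().astype(int)
    if conv.shape != native.shape:
        raise ValueError("converted indicator must match the fine raster")
    X = landscape.covariate_matrix()
    model = fit_model(method, X[native], conv[native], random_state=seed & 0x7FFFFFFF)
    scores = np.full(native.shape, np.nan)
    scores[native] = model.predict(X[native])
    return scores.reshape(landscape.landuse.shape)


def project_landuse(
    map_t1: np.ndarray,
    P: TransitionMatrix,
    n_steps: int,
    suitability: np.ndarray,
    mode: str = "deterministic",
    seed: int = 0,
) -> np.ndarray:
    """Project land conversion ``n_steps`` intervals ahead.

    Per step the expected number of native cells converting is
    ``round_half_up(native_count * P[N->A])``; allocation converts the
    highest-suitability native cells first (ties broken by cell id), or
    samples proportionally to suitability in ``mode="stochastic"``.
    Anthropic never reverts while P[A->N] = 0.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    out = np.asarray(map_t1).copy()
    shape = out.shape
    out = out.ravel()
    suit = np.asarray(suitability, dtype=float).ravel()
    p_conv = P.prob(NATIVE, ANTHROPIC)
    rng = stream(seed, "allocation")
    for _ in range(n_steps):
        native_idx = np.flatnonzero(out == NATIVE)
        n_convert = int(np.floor(len(native_idx) * p_conv + 0.5))
        if n_convert <= 0:
            continue
        s = suit[native_idx]
        s = np.where(np.isnan(s), -np.inf, s)
        if mode == "deterministic":
            # stable sort on -s: ties resolved by ascending cell id
            order = np.argsort(-s, kind="stable")
            chosen = native_idx[order[:n_convert]]
        else:
            w = np.clip(s, 1e-12, None)
            chosen = rng.choice(
                native_idx, size=n_convert, replace=False, p=w / w.sum()
            )
        out[chosen] = ANTHROPIC
    return out.reshape(shape)


def native_fraction(landuse_fine: np.ndarray, landscape: FineLandscape, coarse_grid):
    """Fraction of each coarse cell's fine cells that are native (NaN for
    coarse cells with no mapped fine cells)."""
    mapping = landscape.coarse_cell_of(coarse_grid)
    lu = np.asarray(landuse_fine).ravel()
    ok = mapping >= 0
    counts = np.bincount(mapping[ok], minlength=coarse_grid.n_cells).astype(float)
    native = np.bincount(
        mapping[ok], weights=(lu[ok] == NATIVE).astype(float), minlength=coarse_grid.n_cells
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = native / counts
    return np.where(counts > 0, frac, np.nan)


def habitat_filter(
    consensus: ConsensusMap,
    landuse_fine: np.ndarray,
    landscape: FineLandscape,
    min_native_fraction: float = 0.5,
) -> ConsensusMap:
    """Drop consensus presences from coarse cells whose remaining native
    habitat fraction falls below ``min_native_fraction``.

    A coarse cell with no mapped fine cells is masked (frequency set 0).
    The returned map never gains presences, so filtered richness is
    bounded above by unfiltered richness everywhere.
    """
    if not 0.0 <= min_native_fraction <= 1.0:
        raise ValueError("min_native_fraction must be in [0, 1]")
    frac = native_fraction(landuse_fine, landscape, consensus.grid)
    keep = np.where(np.isnan(frac), False, frac >= min_native_fraction)
    freq = np.where(keep, consensus.frequency, 0.0)
    return ConsensusMap(
        species=consensus.species,
        timeframe=consensus.timeframe,
        grid=consensus.grid,
        frequency=freq,
        scenario=consensus.scenario,
        threshold=consensus.threshold,
    )
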