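"""Synthetic study systems: gridded climates, virtual species, land use.

Real analyses of this kind start from range polygons and interpolated
climate surfaces.  This module generates stand-ins with *known* truth so
every downstream stage (model fitting, consensus, turnover, uncertainty,
land-conversion filtering) can be validated end to end:

* monthly climate fields with a latitudinal gradient plus low-pass-filtered
  noise, and future variants obtained by additive warming deltas and
  multiplicative precipitation factors;
* virtual species with product-Gaussian suitability over the four
  bioclimatic predictors, presences sampled Bernoulli(suitability);
* paired categorical land-use rasters (native/anthropic) at finer
  resolution, with conversion driven by a known logistic function of
  covariates.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from ._rng import stream
from .grid import BIOCLIM_VARS, ClimateGrid, Grid, OccurrenceMatrix

__all__ = [
    "MonthlyClimateField",
    "VirtualSpecies",
    "generate_climate",
    "derive_bioclim",
    "generate_virtual_species",
    "generate_landuse_pair",
    "NATIVE",
    "ANTHROPIC",
]

NATIVE, ANTHROPIC = 0, 1


@dataclass
class MonthlyClimateField:
    """Per-cell monthly temperature (°C) and precipitation (mm >= 0)."""

    temp: np.ndarray  # (rows, cols, 12)
    precip: np.ndarray  # (rows, cols, 12)
    timeframe: str = "current"
    climate_model: str = ""
    scenario: str = ""

    def __post_init__(self):
        self.temp = np.asarray(self.temp, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        if self.temp.shape != self.precip.shape or self.temp.shape[-1] != 12:
            raise ValueError("expected (rows, cols, 12) monthly arrays")
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be non-negative")

    @property
    def dims(self) -> tuple[int, int]:
        return self.temp.shape[:2]


@dataclass
class VirtualSpecies:
    """A species with a known product-Gaussian climatic niche.

    Suitability of a climate vector x is
    ``scaling * exp(-sum_k (x_k - mu_k)^2 / (2 sigma_k^2))`` — separable
    Gaussians, no interactions, so truth is analytically known.
    """

    label: str
    mu: dict[str, float]
    sigma: dict[str, float]
    scaling: float = 1.0

    def __post_init__(self):
        for v in BIOCLIM_VARS:
            if self.sigma[v] <= 0:
                raise ValueError("niche breadth sigma must be strictly positive")
        if not (0 < self.scaling <= 1):
            raise ValueError("scaling must be in (0, 1]")

    def suitability(self, climate: ClimateGrid) -> np.ndarray:
        z2 = np.zeros(climate.grid.n_cells)
        for v in BIOCLIM_VARS:
            z2 += ((climate.values[v] - self.mu[v]) / self.sigma[v]) ** 2
        return self.scaling * np.exp(-0.5 * z2)


def _smooth_noise(rng, dims, sd, radius):
    noise = rng.normal(0.0, sd, size=dims)
    if radius > 0:
        noise = ndimage.uniform_filter(noise, size=2 * radius + 1, mode="nearest")
    return noise


def generate_climate(
    dims: tuple[int, int],
    n_future_models: int = 4,
    n_scenarios: int = 2,
    warming_deltas=None,
    precip_factors=None,
    seed: int = 0,
    smooth_radius: int = 3,
    model_labels=None,
    scenario_labels=None,
):
    """Generate a current monthly climate field plus future variants.

    ``warming_deltas`` and ``precip_factors`` each hold one value per
    (future model, scenario) pair in model-major order; a future field is
    the current field with the delta added to every monthly temperature and
    precipitation scaled by the factor.  Defaults emulate mid-century
    warming of 1.8-3.75 °C with mild drying.
    """
    rows, cols = dims
    if rows < 2 or cols < 2:
        raise ValueError("dims must be at least 2x2")
    n_pairs = n_future_models * n_scenarios
    if model_labels is None:
        model_labels = [f"GCM{i + 1}" for i in range(n_future_models)]
    if scenario_labels is None:
        scenario_labels = ["A2a", "B2a"][:n_scenarios] or []
        while len(scenario_labels) < n_scenarios:
            scenario_labels.append(f"S{len(scenario_labels) + 1}")
    if warming_deltas is None:
        base = [2.5, 3.0, 2.0, 2.2][:n_future_models]
        while len(base) < n_future_models:
            base.append(2.5)
        factor = {0: 1.25, 1: 0.9}  # pessimistic vs optimistic scenario
        warming_deltas = [
            base[m] * factor.get(s, 1.0)
            for m in range(n_future_models)
            for s in range(n_scenarios)
        ]
    warming_deltas = list(warming_deltas)
    if len(warming_deltas) != n_pairs:
        raise ValueError(
            f"need {n_pairs} warming deltas (one per model x scenario), "
            f"got {len(warming_deltas)}"
        )
    if precip_factors is None:
        precip_factors = [1.0 - 0.04 * d for d in warming_deltas]
    precip_factors = list(precip_factors)
    if len(precip_factors) != n_pairs:
        raise ValueError("precip_factors length must match warming_deltas")

    rng = stream(seed, "climate")
    lat = np.linspace(0.0, 1.0, rows)[:, None] * np.ones((1, cols))
    lon = np.ones((rows, 1)) * np.linspace(0.0, 1.0, cols)[None, :]
    diag = (lat + lon) / 2.0
    anti = (1.0 - lat + lon) / 2.0

    # each bioclim driver gets its own spatial orientation plus independent
    # low-pass noise, so the four predictors stay identifiable rather than
    # collinear along a single gradient
    tmean = 28.0 - 12.0 * lat + _smooth_noise(rng, dims, 3.0, smooth_radius)
    tamp = 3.0 + 7.0 * lon + np.abs(_smooth_noise(rng, dims, 1.5, smooth_radius))
    months = np.arange(12)
    cycle = np.cos(2 * np.pi * (months - 0.5) / 12.0)
    temp = tmean[:, :, None] + tamp[:, :, None] * cycle[None, None, :]

    # annual precipitation with a wet/dry seasonal concentration
    pann = 1800.0 - 1200.0 * anti + _smooth_noise(rng, dims, 200.0, smooth_radius)
    pann = np.clip(pann, 60.0, None)
    conc = np.clip(
        0.3 + 0.5 * diag + _smooth_noise(rng, dims, 0.15, smooth_radius), 0.0, 0.95
    )
    shares = 1.0 + conc[:, :, None] * cycle[None, None, :]
    shares = shares / shares.sum(axis=2, keepdims=True)
    precip = pann[:, :, None] * shares

    current = MonthlyClimateField(temp=temp, precip=precip, timeframe="current")
    futures = []
    k = 0
    for m in range(n_future_models):
        for s in range(n_scenarios):
            futures.append(
                MonthlyClimateField(
                    temp=temp + warming_deltas[k],
                    precip=precip * precip_factors[k],
                    timeframe="future",
                    climate_model=model_labels[m],
                    scenario=scenario_labels[s],
                )
            )
            k += 1
    return current, futures


def derive_bioclim(
    mcf: MonthlyClimateField,
    grid: Grid | None = None,
    cv_as_percent: bool = True,
    ddof: int = 0,
) -> ClimateGrid:
    """Summarise 12 monthly values per cell into the four bioclim variables.

    Temperature seasonality is the population SD (``ddof=0``, the WorldClim
    bio4 convention) times 100; precipitation seasonality is the CV of
    monthly precipitation, reported as percent by default (bio15
    convention; set ``cv_as_percent=False`` for the raw ratio).  Cells with
    zero mean monthly precipitation have undefined seasonality and are
    masked out of the returned grid's domain.
    """
    rows, cols = mcf.dims
    if grid is None:
        grid = Grid(n_rows=rows, n_cols=cols)
    elif (grid.n_rows, grid.n_cols) != (rows, cols):
        raise ValueError("grid dims do not match the monthly field")

    t, p = mcf.temp[grid.mask], mcf.precip[grid.mask]  # (n_cells, 12)
    bio1 = t.mean(axis=1)
    bio4 = t.std(axis=1, ddof=ddof) * 100.0
    bio12 = p.sum(axis=1)
    pmean = p.mean(axis=1)
    cv_scale = 100.0 if cv_as_percent else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        bio15 = cv_scale * p.std(axis=1, ddof=ddof) / pmean
    undefined = pmean == 0
    if undefined.any():
        keep_mask = grid.mask.copy()
        rc = grid.rowcols()[undefined]
        keep_mask[rc[:, 0], rc[:, 1]] = False
        grid = Grid(grid.n_rows, grid.n_cols, grid.cell_size, grid.origin, keep_mask)
        keep = ~undefined
        bio1, bio4, bio12, bio15 = bio1[keep], bio4[keep], bio12[keep], bio15[keep]
    return ClimateGrid(
        grid=grid,
        values={"bio1": bio1, "bio4": bio4, "bio12": bio12, "bio15": bio15},
        timeframe=mcf.timeframe,
        climate_model=mcf.climate_model,
        scenario=mcf.scenario,
    )


def generate_virtual_species(
    n_species: int,
    climate: ClimateGrid,
    seed: int = 0,
    min_presences: int = 10,
    retry_cap: int = 100,
    sigma_frac: tuple[float, float] = (0.12, 0.3),
    scaling_range: tuple[float, float] = (0.7, 1.0),
):
    """Draw virtual species on a climate grid and sample their occurrences.

    Niche optima are drawn inside the central 10-90% quantile band of each
    variable; breadths are uniform fractions of the variable's observed
    range (narrow enough that niches are "strong" and recoverable).  A
    species with fewer than ``min_presences`` presences, or with no
    absences, is redrawn with fresh parameters up to ``retry_cap`` times.

    Returns ``(species_list, OccurrenceMatrix)``; the matrix carries the
    true suitability surfaces in its ``truth`` attribute.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    X = climate.matrix()
    lo = {v: np.quantile(climate.values[v], 0.1) for v in BIOCLIM_VARS}
    hi = {v: np.quantile(climate.values[v], 0.9) for v in BIOCLIM_VARS}
    rng_range = {
        v: float(climate.values[v].max() - climate.values[v].min())
        for v in BIOCLIM_VARS
    }
    species, truths, occ = [], [], []
    for i in range(n_species):
        rng = stream(seed, "species", i)
        for attempt in range(retry_cap):
            mu = {v: float(rng.uniform(lo[v], hi[v])) for v in BIOCLIM_VARS}
            sigma = {
                v: float(rng.uniform(*sigma_frac) * max(rng_range[v], 1e-12))
                for v in BIOCLIM_VARS
            }
            sp = VirtualSpecies(
                label=f"sp{i + 1:02d}",
                mu=mu,
                sigma=sigma,
                scaling=float(rng.uniform(*scaling_range)),
            )
            s = sp.suitability(climate)
            pres = (rng.random(len(s)) < s).astype(np.uint8)
            if pres.sum() >= min_presences and pres.sum() < len(pres):
                species.append(sp)
                truths.append(s)
                occ.append(pres)
                break
        else:
            raise RuntimeError(
                f"species index {i}: could not draw >= {min_presences} "
                f"presences in {retry_cap} attempts"
            )
    matrix = OccurrenceMatrix(
        species=[sp.label for sp in species],
        grid=climate.grid,
        values=np.array(occ),
        truth=np.array(truths),
    )
    return species, matrix


@dataclass
class LandusePair:
    """Two fine-resolution categorical rasters plus the covariates and the
    true conversion-propensity function that generated the change."""

    t0: np.ndarray  # (rows, cols) in {NATIVE, ANTHROPIC}
    t1: np.ndarray
    covariates: dict[str, np.ndarray]
    truth_score: np.ndarray  # logistic conversion propensity, in (0, 1)
    truth_coefs: dict[str, float] = field(default_factory=dict)


def generate_landuse_pair(
    fine_dims: tuple[int, int],
    native_fraction_t0: float = 0.75,
    conversion_rate: float = 0.1,
    suitability_covariates: dict[str, np.ndarray] | None = None,
    seed: int = 0,
    smooth_radius: int = 3,
    noise_temperature: float = 0.3,
) -> LandusePair:
    """Generate paired land-use maps with suitability-driven conversion.

    The t1 map converts ``round(conversion_rate * n_native)`` native cells
    of t0, chosen preferentially where a known logistic function of the
    covariates is high (Gumbel-perturbed ranking, so the preference is
    strong but not a hard threshold).  Anthropic cells never revert.
    """
    if not 0 <= conversion_rate <= 1:
        raise ValueError("conversion_rate must be in [0, 1]")
    rng = stream(seed, "landuse")
    rows, cols = fine_dims
    if suitability_covariates is None:
        suitability_covariates = {
            "elevation": 400.0 + _smooth_noise(rng, fine_dims, 250.0, smooth_radius),
            "precip": 1400.0 + _smooth_noise(rng, fine_dims, 300.0, smooth_radius),
            "access": _smooth_noise(rng, fine_dims, 1.0, smooth_radius),
        }
    coefs, eta = {}, np.zeros(fine_dims)
    default_coefs = {"elevation": -1.2, "precip": -0.6, "access": 1.8}
    for j, (name, cov) in enumerate(suitability_covariates.items()):
        z = (cov - cov.mean()) / (cov.std() or 1.0)
        coefs[name] = default_coefs.get(name, ((-1.0) ** j) * 1.0)
        eta += coefs[name] * z
    truth_score = expit(eta)

    n_cells = rows * cols
    n_native = int(round(native_fraction_t0 * n_cells))
    t0 = np.full(fine_dims, ANTHROPIC, dtype=np.int8)
    native_idx = rng.choice(n_cells, size=n_native, replace=False)
    t0.ravel()[native_idx] = NATIVE

    n_convert = int(np.floor(conversion_rate * n_native + 0.5))
    t1 = t0.copy()
    if n_convert > 0:
        scores = truth_score.ravel()[native_idx]
        keys = np.log(np.clip(scores, 1e-12, None))
        if noise_temperature > 0:
            keys = keys + noise_temperature * rng.gumbel(size=n_native)
        order = np.argsort(-keys, kind="stable")
        t1.ravel()[native_idx[order[:n_convert]]] = ANTHROPIC
    return LandusePair(
        t0=t0,
        t1=t1,
        covariates=suitability_covariates,
        truth_score=truth_score,
        truth_coefs=coefs,
    )
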