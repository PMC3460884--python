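"""Grid/raster data model shared by every pipeline stage.

The study domain is a regular latitude/longitude grid (0.25-degree style
cells).  Cells are identified by an integer ``cell_id`` enumerating the
masked-in cells in row-major order; all per-cell surfaces are stored as 1-D
arrays indexed by cell id.  Species range polygons are rasterized with a
centre-in-polygon rule: a cell is a presence iff its centre point falls
inside (or on the boundary of) any polygon of that species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

#: The four bioclimatic predictors, in WorldClim naming: annual mean
#: temperature (bio1, °C), temperature seasonality (bio4, SD x 100),
#: annual precipitation (bio12, mm), precipitation seasonality (bio15, CV %).
BIOCLIM_VARS = ("bio1", "bio4", "bio12", "bio15")


@dataclass(frozen=True)
class Grid:
    """Regular lat/lon grid with an optional boolean domain mask."""

    n_rows: int
    n_cols: int
    cell_size: float = 0.25
    origin: tuple[float, float] = (0.0, 0.0)  # (lon, lat) of upper-left corner
    mask: np.ndarray | None = None  # True = inside domain; default all True

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dims must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        m = self.mask
        if m is None:
            m = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            m = np.asarray(m, dtype=bool)
            if m.shape != (self.n_rows, self.n_cols):
                raise ValueError("mask shape does not match grid dims")
        object.__setattr__(self, "mask", m)

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def rowcols(self) -> np.ndarray:
        """(n_cells, 2) array of (row, col) for each cell id, row-major."""
        rows, cols = np.nonzero(self.mask)
        return np.column_stack([rows, cols])

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def id_of(self, row: int, col: int) -> int:
        if not self.mask[row, col]:
            raise KeyError(f"cell ({row}, {col}) is outside the domain mask")
        flat = np.flatnonzero(self.mask.ravel())
        return int(np.searchsorted(flat, row * self.n_cols + col))

    def centers(self) -> np.ndarray:
        """(n_cells, 2) lon/lat coordinates of masked-in cell centres."""
        rc = self.rowcols()
        lon0, lat0 = self.origin
        lon = lon0 + (rc[:, 1] + 0.5) * self.cell_size
        lat = lat0 - (rc[:, 0] + 0.5) * self.cell_size
        return np.column_stack([lon, lat])

    def to_full(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-cell 1-D array onto the full (n_rows, n_cols) raster."""
        values = np.asarray(values)
        out = np.full((self.n_rows, self.n_cols), fill, dtype=float)
        out[self.mask] = values
        return out

    def same_as(self, other: "Grid") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and bool(np.array_equal(self.mask, other.mask))
        )


@dataclass
class ClimateGrid:
    """Per-cell values of the four bioclimatic variables for one
    timeframe / climate-model / scenario combination."""

    grid: Grid
    values: dict[str, np.ndarray]  # var -> (n_cells,) float array
    timeframe: str = "current"
    climate_model: str = ""
    scenario: str = ""

    def __post_init__(self):
        for var in BIOCLIM_VARS:
            if var not in self.values:
                raise ValueError(f"missing bioclimatic variable {var!r}")
            v = np.asarray(self.values[var], dtype=float)
            if v.shape != (self.grid.n_cells,):
                raise ValueError(f"{var}: expected {self.grid.n_cells} cell values")
            self.values[var] = v
        if np.any(self.values["bio12"] < 0):
            raise ValueError("annual precipitation must be non-negative")
        for var in BIOCLIM_VARS:
            if np.any(np.isnan(self.values[var])):
                raise ValueError(f"{var} contains missing values inside the domain")

    def matrix(self) -> np.ndarray:
        """(n_cells, 4) predictor matrix in BIOCLIM_VARS order."""
        return np.column_stack([self.values[v] for v in BIOCLIM_VARS])

    def to_frame(self) -> pd.DataFrame:
        rc = self.grid.rowcols()
        df = pd.DataFrame(
            {"cell_id": self.grid.cell_ids(), "row": rc[:, 0], "col": rc[:, 1]}
        )
        for v in BIOCLIM_VARS:
            df[v] = self.values[v]
        return df

    @property
    def label(self) -> str:
        parts = [self.timeframe]
        if self.climate_model:
            parts.append(self.climate_model)
        if self.scenario:
            parts.append(self.scenario)
        return "_".join(parts)


@dataclass
class OccurrenceMatrix:
    """Species x cell binary presence/absence matrix."""

    species: list[str]
    grid: Grid
    values: np.ndarray  # (n_species, n_cells) in {0, 1}
    #: when synthetic, the true suitability surfaces (n_species, n_cells)
    truth: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.species), self.grid.n_cells):
            raise ValueError("matrix shape does not match species x cells")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"non-binary value in row for species {self.species[i]!r}"
            )
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicated species labels")
        self.values = self.values.astype(np.uint8)

    def presences(self, species: str) -> int:
        return int(self.values[self.species.index(species)].sum())

    def validate_for_modelling(self) -> None:
        """Every species needs at least one presence and one absence."""
        for i, sp in enumerate(self.species):
            n = int(self.values[i].sum())
            if n == 0 or n == self.grid.n_cells:
                raise ValueError(f"species {sp!r} has a single-class row")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.species, name="species"),
            columns=[f"cell_{i}" for i in self.grid.cell_ids()],
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, grid: Grid) -> "OccurrenceMatrix":
        df = pd.read_csv(path, index_col="species")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicated species label {dup!r} in CSV")
        vals = df.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"non-binary value in CSV row for {df.index[i]!r}")
        return cls(species=list(df.index), grid=grid, values=vals)


def overlay_ranges(polygons: dict, grid: Grid) -> OccurrenceMatrix:
    """Rasterize species range polygons onto the grid.

    Parameters
    ----------
    polygons
        Mapping species label -> shapely geometry (or list of geometries)
        in the grid's lon/lat coordinate system.  An empty list yields an
        all-absence row and a warning.

    Notes
    -----
    Uses the centre-in-polygon rule (``covers``, so boundary points count),
    which is monotone: enlarging a polygon never removes presences.
    """
    centers = grid.centers()
    points = shapely.points(centers[:, 0], centers[:, 1])
    species = list(polygons)
    values = np.zeros((len(species), grid.n_cells), dtype=np.uint8)
    for i, sp in enumerate(species):
        geoms = polygons[sp]
        if geoms is None or (isinstance(geoms, (list, tuple)) and len(geoms) == 0):
            warnings.warn(f"species {sp!r}: empty polygon list, all-absence row")
            continue
        if isinstance(geoms, (list, tuple)):
            geom = shapely.union_all(geoms)
        else:
            geom = geoms
        if geom.is_empty:
            warnings.warn(f"species {sp!r}: empty geometry, all-absence row")
            continue
        values[i] = shapely.covers(geom, points).astype(np.uint8)
    return OccurrenceMatrix(species=species, grid=grid, values=values)


def roundtrip_matrix(matrix: OccurrenceMatrix, path) -> OccurrenceMatrix:
    """Write the matrix to CSV and read it back (I/O self-check)."""
    matrix.to_csv(path)
    return OccurrenceMatrix.from_csv(path, matrix.grid)


def write_ascii_grid(path, grid: Grid, values: np.ndarray, nodata: float = -9999.0):
    """Write a per-cell surface as an ESRI ASCII grid (single band)."""
    full = grid.to_full(values)
    full = np.where(np.isnan(full), nodata, full)
    lon0, lat0 = grid.origin
    yll = lat0 - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {lon0}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for r in range(grid.n_rows):
            fh.write(" ".join(format(v, ".6g") for v in full[r]) + "\n")


def write_surface_csv(path, grid: Grid, surfaces: dict[str, np.ndarray]) -> None:
    """Tidy CSV (cell_id, row, col, variable, value) for one or more surfaces."""
    rc = grid.rowcols()
    frames = []
    for name, vals in surfaces.items():
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": grid.cell_ids(),
                    "row": rc[:, 0],
                    "col": rc[:, 1],
                    "variable": name,
                    "value": np.asarray(vals, dtype=float),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
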