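"""Gridded environmental covariates and presence/absence observations.

The spatial unit throughout the package is a square raster cell (8 km by
default, matching downscaled meteorological products). An
:class:`EnvironmentalGrid` stacks one 2-D layer per environmental variable
over a common extent; a :class:`DetectionGrid` holds a binary
presence (1) / absence (0) outcome per cell, with NaN marking unsurveyed
cells.

Raster layers are read and written as ESRI ASCII grids (``.asc``), one file
per variable; observations as CSV tables with columns
``cell_id,x,y,outcome``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "EnvironmentalGrid",
    "DetectionGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_grid_dir",
    "write_grid_dir",
    "read_detections_csv",
    "write_detections_csv",
]

#: sentinel written to .asc files for masked / unsurveyed cells
NODATA = -9999.0


@dataclass
class EnvironmentalGrid:
    """Rectangular grid of cells, each carrying a covariate vector.

    Parameters
    ----------
    values
        Mapping from variable code (e.g. ``"Prec"``, ``"Temp"``, ``"Lati"``)
        to a 2-D float array of shape ``(n_rows, n_cols)``. Insertion order
        is the declared variable order. Units are the variable's natural
        units (mm, degC, degN, ...); covariates are used unstandardized.
    cell_size
        Cell edge length in km. Defaults to 8 km.
    origin
        ``(x, y)`` of the lower-left corner of the grid.
    mask
        Optional boolean array, ``True`` where the cell is valid. ``None``
        means all cells are valid. Row 0 is the northernmost row.
    """

    values: dict[str, np.ndarray]
    cell_size: float = 8.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise InputError("EnvironmentalGrid needs at least one variable")
        if not (math.isfinite(self.cell_size) and self.cell_size > 0):
            raise InputError(f"cell_size must be positive, got {self.cell_size}")
        shapes = {v: np.asarray(a).shape for v, a in self.values.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2 or min(first) < 1:
            raise InputError(f"layers must be 2-D with positive dims, got {first}")
        for var, shp in shapes.items():
            if shp != first:
                raise InputError(
                    f"layer {var!r} has shape {shp}, expected {first}"
                )
        self.values = {v: np.asarray(a, dtype=float) for v, a in self.values.items()}
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != first:
                raise InputError("mask shape does not match layers")
        for var, arr in self.values.items():
            bad = ~np.isfinite(arr)
            if self.mask is not None:
                bad &= self.mask
            if bad.any():
                raise InputError(
                    f"variable {var!r} has non-finite values on valid cells"
                )

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.values.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def variables(self) -> list[str]:
        return list(self.values)

    def valid_mask(self) -> np.ndarray:
        """Boolean array of valid cells (all-True when no mask is set)."""
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell centre coordinates ``(x, y)``, each shaped like the grid.

        Row 0 is the top (largest y), matching raster conventions.
        """
        rows, cols = np.indices(self.shape)
        x0, y0 = self.origin
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.n_rows - rows - 0.5) * self.cell_size
        return x, y

    # -- access -----------------------------------------------------------

    def layer(self, variable: str) -> np.ndarray:
        try:
            return self.values[variable]
        except KeyError:
            raise InputError(
                f"variable {variable!r} not in grid (has: {', '.join(self.variables)})"
            ) from None

    def design_matrix(self, variables: list[str] | None = None) -> np.ndarray:
        """Stack the requested layers into an ``(n_cells, k)`` matrix.

        Cells are flattened row-major; masked cells are retained (callers
        subset with :meth:`valid_mask` as needed) so that row ``i`` always
        corresponds to cell id ``i``.
        """
        variables = self.variables if variables is None else variables
        cols = [self.layer(v).ravel() for v in variables]
        return np.column_stack(cols) if cols else np.empty((self.n_cells, 0))

    def to_table(self) -> pd.DataFrame:
        """One row per cell: ``cell_id, x, y`` plus one column per variable."""
        x, y = self.cell_centres()
        data = {"cell_id": np.arange(self.n_cells), "x": x.ravel(), "y": y.ravel()}
        for var in self.variables:
            data[var] = self.layer(var).ravel()
        return pd.DataFrame(data)


@dataclass
class DetectionGrid:
    """Per-cell presence/absence outcomes aligned with an EnvironmentalGrid.

    ``outcomes`` is a float array with values in {0.0, 1.0, NaN}; NaN marks
    a cell without a survey outcome. ``n1``/``n0`` (presences/absences) are
    derived, never stored, so they can never disagree with the data.
    """

    outcomes: np.ndarray
    cell_size: float = 8.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if self.outcomes.ndim != 2:
            raise InputError("outcomes must be a 2-D array")
        finite = self.outcomes[np.isfinite(self.outcomes)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise InputError("outcomes must be 0, 1 or NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.outcomes.shape

    @property
    def n1(self) -> int:
        """Number of presence cells."""
        return int(np.nansum(self.outcomes == 1.0))

    @property
    def n0(self) -> int:
        """Number of absence cells."""
        return int(np.nansum(self.outcomes == 0.0))

    @property
    def prevalence(self) -> float:
        """n1 / (n1 + n0); the proportion of surveyed cells with a presence."""
        n = self.n1 + self.n0
        if n == 0:
            raise InputError("no surveyed cells")
        return self.n1 / n

    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.outcomes)


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, array: np.ndarray, *, cell_size: float,
                     origin: tuple[float, float] = (0.0, 0.0),
                     mask: np.ndarray | None = None) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost)."""
    array = np.asarray(array, dtype=float)
    out = array.copy()
    invalid = ~np.isfinite(out)
    if mask is not None:
        invalid |= ~np.asarray(mask, bool)
    out[invalid] = NODATA
    n_rows, n_cols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {origin[0]!r}\n")
        fh.write(f"yllcorner {origin[1]!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN.

    Returns ``(array, cell_size, origin)``.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: bad header value {parts[1]!r}"
                    ) from None
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: {exc}") from None
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise InputError(f"{path}: missing header field {key!r}")
    array = np.array(rows, dtype=float)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if array.shape != expected:
        raise InputError(
            f"{path}: data shape {array.shape} does not match header {expected}"
        )
    nodata = header.get("nodata_value", NODATA)
    array[array == nodata] = np.nan
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return array, header["cellsize"], origin


def write_grid_dir(directory: str | Path, grid: EnvironmentalGrid) -> list[Path]:
    """Write one ``<variable>.asc`` file per layer; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for var in grid.variables:
        p = directory / f"{var}.asc"
        write_ascii_grid(p, grid.layer(var), cell_size=grid.cell_size,
                         origin=grid.origin, mask=grid.mask)
        paths.append(p)
    return paths


def read_grid_dir(directory: str | Path,
                  variables: list[str] | None = None) -> EnvironmentalGrid:
    """Assemble an EnvironmentalGrid from a directory of ``.asc`` layers.

    Cells that are NODATA in any layer become masked. When ``variables``
    is omitted, all ``.asc`` files are loaded in sorted-name order.
    """
    directory = Path(directory)
    if variables is None:
        variables = sorted(p.stem for p in directory.glob("*.asc"))
    if not variables:
        raise InputError(f"no .asc layers found in {directory}")
    values: dict[str, np.ndarray] = {}
    cell_size = None
    origin = None
    for var in variables:
        p = directory / f"{var}.asc"
        if not p.exists():
            raise InputError(f"missing raster layer: {p}")
        arr, cs, org = read_ascii_grid(p)
        if cell_size is None:
            cell_size, origin = cs, org
        elif (cs, org) != (cell_size, origin):
            raise InputError(f"{p}: geometry differs from other layers")
        values[var] = arr
    stacked = np.stack(list(values.values()))
    mask = np.isfinite(stacked).all(axis=0)
    if mask.all():
        mask = None
    else:
        # represent masked cells with a finite placeholder so the grid validates
        for var in values:
            values[var] = np.where(np.isfinite(values[var]), values[var], 0.0)
    return EnvironmentalGrid(values, cell_size=cell_size, origin=origin, mask=mask)


# ---------------------------------------------------------------------------
# Detection table IO
# ---------------------------------------------------------------------------

def write_detections_csv(path: str | Path, det: DetectionGrid) -> None:
    """Write per-cell outcomes as ``cell_id,x,y,outcome`` (blank = unsurveyed)."""
    helper = EnvironmentalGrid({"_": np.zeros(det.shape)},
                               cell_size=det.cell_size, origin=det.origin)
    x, y = helper.cell_centres()
    out = det.outcomes.ravel()
    df = pd.DataFrame({
        "cell_id": np.arange(out.size),
        "x": x.ravel(),
        "y": y.ravel(),
        "outcome": [("" if not np.isfinite(v) else int(v)) for v in out],
    })
    df.to_csv(path, index=False)


def read_detections_csv(path: str | Path, n_rows: int, n_cols: int,
                        cell_size: float = 8.0,
                        origin: tuple[float, float] = (0.0, 0.0)) -> DetectionGrid:
    """Read a ``cell_id,x,y,outcome`` table back into a DetectionGrid."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    for col in ("cell_id", "outcome"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    outcomes = np.full(n_rows * n_cols, np.nan)
    ids = df["cell_id"].to_numpy(dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= outcomes.size):
        raise InputError(
            f"{path}: cell_id out of range for a {n_rows}x{n_cols} grid"
        )
    vals = pd.to_numeric(df["outcome"], errors="coerce").to_numpy(dtype=float)
    outcomes[ids] = vals
    return DetectionGrid(outcomes.reshape(n_rows, n_cols),
                         cell_size=cell_size, origin=origin)
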