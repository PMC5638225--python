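"""Equal-area analysis grids and gridded climate stacks.

All spatial data in this package live on a fishnet-like square grid in an
equal-area projection: ``GridSpec`` describes the grid geometry in km, and
``ClimateStack`` holds one or more named climate variables on that grid,
tagged with the scenario (current conditions, or an emission pathway plus a
climate-forecast realization) they describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GridSpec", "Scenario", "CURRENT", "ClimateStack"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a square-celled, equal-area analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions. Rows index south to north is *not* assumed; row 0
        is the top (north) row, matching raster conventions.
    cell_size
        Side length of each (square) cell, in km. Cell area is
        ``cell_size ** 2``.
    origin
        ``(x, y)`` of the grid's lower-left corner, in km.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ValueError("grid too small")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in km."""
        x0, y0 = self.origin
        return (
            x0,
            x0 + self.n_cols * self.cell_size,
            y0,
            y0 + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates in km, C order."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        # row 0 is the northernmost row
        ys = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat cell index for point coordinates; raises if out of extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, xmax, ymin, ymax = self.extent
        bad = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
        if np.any(bad):
            offenders = np.nonzero(bad)[0][:10].tolist()
            raise ValueError(f"points outside grid extent at indices {offenders}")
        col = np.clip(((x - xmin) / self.cell_size).astype(int), 0, self.n_cols - 1)
        # y increases northwards but row index increases southwards
        row = np.clip(self.n_rows - 1 - ((y - ymin) / self.cell_size).astype(int), 0, self.n_rows - 1)
        return row * self.n_cols + col


@dataclass(frozen=True)
class Scenario:
    """Tag identifying which climate a stack describes.

    ``Scenario.current()`` for the baseline; otherwise an emission pathway
    (e.g. ``"rcp26"``/``"rcp85"``) paired with a forecast (AOGCM) id.
    """

    rcp: str | None = None
    forecast: str | None = None

    @classmethod
    def current(cls) -> "Scenario":
        return cls(None, None)

    @property
    def is_current(self) -> bool:
        return self.rcp is None and self.forecast is None

    def __str__(self) -> str:
        if self.is_current:
            return "current"
        return f"{self.rcp}/{self.forecast}"


CURRENT = Scenario.current()


@dataclass
class ClimateStack:
    """Named climate variables on an equal-area grid.

    ``values`` has shape ``(n_variables, n_rows, n_cols)``; missing cells
    may be NaN only in stacks read from external rasters — generated stacks
    are always finite.
    """

    grid: GridSpec
    variables: list[str]
    values: np.ndarray
    scenario: Scenario = field(default_factory=Scenario.current)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.variables), self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.variables)}, {self.grid.n_rows}, {self.grid.n_cols})"
            )
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def layer(self, name: str) -> np.ndarray:
        """The (n_rows, n_cols) array for one variable."""
        try:
            i = self.variables.index(name)
        except ValueError:
            raise KeyError(f"no variable named {name!r}") from None
        return self.values[i]

    def table(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """Cells-by-variables design matrix (C-order flattening of the grid)."""
        names = list(variables) if variables is not None else self.variables
        missing = [v for v in names if v not in self.variables]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        idx = [self.variables.index(v) for v in names]
        return self.values[idx].reshape(len(idx), -1).T

    def subset(self, variables: Iterable[str]) -> "ClimateStack":
        names = list(variables)
        idx = [self.variables.index(v) for v in names]
        return ClimateStack(self.grid, names, self.values[idx].copy(), self.scenario)

    def with_scenario(self, scenario: Scenario) -> "ClimateStack":
        return ClimateStack(self.grid, list(self.variables), self.values, scenario)
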