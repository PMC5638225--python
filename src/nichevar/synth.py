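"""Virtual landscapes, climates, species, range maps and occurrence records.

This module generates the full set of inputs the distribution-modeling
pipeline consumes, with the statistical structure real inputs would have:

* climate surfaces with a dominant geographic gradient plus a spatially
  autocorrelated random field (interpolated-station products look like this);
* future scenario stacks structured as emission pathway x forecast variant,
  with divergent mean shifts between pathways and a smooth forecast-specific
  perturbation;
* virtual species whose true occupancy follows a low-dimensional climatic
  niche, thresholded to hit a prescribed prevalence;
* expert-style range maps that over-smooth and dilate true occupancy
  (commission error in the direction range maps exhibit);
* sparse, optionally spatially biased point-locality records drawn from
  occupied cells only.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grid import CURRENT, ClimateStack, GridSpec, Scenario

__all__ = [
    "VirtualSpecies",
    "RangeMap",
    "OccurrenceSet",
    "NicheConfig",
    "gen_climate",
    "gen_future",
    "gen_species",
    "gen_range_map",
    "gen_point_records",
    "DEFAULT_GRID",
    "DEFAULT_VARIABLES",
]

#: Study-default grid: 50 x 50 cells of 25 km, an equal-area desk-scale extent.
DEFAULT_GRID = GridSpec(n_rows=50, n_cols=50, cell_size=25.0)

#: Five synthetic variables playing the roles of the bioclimatic predictors
#: (diurnal range, seasonality, warm-quarter temperature, dry-month and
#: warm-quarter precipitation).
DEFAULT_VARIABLES = ["v1", "v2", "v3", "v4", "v5"]


@dataclass
class VirtualSpecies:
    """A simulated species with a known climatic niche.

    ``niche`` maps variable name -> ``("bell", optimum, breadth)`` for a
    Gaussian response or ``("box", lower, upper)`` for hard tolerance
    bounds.  ``true_occupancy`` is the boolean ground-truth occupancy grid
    derived from niche suitability and ``prevalence_target``.
    """

    species_id: str
    niche: dict[str, tuple]
    prevalence_target: float
    true_occupancy: np.ndarray
    suitability: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_occupied(self) -> int:
        return int(self.true_occupancy.sum())


@dataclass
class RangeMap:
    """Expert-polygon-style range map as per-cell coverage fractions."""

    species_id: str
    grid: GridSpec
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.shape != self.grid.shape:
            raise ValueError("coverage shape does not match grid")
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise ValueError("coverage fractions must lie in [0, 1]")

    def support(self, threshold: float = 0.5) -> np.ndarray:
        """Boolean mask of cells with coverage strictly above ``threshold``."""
        return self.coverage > threshold


@dataclass
class OccurrenceSet:
    """Point-locality records for one species, coordinates in km."""

    species_id: str
    points: np.ndarray  # (n, 2) x, y
    source_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class NicheConfig:
    """How virtual-species niches are drawn.

    n_niche_vars
        Number of climate variables each species responds to.
    shape
        "bell" for Gaussian responses, "box" for tolerance intervals.
    breadth_range
        Niche breadth (bell: response sd; box: half-width), as multiples of
        the landscape sd of the variable.
    prevalence_range
        Per-species prevalence target drawn uniformly from this interval.
    optimum_quantiles
        Niche optima are placed at climate values between these landscape
        quantiles, keeping species ranges inside the modeled extent.
    """

    n_niche_vars: int = 2
    shape: str = "bell"
    breadth_range: tuple[float, float] = (0.35, 0.8)
    prevalence_range: tuple[float, float] = (0.08, 0.25)
    optimum_quantiles: tuple[float, float] = (0.15, 0.85)


def _smooth_field(shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Kernel-smoothed white noise, rescaled to zero mean, unit sd."""
    noise = rng.standard_normal(shape)
    if sigma_cells > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="nearest")
    sd = noise.std()
    if sd == 0:  # pragma: no cover - only a 1-cell grid could do this
        raise ValueError("degenerate smoothed field")
    return (noise - noise.mean()) / sd


def gen_climate(
    grid: GridSpec = DEFAULT_GRID,
    n_vars: int = 5,
    gradient_strength: float = 1.0,
    autocorr_range: float = 150.0,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> ClimateStack:
    """Generate a current-conditions climate stack.

    Each variable is a deterministic geographic gradient (alternating
    east-west, north-south and radial "elevation-like" ramps, scaled by
    ``gradient_strength``) plus a spatially autocorrelated random field
    whose correlation length is set by ``autocorr_range`` (km).
    """
    if grid.n_cells < 4:
        raise ValueError("grid too small")
    if n_vars < 2:
        raise ValueError("need at least 2 climate variables")
    if autocorr_range <= 0:
        raise ValueError("autocorr_range must be positive")
    names = list(variables) if variables is not None else [f"v{i + 1}" for i in range(n_vars)]
    if len(names) != n_vars:
        raise ValueError("variables length must equal n_vars")

    rng = np.random.default_rng(seed)
    rows = np.linspace(-1, 1, grid.n_rows)[:, None] * np.ones((1, grid.n_cols))
    cols = np.ones((grid.n_rows, 1)) * np.linspace(-1, 1, grid.n_cols)[None, :]
    radial = np.hypot(rows, cols) / np.sqrt(2)
    ramps = [cols, rows, 1 - radial, 0.5 * (cols - rows), 0.5 * (cols + rows)]

    sigma = autocorr_range / grid.cell_size
    layers = np.empty((n_vars, grid.n_rows, grid.n_cols))
    for i in range(n_vars):
        ramp = ramps[i % len(ramps)]
        layers[i] = gradient_strength * ramp + _smooth_field(grid.shape, sigma, rng)
    return ClimateStack(grid, names, layers, CURRENT)


def gen_future(
    current: ClimateStack,
    rcp_shifts: Mapping[str, Mapping[str, float]],
    n_forecasts: int = 5,
    forecast_spread: float = 0.3,
    seed: int = 0,
    forecast_ids: Sequence[str] | None = None,
) -> list[ClimateStack]:
    """Generate one future stack per (emission pathway, forecast variant).

    Each stack is the current climate plus the pathway's per-variable mean
    shift plus a smooth forecast-specific perturbation with sd
    ``forecast_spread``.  The perturbation field is seeded by forecast id
    and shared across pathways, mimicking the same forecast model driven by
    two emission pathways.
    """
    if n_forecasts < 1:
        raise ValueError("n_forecasts must be >= 1")
    if not rcp_shifts:
        raise ValueError("rcp_shifts must be non-empty")
    for rcp, shifts in rcp_shifts.items():
        unknown = set(shifts) - set(current.variables)
        if unknown:
            raise ValueError(f"shift variables {sorted(unknown)} not in stack (rcp {rcp!r})")
    if forecast_ids is None:
        forecast_ids = [f"gcm{i + 1}" for i in range(n_forecasts)]
    elif len(forecast_ids) != n_forecasts:
        raise ValueError("forecast_ids length must equal n_forecasts")

    # one perturbation field per (forecast, variable), shared across rcps
    sigma = max(2.0, 0.1 * min(current.grid.shape))
    perturbations = {}
    for j, fc in enumerate(forecast_ids):
        rng = np.random.default_rng(np.random.SeedSequence([seed, j]))
        perturbations[fc] = np.stack(
            [forecast_spread * _smooth_field(current.grid.shape, sigma, rng) for _ in current.variables]
        )

    stacks = []
    for rcp in rcp_shifts:
        shift = np.array([rcp_shifts[rcp].get(v, 0.0) for v in current.variables])
        for fc in forecast_ids:
            values = current.values + shift[:, None, None] + perturbations[fc]
            stacks.append(
                ClimateStack(current.grid, list(current.variables), values, Scenario(rcp, fc))
            )
    return stacks


def _suitability(climate: ClimateStack, niche: Mapping[str, tuple]) -> np.ndarray:
    suit = np.ones(climate.grid.shape)
    for var, resp in niche.items():
        layer = climate.layer(var)
        kind = resp[0]
        if kind == "bell":
            _, opt, breadth = resp
            suit *= np.exp(-0.5 * ((layer - opt) / breadth) ** 2)
        elif kind == "box":
            _, lo, hi = resp
            suit *= ((layer >= lo) & (layer <= hi)).astype(float)
        else:
            raise ValueError(f"unknown niche response kind {kind!r}")
    return suit


def gen_species(
    climate: ClimateStack,
    n_species: int = 10,
    niche_config: NicheConfig | None = None,
    seed: int = 0,
) -> list[VirtualSpecies]:
    """Draw virtual species with low-dimensional climatic niches.

    True suitability is the product of per-variable responses; occupancy is
    the top-``k`` suitability cells with ``k = round(prevalence * n_cells)``
    (ties broken by a seeded random order), so realized prevalence is within
    one cell of the target whenever enough cells have positive suitability.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    cfg = niche_config or NicheConfig()
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_species):
        prevalence = rng.uniform(*cfg.prevalence_range)
        if not 0 < prevalence < 1:
            raise ValueError("prevalence_target must lie in (0, 1)")
        chosen = rng.choice(
            climate.variables, size=min(cfg.n_niche_vars, climate.n_variables), replace=False
        )
        niche: dict[str, tuple] = {}
        for var in chosen:
            layer = climate.layer(var)
            opt = np.quantile(layer, rng.uniform(*cfg.optimum_quantiles))
            breadth = layer.std() * rng.uniform(*cfg.breadth_range)
            if cfg.shape == "bell":
                niche[var] = ("bell", float(opt), float(breadth))
            else:
                niche[var] = ("box", float(opt - breadth), float(opt + breadth))
        sp = make_species(climate, f"sp{s + 1:03d}", niche, prevalence, tie_break_seed=int(rng.integers(2**31)))
        out.append(sp)
    return out


def make_species(
    climate: ClimateStack,
    species_id: str,
    niche: Mapping[str, tuple],
    prevalence_target: float,
    tie_break_seed: int = 0,
) -> VirtualSpecies:
    """Build one virtual species from an explicit niche definition."""
    if not 0 < prevalence_target < 1:
        raise ValueError("prevalence_target must lie in (0, 1)")
    suit = _suitability(climate, niche)
    n_cells = climate.grid.n_cells
    k = max(1, int(round(prevalence_target * n_cells)))
    flat = suit.ravel()
    positive = flat > 0
    if positive.sum() < k:
        warnings.warn(
            f"{species_id}: only {int(positive.sum())} cells have positive suitability; "
            f"prevalence target {prevalence_target:.3f} not reachable",
            stacklevel=2,
        )
        k = max(1, int(positive.sum()))
    tie = np.random.default_rng(tie_break_seed).random(n_cells)
    order = np.lexsort((tie, -flat))  # best suitability first, seeded tie-break
    occ = np.zeros(n_cells, dtype=bool)
    occ[order[:k]] = True
    occ &= positive
    if not occ.any():
        raise ValueError(f"{species_id}: no occupied cells")
    return VirtualSpecies(
        species_id=species_id,
        niche=dict(niche),
        prevalence_target=float(prevalence_target),
        true_occupancy=occ.reshape(climate.grid.shape),
        suitability=suit,
    )


def gen_range_map(
    sp: VirtualSpecies,
    grid: GridSpec,
    dilation_cells: int = 2,
    smoothing: float = 0.7,
    seed: int = 0,
) -> RangeMap:
    """Expert-style range map: smoothed dilation of true occupancy.

    Coverage is a Gaussian-smoothed indicator of the morphologically dilated
    occupancy.  When ``dilation_cells >= 1`` coverage is floored at just
    above 0.5 on every truly occupied cell, so the range-map support always
    contains the true range — the commission-error direction expert maps
    exhibit.  ``seed`` perturbs the pre-smoothing mask edge very slightly to
    vary polygon outlines between species.
    """
    if dilation_cells < 0:
        raise ValueError("dilation_cells must be >= 0")
    occ = sp.true_occupancy
    if occ.shape != grid.shape:
        raise ValueError("species occupancy does not match grid")
    mask = occ.astype(float)
    if dilation_cells > 0:
        dilated = ndimage.binary_dilation(occ, iterations=dilation_cells)
        edge = dilated & ~occ
        rng = np.random.default_rng(seed)
        mask = dilated.astype(float)
        mask[edge] *= rng.uniform(0.8, 1.0, size=int(edge.sum()))
    coverage = ndimage.gaussian_filter(mask, sigma=smoothing, mode="nearest") if smoothing > 0 else mask
    coverage = np.clip(coverage, 0.0, 1.0)
    if dilation_cells >= 1:
        coverage[occ] = np.maximum(coverage[occ], 0.5 + 1e-9)
    return RangeMap(sp.species_id, grid, coverage)


def gen_point_records(
    sp: VirtualSpecies,
    grid: GridSpec,
    n_records: int = 60,
    bias_surface: np.ndarray | None = None,
    seed: int = 0,
    source_tag: str = "synthetic",
) -> OccurrenceSet:
    """Sample point-locality records from occupied cells.

    Cells are drawn (with replacement) with probability proportional to
    ``bias_surface`` restricted to occupied cells — uniform if None — and
    each record is jittered uniformly inside its cell.  Every record
    therefore falls in a truly occupied cell: observation error is not
    simulated here.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    occ_flat = sp.true_occupancy.ravel()
    occupied = np.nonzero(occ_flat)[0]
    if occupied.size == 0:
        raise ValueError(f"{sp.species_id}: species occupies no cells")
    if bias_surface is None:
        weights = np.ones(occupied.size)
    else:
        bias = np.asarray(bias_surface, dtype=float).ravel()
        if bias.size != grid.n_cells:
            raise ValueError("bias_surface size does not match grid")
        if np.any(bias < 0):
            raise ValueError("bias weights must be non-negative")
        weights = bias[occupied]
        if weights.sum() == 0:
            raise ValueError("bias_surface is zero on every occupied cell")
    rng = np.random.default_rng(seed)
    cells = rng.choice(occupied, size=n_records, p=weights / weights.sum())
    rows, cols = np.divmod(cells, grid.n_cols)
    x0, y0 = grid.origin
    x = x0 + (cols + rng.random(n_records)) * grid.cell_size
    y = y0 + (grid.n_rows - rows - rng.random(n_records)) * grid.cell_size
    return OccurrenceSet(sp.species_id, np.column_stack([x, y]), source_tag)
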