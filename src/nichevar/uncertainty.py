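"""Factorial design enumeration and per-cell variance partitioning.

The projection experiment is factorial: biological data type x modeling
method (or ensemble family) x emission pathway x climate forecast.  For
each grid cell the richness-change response C - F (current minus future
richness) observed once per design combination is decomposed by a
hierarchical ANOVA without replication: balanced main-effect sums of
squares for data type, method and pathway, forecast SS nested within
pathway (or fully crossed), and the remainder as residual.  A factor's
variance component is its share of the total sum of squares.

Species-level range shifts use the relative change (F - C) / C so that
losses are negative; the dispersion of those shifts across the design is
regressed on observed range size.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluation import RichnessSurface

__all__ = [
    "DesignTable",
    "RangeShiftRecord",
    "VarianceComponents",
    "build_design",
    "range_shift",
    "count_total_loss",
    "richness_change_stack",
    "anova_partition",
    "uncertainty_maps",
    "shift_sd_vs_range",
]


@dataclass
class DesignTable:
    """All combinations of the design factors, in lexicographic order."""

    factors: dict[str, list]
    rows: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def _make_table(factors: dict[str, list]) -> DesignTable:
    names = list(factors)
    rows = pd.DataFrame(
        list(itertools.product(*(factors[n] for n in names))), columns=names
    )
    return DesignTable(factors, rows)


def build_design(
    datasets: int = 2,
    methods: int = 9,
    rcps: int = 2,
    forecasts: int = 5,
    replicates: int = 10,
    stage: str = "fit",
    families: int = 3,
) -> DesignTable:
    """Enumerate the design rows for one stage of the experiment.

    Stages and their factor sets:

    * ``fit`` — datasets x methods x replicates (models fitted per species)
    * ``current_single`` — methods x replicates (current projections per
      species per data type)
    * ``current_ensemble`` — datasets x families
    * ``future_ensemble`` — datasets x families x rcps x forecasts
    """
    for name, v in [
        ("datasets", datasets), ("methods", methods), ("rcps", rcps),
        ("forecasts", forecasts), ("replicates", replicates), ("families", families),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    data_levels = ["range_map", "points"][:datasets] or [f"d{i}" for i in range(datasets)]
    if datasets > 2:
        data_levels = [f"d{i + 1}" for i in range(datasets)]
    method_levels = [f"m{i + 1}" for i in range(methods)]
    family_levels = ["envelope", "statistical", "machine_learning"][:families]
    if families > 3:
        family_levels = [f"f{i + 1}" for i in range(families)]
    rcp_levels = ["rcp26", "rcp85"][:rcps] if rcps <= 2 else [f"rcp{i + 1}" for i in range(rcps)]
    fc_levels = [f"gcm{i + 1}" for i in range(forecasts)]
    rep_levels = list(range(1, replicates + 1))

    if stage == "fit":
        factors = {"data_type": data_levels, "method": method_levels, "replicate": rep_levels}
    elif stage == "current_single":
        factors = {"method": method_levels, "replicate": rep_levels}
    elif stage == "current_ensemble":
        factors = {"data_type": data_levels, "family": family_levels}
    elif stage == "future_ensemble":
        factors = {
            "data_type": data_levels,
            "family": family_levels,
            "rcp": rcp_levels,
            "forecast": fc_levels,
        }
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return _make_table(factors)


@dataclass
class RangeShiftRecord:
    """Relative change in suitable area for one species x design row."""

    species_id: str
    combination: dict
    C: float
    F: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("species absent under current climate")
        if self.F < 0:
            raise ValueError("future area cannot be negative")

    @property
    def delta_rel(self) -> float:
        """(F - C) / C; -1 is total loss, 0 is no change, losses negative."""
        return (self.F - self.C) / self.C


def range_shift(C: float, F: float, species_id: str = "", combination: dict | None = None) -> RangeShiftRecord:
    """Relative range shift between current (C) and future (F) suitable area."""
    return RangeShiftRecord(species_id, combination or {}, float(C), float(F))


def count_total_loss(records: list[RangeShiftRecord], tol: float = 1e-12) -> int:
    """Species predicted to lose all suitable area by >= 1 design combination."""
    lost = {r.species_id for r in records if r.delta_rel <= -1 + tol}
    return len(lost)


def richness_change_stack(
    current: dict | RichnessSurface,
    futures: dict,
    design: DesignTable,
    current_keys: tuple[str, ...] = ("data_type", "family"),
) -> np.ndarray:
    """Per-cell richness-change responses, one column per design row.

    ``futures`` maps each design-row key (the tuple of the row's factor
    levels) to its future RichnessSurface.  ``current`` is either a single
    current surface used for every row, or a dict keyed by the
    ``current_keys`` factors (one current ensemble per data type and
    family).  The response is C - F: positive values are projected
    richness losses.
    """
    cols = []
    grid = None
    for _, row in design.rows.iterrows():
        fut = futures[tuple(row)]
        if isinstance(current, RichnessSurface):
            cur = current
        else:
            cur = current[tuple(row[k] for k in current_keys)]
        if grid is None:
            grid = fut.grid
        if fut.grid != grid or cur.grid != grid:
            raise ValueError("richness surfaces are on different grids")
        cols.append(cur.values.ravel() - fut.values.ravel())
    return np.column_stack(cols)


@dataclass
class VarianceComponents:
    """Per-cell variance decomposition over the design factors.

    ``proportions`` is (n_cells, n_factors + 1) with columns in
    ``factor_names`` order plus a final residual column; rows of flagged
    (zero-variance) cells are all zero.
    """

    factor_names: list[str]
    proportions: np.ndarray
    total_ss: np.ndarray
    flagged: np.ndarray  # True where total_ss == 0

    def as_frame(self) -> pd.DataFrame:
        cols = self.factor_names + ["residual"]
        df = pd.DataFrame(self.proportions, columns=cols)
        df["total_ss"] = self.total_ss
        df["flagged"] = self.flagged
        return df


def anova_partition(
    y: np.ndarray,
    design: DesignTable,
    nesting: str = "forecast_within_rcp",
) -> VarianceComponents:
    """Hierarchical ANOVA without replication, per cell (vectorized).

    ``y`` is (n_cells, n_rows): one observation per design combination per
    cell.  Main-effect SS use the balanced-design formula
    ``SS_f = n_per_level * sum_levels (mean_level - grand_mean)^2``; with
    ``nesting="forecast_within_rcp"`` the forecast SS is computed within
    each pathway, ``SS_fc = sum_rcp sum_fc n_cell * (mean_rcp_fc - mean_rcp)^2``;
    the residual is the remainder to the total SS.  Cells with zero total
    SS are flagged and get all-zero components.
    """
    if nesting not in ("forecast_within_rcp", "fully_crossed"):
        raise ValueError("nesting must be 'forecast_within_rcp' or 'fully_crossed'")
    rows = design.rows
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] != len(rows):
        raise ValueError(f"y has {y.shape[1]} columns but design has {len(rows)} rows")
    # balance check: every factor-level combination must appear exactly once
    if rows.duplicated().any():
        raise ValueError("hierarchical ANOVA requires balanced factorial (duplicate rows)")
    counts = rows.groupby(list(rows.columns), observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("hierarchical ANOVA requires balanced factorial")

    n = len(rows)
    grand = y.mean(axis=1, keepdims=True)
    ss_total = ((y - grand) ** 2).sum(axis=1)

    factor_names = [c for c in rows.columns]
    nested = nesting == "forecast_within_rcp" and {"rcp", "forecast"} <= set(factor_names)

    ss = {}
    for fac in factor_names:
        if nested and fac == "forecast":
            continue
        codes, _ = pd.factorize(rows[fac])
        n_levels = codes.max() + 1
        level_sum = np.zeros((y.shape[0], n_levels))
        np.add.at(level_sum.T, codes, y.T)  # accumulate columns by level
        n_per = np.bincount(codes)
        level_mean = level_sum / n_per
        ss[fac] = (n_per * (level_mean - grand) ** 2).sum(axis=1)
    if nested:
        pair_codes, _ = pd.factorize(pd.Series(zip(rows["rcp"], rows["forecast"])))
        rcp_codes, _ = pd.factorize(rows["rcp"])
        n_pairs = pair_codes.max() + 1
        pair_sum = np.zeros((y.shape[0], n_pairs))
        np.add.at(pair_sum.T, pair_codes, y.T)
        pair_n = np.bincount(pair_codes)
        pair_mean = pair_sum / pair_n
        n_rcp = rcp_codes.max() + 1
        rcp_sum = np.zeros((y.shape[0], n_rcp))
        np.add.at(rcp_sum.T, rcp_codes, y.T)
        rcp_mean = rcp_sum / np.bincount(rcp_codes)
        pair_rcp = np.empty(n_pairs, dtype=int)
        for p in range(n_pairs):
            pair_rcp[p] = rcp_codes[np.nonzero(pair_codes == p)[0][0]]
        ss["forecast"] = (pair_n * (pair_mean - rcp_mean[:, pair_rcp]) ** 2).sum(axis=1)

    explained = sum(ss[f] for f in factor_names)
    residual = np.maximum(ss_total - explained, 0.0)

    ordered = factor_names
    comps = np.zeros((y.shape[0], len(ordered) + 1))
    nonzero = ss_total > 0
    denom = np.where(nonzero, ss_total, 1.0)
    for i, fac in enumerate(ordered):
        comps[:, i] = np.where(nonzero, ss[fac] / denom, 0.0)
    comps[:, -1] = np.where(nonzero, residual / denom, 0.0)
    return VarianceComponents(
        factor_names=ordered,
        proportions=comps,
        total_ss=ss_total,
        flagged=~nonzero,
    )


def uncertainty_maps(components: VarianceComponents, grid) -> dict[str, np.ndarray]:
    """Per-factor component maps plus a total-SS map, on the grid.

    Flagged (zero-variance) cells are NaN in every component map so they
    render as missing data.
    """
    shape = grid.shape
    out = {}
    names = components.factor_names + ["residual"]
    for i, name in enumerate(names):
        layer = components.proportions[:, i].astype(float).copy()
        layer[components.flagged] = np.nan
        out[name] = layer.reshape(shape)
    out["total_ss"] = components.total_ss.reshape(shape)
    return out


def shift_sd_vs_range(
    records: list[RangeShiftRecord], observed_range: dict[str, float]
) -> dict:
    """Regress projection disagreement on observed range size.

    For every species the standard deviation of ``delta_rel`` over all its
    design combinations measures how much projections disagree; that SD is
    regressed (OLS) on the species' observed range size (presence count).
    Returns slope, F statistic and residual degrees of freedom, plus the
    per-species table.
    """
    df = pd.DataFrame(
        {"species_id": [r.species_id for r in records], "delta_rel": [r.delta_rel for r in records]}
    )
    per = df.groupby("species_id")["delta_rel"].agg(["std", "size"]).reset_index()
    single = per["size"] < 2
    if single.any():
        warnings.warn(
            f"excluding {int(single.sum())} species with a single combination", stacklevel=2
        )
        per = per[~single]
    per = per[per["species_id"].isin(observed_range)]
    if len(per) < 3:
        raise ValueError("need at least 3 species for the regression")
    per["range_size"] = per["species_id"].map(observed_range)
    X = sm.add_constant(per["range_size"].to_numpy(dtype=float))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # F is 0/0 when every species has the same SD
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = sm.OLS(per["std"].to_numpy(), X).fit()
        fvalue, f_pvalue = fit.fvalue, fit.f_pvalue
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "F": float(fvalue) if np.isfinite(fvalue) else 0.0,
        "p": float(f_pvalue) if np.isfinite(f_pvalue) else 1.0,
        "df_resid": int(fit.df_resid),
        "table": per.reset_index(drop=True),
    }
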