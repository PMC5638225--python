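"""End-to-end factorial projection experiment on virtual species.

``run_experiment`` wires every stage together: generate a virtual landscape
and species, derive both biological data types (range maps and point
records), build and filter PA matrices, screen predictors, fit all nine
methods over repeated random partitions, evaluate and threshold each model,
build TSS-weighted family ensembles for the current climate and every
(emission pathway x forecast) future, stack richness surfaces, and
partition the per-cell richness-change variance across the design factors.

The default configuration is the desk-scale analogue of the study design:
2 data types x 9 methods x 10 random partitions per species (180 fitted
models), 2 pathways x 5 forecasts of future climate, family-level
ensembles (2 x 3 current, 2 x 3 x 2 x 5 = 60 future projections per
species).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import occurrence as occ
from . import sdm, synth, uncertainty as unc
from .grid import ClimateStack, GridSpec
from .methods import FAMILIES, METHOD_FAMILIES
from .predictors import select_variables

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

#: Pathway-specific mean climate shifts (in landscape-sd units): the
#: pessimistic pathway roughly triples the optimistic warming/drying.
DEFAULT_RCP_SHIFTS: dict[str, dict[str, float]] = {
    "rcp26": {"v1": 0.4, "v2": 0.3, "v3": 0.4, "v4": -0.2, "v5": -0.15},
    "rcp85": {"v1": 1.2, "v2": 0.9, "v3": 1.2, "v4": -0.6, "v5": -0.45},
}


@dataclass
class ExperimentConfig:
    """All knobs of the factorial experiment, with study-shaped defaults."""

    n_rows: int = 30
    n_cols: int = 30
    cell_size: float = 25.0
    n_vars: int = 5
    gradient_strength: float = 1.0
    autocorr_range: float = 150.0
    n_species: int = 10
    niche: synth.NicheConfig = field(default_factory=synth.NicheConfig)
    rcp_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_RCP_SHIFTS
    )
    n_forecasts: int = 5
    forecast_spread: float = 0.3
    n_records: int = 80
    dilation_cells: int = 1
    range_smoothing: float = 0.6
    min_presences: int = 30
    correlation_cutoff: float = 0.6
    methods: tuple[str, ...] = tuple(METHOD_FAMILIES)
    n_repeats: int = 10
    train_fraction: float = 0.75
    min_tss: float = 0.5
    richness_mode: str = "expected"
    nesting: str = "forecast_within_rcp"

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size)


@dataclass
class ExperimentResult:
    """Everything the experiment computes, ready for reporting."""

    config: ExperimentConfig
    species_ids: list[str]
    variable_selection: object
    evaluations: pd.DataFrame
    consensus_current: dict
    consensus_future: dict
    richness_current: dict
    richness_future: dict
    design: unc.DesignTable
    responses: np.ndarray
    components: unc.VarianceComponents
    shift_records: list
    total_loss_count: int
    shift_regression: dict | None
    observed_range: dict[str, int]

    def median_components(self) -> dict[str, float]:
        """Median variance component per factor over non-degenerate cells."""
        ok = ~self.components.flagged
        names = self.components.factor_names + ["residual"]
        return {
            name: float(np.median(self.components.proportions[ok, i]))
            for i, name in enumerate(names)
        }

    def design_counts(self) -> dict[str, int]:
        """The factorial bookkeeping: fitted models and projections per species."""
        n_methods = len(self.config.methods)
        n_fam = len({METHOD_FAMILIES[m] for m in self.config.methods})
        n_rcps = len(self.config.rcp_shifts)
        return {
            "models_fitted_per_species": unc.build_design(
                2, n_methods, n_rcps, self.config.n_forecasts, self.config.n_repeats, "fit"
            ).n_rows,
            "current_projections_per_species_per_data_type": unc.build_design(
                2, n_methods, n_rcps, self.config.n_forecasts, self.config.n_repeats,
                "current_single",
            ).n_rows,
            "current_ensembles_per_species": unc.build_design(
                2, n_methods, n_rcps, self.config.n_forecasts, self.config.n_repeats,
                "current_ensemble", families=n_fam,
            ).n_rows,
            "future_projections_per_species": unc.build_design(
                2, n_methods, n_rcps, self.config.n_forecasts, self.config.n_repeats,
                "future_ensemble", families=n_fam,
            ).n_rows,
        }


def _subseed(seed: int, *key) -> int:
    """Stable derived seed below 2**31."""
    ss = np.random.SeedSequence([seed, *map(_hash_part, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def _hash_part(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part)
    # process-independent hash (builtin str hash is salted per run)
    return zlib.crc32(str(part).encode()) % (2**31)


def run_experiment(config: ExperimentConfig | None = None, seed: int = 0) -> ExperimentResult:
    """Run the full factorial experiment; deterministic given ``seed``."""
    cfg = config or ExperimentConfig()
    grid = cfg.grid

    # --- synthetic inputs -------------------------------------------------
    climate = synth.gen_climate(
        grid, cfg.n_vars, cfg.gradient_strength, cfg.autocorr_range, seed=_subseed(seed, "climate")
    )
    future_stacks = synth.gen_future(
        climate, cfg.rcp_shifts, cfg.n_forecasts, cfg.forecast_spread, seed=_subseed(seed, "future")
    )
    species = synth.gen_species(climate, cfg.n_species, cfg.niche, seed=_subseed(seed, "species"))

    range_maps = [
        synth.gen_range_map(sp, grid, cfg.dilation_cells, cfg.range_smoothing,
                            seed=_subseed(seed, "rmap", sp.species_id))
        for sp in species
    ]
    records = [
        synth.gen_point_records(sp, grid, cfg.n_records, seed=_subseed(seed, "points", sp.species_id))
        for sp in species
    ]
    rmap_by_id = {m.species_id: m for m in range_maps}
    records = [
        occ.filter_records_by_range(r, rmap_by_id[r.species_id]) for r in records
    ]

    # --- PA matrices and filters -----------------------------------------
    pa_range = occ.filter_min_presences(
        occ.pa_from_range_maps(range_maps, grid), cfg.min_presences
    )
    pa_points = occ.filter_min_presences(
        occ.pa_from_points(records, grid), cfg.min_presences
    )
    kept = [s for s in pa_range.species_ids if s in set(pa_points.species_ids)]
    if not kept:
        raise RuntimeError("no species passed the presence filters in both data types")
    pa = {"range_map": pa_range, "points": pa_points}

    # --- predictors -------------------------------------------------------
    selection = select_variables(climate, cfg.correlation_cutoff)
    current = climate.subset(selection.kept)
    futures = {
        (s.scenario.rcp, s.scenario.forecast): s.subset(selection.kept) for s in future_stacks
    }

    # --- fit, evaluate, project ------------------------------------------
    eval_rows = []
    # binaries[(species, dtype, method, rep)][scenario key] -> BinarySurface
    consensus_current: dict = {}
    consensus_future: dict = {}
    families = sorted({METHOD_FAMILIES[m] for m in cfg.methods}, key=FAMILIES.index)
    rcps = list(cfg.rcp_shifts)
    forecast_ids = sorted({fc for (_, fc) in futures})

    dropped_species: set[str] = set()
    per_species_members: dict = {}
    for sp_id in kept:
        for dtype in ("range_map", "points"):
            col = pa[dtype].column(sp_id)
            presences = np.nonzero(col == 1)[0]
            pseudo = sdm.sample_pseudo_absences(
                pa[dtype], sp_id, "match", seed=_subseed(seed, "pseudo", sp_id, dtype)
            )
            splits = sdm.make_splits(
                presences, pseudo, cfg.train_fraction, cfg.n_repeats,
                seed=_subseed(seed, "splits", sp_id, dtype),
            )
            table = current.table()
            for method in cfg.methods:
                hyper = dict_with_seed(method, _subseed(seed, "fit", sp_id, dtype, method))
                spec = sdm.ModelSpec(method, hyper)
                for split in splits:
                    model = sdm.fit(spec, split, current, sp_id, dtype)
                    test_scores = np.asarray(
                        model.algorithm.predict(
                            table[split.test_cells][:, [current.variables.index(v) for v in model.kept_variables]]
                        )
                    )
                    evaluation = ev.roc_threshold(test_scores, split.test_labels)
                    eval_rows.append(
                        {
                            "species_id": sp_id,
                            "data_type": dtype,
                            "method": method,
                            "family": METHOD_FAMILIES[method],
                            "replicate": split.replicate_id,
                            "threshold": evaluation.threshold,
                            "sensitivity": evaluation.sensitivity,
                            "specificity": evaluation.specificity,
                            "tss": evaluation.tss,
                        }
                    )
                    cur_bin = ev.binarize(sdm.predict(model, current), evaluation.threshold)
                    fut_bins = {
                        key: ev.binarize(sdm.predict(model, stack), evaluation.threshold)
                        for key, stack in futures.items()
                    }
                    per_species_members.setdefault((sp_id, dtype), []).append(
                        (METHOD_FAMILIES[method], evaluation, cur_bin, fut_bins)
                    )

    # --- ensembles --------------------------------------------------------
    for sp_id in kept:
        if sp_id in dropped_species:
            continue
        try:
            for dtype in ("range_map", "points"):
                members = per_species_members[(sp_id, dtype)]
                for family in families:
                    fam_members = [m for m in members if m[0] == family]
                    evals = [m[1] for m in fam_members]
                    cur = ev.ensemble([m[2] for m in fam_members], evals, cfg.min_tss, family)
                    consensus_current[(sp_id, dtype, family)] = cur
                    for key in futures:
                        fut = ev.ensemble(
                            [m[3][key] for m in fam_members], evals, cfg.min_tss, family
                        )
                        consensus_future[(sp_id, dtype, family) + key] = fut
        except ValueError as exc:
            warnings.warn(f"dropping {sp_id}: {exc}", stacklevel=2)
            dropped_species.add(sp_id)
            for k in [k for k in consensus_current if k[0] == sp_id]:
                del consensus_current[k]
            for k in [k for k in consensus_future if k[0] == sp_id]:
                del consensus_future[k]
    final_species = [s for s in kept if s not in dropped_species]
    if not final_species:
        raise RuntimeError("no species survived the TSS ensemble filter")

    # --- richness surfaces ------------------------------------------------
    richness_current = {}
    richness_future = {}
    for dtype in ("range_map", "points"):
        for family in families:
            layers = [consensus_current[(s, dtype, family)] for s in final_species]
            richness_current[(dtype, family)] = ev.richness_map(layers, cfg.richness_mode)
            for key in futures:
                layers_f = [consensus_future[(s, dtype, family) + key] for s in final_species]
                richness_future[(dtype, family) + key] = ev.richness_map(
                    layers_f, cfg.richness_mode
                )

    # --- variance partition ----------------------------------------------
    design = unc.DesignTable(
        factors={
            "data_type": ["range_map", "points"],
            "family": families,
            "rcp": rcps,
            "forecast": forecast_ids,
        },
        rows=pd.DataFrame(
            [
                (d, f, r, g)
                for d in ("range_map", "points")
                for f in families
                for r in rcps
                for g in forecast_ids
            ],
            columns=["data_type", "family", "rcp", "forecast"],
        ),
    )
    responses = unc.richness_change_stack(
        {k: v for k, v in richness_current.items()}, richness_future, design
    )
    components = unc.anova_partition(responses, design, cfg.nesting)

    # --- species-level shifts ---------------------------------------------
    shift_records = []
    for sp_id in final_species:
        for _, row in design.rows.iterrows():
            cur = consensus_current[(sp_id, row["data_type"], row["family"])]
            fut = consensus_future[
                (sp_id, row["data_type"], row["family"], row["rcp"], row["forecast"])
            ]
            if cur.area <= 0:
                warnings.warn(f"{sp_id}: zero current consensus area; shift skipped", stacklevel=2)
                continue
            shift_records.append(
                unc.range_shift(cur.area, fut.area, sp_id, dict(row))
            )
    observed_range = {
        s: int(pa["range_map"].column(s).sum()) for s in final_species
    }
    regression = None
    if len(final_species) >= 3:
        regression = unc.shift_sd_vs_range(shift_records, observed_range)

    evaluations = pd.DataFrame(eval_rows)
    return ExperimentResult(
        config=cfg,
        species_ids=final_species,
        variable_selection=selection,
        evaluations=evaluations,
        consensus_current=consensus_current,
        consensus_future=consensus_future,
        richness_current=richness_current,
        richness_future=richness_future,
        design=design,
        responses=responses,
        components=components,
        shift_records=shift_records,
        total_loss_count=unc.count_total_loss(shift_records),
        shift_regression=regression,
        observed_range=observed_range,
    )


def dict_with_seed(method: str, seed: int) -> dict:
    """Method hyperparameters carrying a derived random_state where needed."""
    if method in ("rndfor", "nnet", "maxent"):
        return {"random_state": seed}
    return {}
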