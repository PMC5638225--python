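"""Model evaluation, TSS-weighted consensus ensembles and richness maps.

Continuous suitability scores are thresholded at the ROC-optimal cutpoint
(the one maximizing sensitivity + specificity on held-out data) and scored
with the true skill statistic, TSS = sensitivity + specificity - 1.
Within-family ensembles weight each member's binary projection by its TSS,
after excluding members below a skill floor (default TSS < 0.5); the
consensus value in each cell is the weighted frequency with which the
species is predicted present.  Stacking per-species consensus layers gives
the richness surfaces the uncertainty analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sdm import SuitabilitySurface

__all__ = [
    "Evaluation",
    "BinarySurface",
    "ConsensusSurface",
    "RichnessSurface",
    "tss",
    "roc_threshold",
    "binarize",
    "ensemble",
    "richness_map",
    "compare_model_fit",
]


@dataclass
class Evaluation:
    """ROC-selected threshold and the accuracy statistics at it."""

    threshold: float
    sensitivity: float
    specificity: float

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class BinarySurface:
    """A thresholded (presence/absence) projection of one model."""

    values: np.ndarray  # flat {0,1} per cell
    grid: object
    species_id: str
    data_type: str
    method_id: str
    replicate_id: int
    scenario: object

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(np.int8)


@dataclass
class ConsensusSurface:
    """TSS-weighted presence frequency for one (species, data type, family)."""

    frequency: np.ndarray  # flat, in [0, 1]
    grid: object
    species_id: str
    data_type: str
    family: str
    scenario: object
    members: list[tuple[str, float]] = field(default_factory=list)  # (label, tss)

    @property
    def area(self) -> float:
        """Consensus-area sum: expected number of suitable cells."""
        return float(self.frequency.sum())


@dataclass
class RichnessSurface:
    """Per-cell expected species count from stacked consensus layers."""

    values: np.ndarray
    grid: object
    species_ids: list[str]
    scenario: object


def tss(sensitivity: float, specificity: float) -> float:
    """True skill statistic, sensitivity + specificity - 1, in [-1, 1]."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def roc_threshold(scores: np.ndarray, labels: np.ndarray) -> Evaluation:
    """Threshold maximizing sensitivity + specificity over all cutpoints.

    Candidate cutpoints are the distinct observed scores plus +inf
    (predict-nothing); prediction is ``score >= threshold``.  Ties are
    broken toward the smallest maximizing threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("TSS undefined: labels contain a single class")
    cuts = np.append(np.unique(scores), np.inf)
    pred = scores[:, None] >= cuts[None, :]
    tp = (pred & (labels == 1)[:, None]).sum(axis=0)
    tn = (~pred & (labels == 0)[:, None]).sum(axis=0)
    sens = tp / n_pos
    spec = tn / n_neg
    j = sens + spec
    best = int(np.argmax(j))  # argmax takes the first (smallest) maximizer
    return Evaluation(float(cuts[best]), float(sens[best]), float(spec[best]))


def binarize(surface: SuitabilitySurface, threshold: float) -> BinarySurface:
    """Convert continuous suitability to presence/absence at ``threshold``
    (presence iff score >= threshold)."""
    return BinarySurface(
        values=(surface.scores >= threshold).astype(np.int8),
        grid=surface.grid,
        species_id=surface.species_id,
        data_type=surface.data_type,
        method_id=surface.method_id,
        replicate_id=surface.replicate_id,
        scenario=surface.scenario,
    )


def ensemble(
    binaries: list[BinarySurface],
    evals: list[Evaluation],
    min_tss: float = 0.5,
    family: str | None = None,
) -> ConsensusSurface:
    """TSS-weighted consensus of binary projections.

    Members with TSS below ``min_tss`` are removed; the per-cell frequency
    is the weighted mean of member binary maps with raw TSS weights
    (normalized to sum to 1).  Raises if no member survives the filter.
    Members must share species, data type and scenario — the caller groups
    them by family.
    """
    if len(binaries) != len(evals):
        raise ValueError("binaries and evals must align")
    if not binaries:
        raise ValueError("no member surfaces")
    key = (binaries[0].species_id, binaries[0].data_type, str(binaries[0].scenario))
    for b in binaries:
        if (b.species_id, b.data_type, str(b.scenario)) != key:
            raise ValueError("ensemble members must share species, data type and scenario")
    surviving = [(b, e) for b, e in zip(binaries, evals) if e.tss >= min_tss]
    if not surviving:
        raise ValueError("no models passed TSS filter")
    weights = np.array([e.tss for _, e in surviving], dtype=float)
    stackv = np.stack([b.values for b, _ in surviving]).astype(float)
    frequency = (weights[:, None] * stackv).sum(axis=0) / weights.sum()
    frequency = np.clip(frequency, 0.0, 1.0)  # guard roundoff at the extremes
    return ConsensusSurface(
        frequency=frequency,
        grid=binaries[0].grid,
        species_id=binaries[0].species_id,
        data_type=binaries[0].data_type,
        family=family or "",
        scenario=binaries[0].scenario,
        members=[(f"{b.method_id}/r{b.replicate_id}", e.tss) for b, e in surviving],
    )


def richness_map(
    consensus: list[ConsensusSurface], mode: str = "expected", grid=None
) -> RichnessSurface:
    """Stack one consensus layer per species into a richness surface.

    ``"expected"`` sums consensus frequencies (expected species count);
    ``"binary@0.5"`` counts species whose consensus frequency is >= 0.5.
    An empty species list yields an all-zero map when ``grid`` is given.
    """
    if not consensus:
        if grid is None:
            raise ValueError("no consensus surfaces (pass grid= for an empty stack)")
        from .grid import CURRENT

        return RichnessSurface(np.zeros(grid.n_cells), grid, [], CURRENT)
    ids = [c.species_id for c in consensus]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species in richness stack")
    scen = str(consensus[0].scenario)
    for c in consensus:
        if str(c.scenario) != scen or c.grid != consensus[0].grid:
            raise ValueError("consensus layers must share scenario and grid")
    freq = np.stack([c.frequency for c in consensus])
    if mode == "expected":
        values = freq.sum(axis=0)
    elif mode == "binary@0.5":
        values = (freq >= 0.5).sum(axis=0).astype(float)
    else:
        raise ValueError("mode must be 'expected' or 'binary@0.5'")
    return RichnessSurface(values, consensus[0].grid, ids, consensus[0].scenario)


def compare_model_fit(evals: pd.DataFrame) -> dict:
    """Compare TSS across data types and method groups.

    ``evals`` needs columns ``tss``, ``data_type`` and ``group`` (family or
    method id).  Returns group means/sds plus a coefficient table from a
    binomial-family GLM (logit link) of TSS — rescaled from [-1, 1] to
    (0, 1) — on data_type x group, the link/family choice suited to a
    bounded response.
    """
    required = {"tss", "data_type", "group"}
    if not required.issubset(evals.columns):
        raise ValueError(f"evals must have columns {sorted(required)}")
    if evals.groupby(["data_type", "group"]).ngroups < 2:
        raise ValueError("need at least 2 (data_type, group) cells to compare")
    sizes = evals.groupby(["data_type", "group"])["tss"].size()
    if (sizes < 2).any():
        raise ValueError("degenerate single-observation groups")
    summary = (
        evals.groupby(["data_type", "group"])["tss"]
        .agg(["mean", "std", "size"])
        .reset_index()
    )
    eps = 1e-6
    y = np.clip((evals["tss"].to_numpy() + 1.0) / 2.0, eps, 1 - eps)
    X = pd.get_dummies(
        evals[["data_type", "group"]], drop_first=True, dtype=float
    )
    inter_cols = {}
    for dcol in [c for c in X.columns if c.startswith("data_type_")]:
        for gcol in [c for c in X.columns if c.startswith("group_")]:
            inter_cols[f"{dcol}:{gcol}"] = X[dcol] * X[gcol]
    X = pd.concat([X, pd.DataFrame(inter_cols, index=X.index)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    coefs = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "p": model.pvalues}
    )
    return {"group_summary": summary, "coefficients": coefs, "model": model}
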