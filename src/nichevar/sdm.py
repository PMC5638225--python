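"""Model fitting protocol: pseudo-absences, repeated splits, fit, predict.

The comparative design requires that all nine methods see *identical*
inputs: one shared pseudo-absence sample per (species, data type), the same
10 random 75/25 train/test partitions, and the same selected climate
variables.  ``fit`` returns a ``FittedModel`` whose ``predict`` is a pure
function of the fitted state and any climate stack with the right
variables — projecting a model onto a future stack is just predicting on
that stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import ClimateStack
from .methods import METHOD_FAMILIES, make_algorithm
from .occurrence import PAMatrix

__all__ = [
    "ModelSpec",
    "TrainTestSplit",
    "FittedModel",
    "SuitabilitySurface",
    "sample_pseudo_absences",
    "make_splits",
    "fit",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    """One modeling method with its family and hyperparameters."""

    method_id: str
    hyperparameters: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.method_id not in METHOD_FAMILIES:
            raise ValueError(f"unknown method {self.method_id!r}")

    @property
    def family(self) -> str:
        return METHOD_FAMILIES[self.method_id]


@dataclass
class TrainTestSplit:
    """One 75/25 (by default) random partition of presences and absences."""

    replicate_id: int
    train_cells: np.ndarray
    train_labels: np.ndarray
    test_cells: np.ndarray
    test_labels: np.ndarray
    train_fraction: float = 0.75


@dataclass
class FittedModel:
    """Fitted state of one (species, data type, method, replicate)."""

    spec: ModelSpec
    species_id: str
    data_type: str
    replicate_id: int
    algorithm: object
    variable_names: list[str]
    kept_variables: list[str]

    @property
    def method_id(self) -> str:
        return self.spec.method_id

    @property
    def family(self) -> str:
        return self.spec.family


@dataclass
class SuitabilitySurface:
    """Continuous per-cell suitability from one fitted model on one stack."""

    scores: np.ndarray  # flat, one per cell
    grid: object
    species_id: str
    data_type: str
    method_id: str
    replicate_id: int
    scenario: object

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("suitability scores must be finite")


def sample_pseudo_absences(
    pa: PAMatrix, species_id: str, n: int | str = "match", seed: int = 0
) -> np.ndarray:
    """Uniform random pseudo-absence cells for one species.

    Sampled without replacement from the cells recorded as absences;
    ``n="match"`` draws as many pseudo-absences as there are presences.
    The caller reuses the returned set across all nine methods so every
    method sees the same background.
    """
    col = pa.column(species_id)
    absences = np.nonzero(col == 0)[0]
    n_pres = int(col.sum())
    n_draw = n_pres if n == "match" else int(n)
    if n_draw > absences.size:
        raise ValueError(
            f"requested {n_draw} pseudo-absences but only {absences.size} absence cells exist"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(absences, size=n_draw, replace=False))


def make_splits(
    presences: np.ndarray,
    pseudo_absences: np.ndarray,
    train_fraction: float = 0.75,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[TrainTestSplit]:
    """Repeated random train/test partitions, stratified by label.

    Each replicate independently shuffles presences and pseudo-absences and
    cuts each at ``train_fraction`` (test size floored), so the 75/25 split
    holds within both classes.
    """
    presences = np.asarray(presences)
    pseudo_absences = np.asarray(pseudo_absences)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if presences.size < 4:
        raise ValueError("need at least 4 presences to split")
    rng = np.random.default_rng(seed)
    splits = []
    for r in range(1, n_repeats + 1):
        parts = {}
        for name, cells in (("pres", presences), ("abs", pseudo_absences)):
            perm = rng.permutation(cells)
            n_test = int(np.floor(len(cells) * (1 - train_fraction)))
            n_test = min(max(n_test, 1), len(cells) - 1)
            parts[name] = (perm[n_test:], perm[:n_test])
        train_cells = np.concatenate([parts["pres"][0], parts["abs"][0]])
        train_labels = np.concatenate(
            [np.ones(len(parts["pres"][0]), dtype=int), np.zeros(len(parts["abs"][0]), dtype=int)]
        )
        test_cells = np.concatenate([parts["pres"][1], parts["abs"][1]])
        test_labels = np.concatenate(
            [np.ones(len(parts["pres"][1]), dtype=int), np.zeros(len(parts["abs"][1]), dtype=int)]
        )
        splits.append(
            TrainTestSplit(r, train_cells, train_labels, test_cells, test_labels, train_fraction)
        )
    return splits


def fit(
    spec: ModelSpec,
    split: TrainTestSplit,
    climate: ClimateStack,
    species_id: str = "",
    data_type: str = "points",
) -> FittedModel:
    """Fit one method on one train partition of one species' data.

    Variables that are constant in the training data are dropped (with a
    warning) before fitting; the fitted model remembers which variables
    survived and predicts with those.
    """
    if int(split.train_labels.sum()) < 2:
        raise ValueError("need at least 2 training presences")
    table = climate.table()
    X = table[split.train_cells]
    y = split.train_labels
    sds = X.std(axis=0)
    kept = [v for v, sd in zip(climate.variables, sds) if sd > 0]
    if not kept:
        raise ValueError("all variables constant in training data")
    if len(kept) < len(climate.variables):
        dropped = sorted(set(climate.variables) - set(kept))
        warnings.warn(
            f"{spec.method_id}: dropping constant training variables {dropped}", stacklevel=2
        )
        idx = [climate.variables.index(v) for v in kept]
        X = X[:, idx]
    algo = make_algorithm(spec.method_id, spec.hyperparameters)
    algo.fit(X, y)
    return FittedModel(
        spec=spec,
        species_id=species_id,
        data_type=data_type,
        replicate_id=split.replicate_id,
        algorithm=algo,
        variable_names=list(climate.variables),
        kept_variables=kept,
    )


def predict(model: FittedModel, climate: ClimateStack) -> SuitabilitySurface:
    """Score every cell of a climate stack with a fitted model.

    The stack may describe any scenario (current or future); its scenario
    tag is copied onto the output surface.
    """
    missing = [v for v in model.kept_variables if v not in climate.variables]
    if missing:
        raise ValueError(f"stack lacks model variables {missing}")
    X = climate.table(model.kept_variables)
    scores = np.asarray(model.algorithm.predict(X), dtype=float)
    return SuitabilitySurface(
        scores=scores,
        grid=climate.grid,
        species_id=model.species_id,
        data_type=model.data_type,
        method_id=model.method_id,
        replicate_id=model.replicate_id,
        scenario=climate.scenario,
    )
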