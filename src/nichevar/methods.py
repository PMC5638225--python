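"""The nine distribution-modeling algorithms, in three families.

Envelope methods (bioclim, euclid, enfa) characterize presences alone
against the climatic background; statistical methods (glm, gam, mars) are
regression models of presence/pseudo-absence; machine-learning methods
(rndfor, nnet, maxent) are flexible classifiers.  Every algorithm exposes
the same tiny interface:

    algo.fit(X, y)        # X: samples x variables; y: 1 presence, 0 absence
    algo.predict(X)       # continuous suitability per row

Suitability scores are comparable only within one fitted model — the ROC
threshold search downstream consumes rankings, not calibrated
probabilities — but all methods here emit scores in [0, 1].

Presence-only envelope methods ignore the absences in ``fit`` except where
the background is needed (enfa's marginality is presence-vs-background);
pseudo-absences still flow in so all nine methods see identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import SplineTransformer, StandardScaler

__all__ = [
    "METHOD_FAMILIES",
    "FAMILIES",
    "make_algorithm",
]

#: The study's method -> family grouping.
METHOD_FAMILIES: dict[str, str] = {
    "bioclim": "envelope",
    "euclid": "envelope",
    "enfa": "envelope",
    "glm": "statistical",
    "gam": "statistical",
    "mars": "statistical",
    "rndfor": "machine_learning",
    "nnet": "machine_learning",
    "maxent": "machine_learning",
}

FAMILIES = ["envelope", "statistical", "machine_learning"]


# ---------------------------------------------------------------------------
# envelope methods


class Bioclim:
    """Percentile envelope: suitability peaks at the presence medians.

    score(cell) = min over variables of 1 - 2|p_v - 0.5|, where p_v is the
    cell value's percentile among training-presence values; 0 outside the
    training min-max envelope on any variable.
    """

    def __init__(self, **_: object) -> None:
        self._pres: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Bioclim":
        self._pres = np.sort(X[y == 1], axis=0)
        return self

    @property
    def envelope_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variable (min, max) of training presences."""
        assert self._pres is not None
        return self._pres[0], self._pres[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        pres = self._pres
        assert pres is not None
        n = pres.shape[0]
        scores = np.empty_like(X, dtype=float)
        for v in range(X.shape[1]):
            col = pres[:, v]
            less = np.searchsorted(col, X[:, v], side="left")
            leq = np.searchsorted(col, X[:, v], side="right")
            p = (less + 0.5 * (leq - less)) / n
            s = 1.0 - 2.0 * np.abs(p - 0.5)
            s[(X[:, v] < col[0]) | (X[:, v] > col[-1])] = 0.0
            scores[:, v] = s
        return scores.min(axis=1)


class EuclideanDistance:
    """Suitability 1/(1+d) by distance to the presence centroid.

    Variables are standardized by presence means and sds, so the centroid
    sits at the origin and d is a z-space Euclidean distance.
    """

    def __init__(self, **_: object) -> None:
        self._mean: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EuclideanDistance":
        pres = X[y == 1]
        self._mean = pres.mean(axis=0)
        sd = pres.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = (X - self._mean) / self._sd
        return 1.0 / (1.0 + np.linalg.norm(z, axis=1))


class Enfa:
    """Ecological niche factor analysis.

    The marginality axis points from the background mean to the presence
    mean in background-standardized climate space; specialization axes are
    eigenvectors of the presence covariance restricted to the orthogonal
    complement, retained until they cover ``spec_variance`` of the
    specialization variance.  Suitability is the rank percentile, among
    training presences, of the negative squared distance to the presence
    centroid in the retained factor space (axes scaled by presence sds).
    """

    def __init__(self, spec_variance: float = 0.8, **_: object) -> None:
        self.spec_variance = spec_variance

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Enfa":
        bg_mean = X.mean(axis=0)
        bg_sd = X.std(axis=0)
        self._bg_mean = bg_mean
        self._bg_sd = np.where(bg_sd > 0, bg_sd, 1.0)
        Z = (X - self._bg_mean) / self._bg_sd
        pres = Z[y == 1]
        m = pres.mean(axis=0)
        norm = np.linalg.norm(m)
        u = m / norm if norm > 1e-12 else np.eye(X.shape[1])[:, 0]
        # presence scatter orthogonal to the marginality axis
        perp = pres - np.outer(pres @ u, u)
        cov = np.cov(perp, rowvar=False) if perp.shape[0] > 1 else np.zeros((X.shape[1],) * 2)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        total = evals.sum()
        if total > 0:
            n_keep = int(np.searchsorted(np.cumsum(evals) / total, self.spec_variance) + 1)
            n_keep = min(n_keep, max(X.shape[1] - 1, 1))
        else:
            n_keep = 0
        basis = np.column_stack([u] + [evecs[:, i] for i in range(n_keep)])
        self._basis = basis
        coords = pres @ basis
        self._center = coords.mean(axis=0)
        scale = coords.std(axis=0)
        self._scale = np.where(scale > 1e-12, scale, 1.0)
        d2 = (((coords - self._center) / self._scale) ** 2).sum(axis=1)
        self._pres_d2 = np.sort(d2)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self._bg_mean) / self._bg_sd
        coords = Z @ self._basis
        d2 = (((coords - self._center) / self._scale) ** 2).sum(axis=1)
        n = self._pres_d2.size
        # rank percentile of -d2 among presences: closer than most -> near 1
        less = np.searchsorted(self._pres_d2, d2, side="left")
        leq = np.searchsorted(self._pres_d2, d2, side="right")
        return 1.0 - (less + 0.5 * (leq - less)) / n


# ---------------------------------------------------------------------------
# statistical methods


class _SklearnScorer:
    """Shared wrapper: feature expansion + an sklearn classifier."""

    def __init__(self) -> None:
        self._clf = None
        self._expand: Callable[[np.ndarray], np.ndarray] = lambda X: X

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self._clf.predict_proba(self._expand(X))
        return proba[:, list(self._clf.classes_).index(1)]


def _quadratic(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, X**2])


class Glm(_SklearnScorer):
    """Logistic regression with linear + quadratic terms per variable."""

    def __init__(self, C: float = 100.0, **_: object) -> None:
        super().__init__()
        self.C = C

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Glm":
        self._expand = _quadratic
        self._clf = LogisticRegression(C=self.C, max_iter=2000)
        self._clf.fit(self._expand(X), y)
        return self


class Gam(_SklearnScorer):
    """Additive logistic model with low-rank per-variable spline smooths.

    Each variable enters through a cubic B-spline basis; an L2 (ridge)
    penalty on the basis coefficients plays the role of the smoothness
    penalty, giving a penalized-spline additive fit.
    """

    def __init__(self, n_knots: int = 6, C: float = 10.0, **_: object) -> None:
        super().__init__()
        self.n_knots = n_knots
        self.C = C

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Gam":
        n_knots = int(np.clip(X.shape[0] // 4, 3, self.n_knots))
        spl = SplineTransformer(
            n_knots=n_knots, degree=3, knots="quantile", extrapolation="constant"
        )
        spl.fit(X)
        self._expand = spl.transform
        self._clf = LogisticRegression(C=self.C, max_iter=2000)
        self._clf.fit(self._expand(X), y)
        return self


class Mars:
    """Multivariate adaptive regression splines (additive, logistic scores).

    Forward selection adds hinge basis functions max(0, x - t) / max(0, t - x)
    at quantile knots while they reduce training SSE, then backward deletion
    prunes by generalized cross-validation (GCV) with the customary penalty
    of 3 effective parameters per knot.  The pruned linear predictor is
    passed through a 1-D logistic calibration so scores land in [0, 1].
    """

    def __init__(
        self,
        max_terms: int = 15,
        n_knots: int = 7,
        penalty: float = 3.0,
        **_: object,
    ) -> None:
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.penalty = penalty

    def _basis_catalog(self, X: np.ndarray) -> list[tuple[int, float, int]]:
        """(variable, knot, direction) candidates; direction +1 is x-t."""
        out = []
        qs = np.linspace(0.1, 0.9, self.n_knots)
        for v in range(X.shape[1]):
            for t in np.unique(np.quantile(X[:, v], qs)):
                out.append((v, float(t), +1))
                out.append((v, float(t), -1))
        return out

    @staticmethod
    def _hinge(X: np.ndarray, v: int, t: float, d: int) -> np.ndarray:
        return np.maximum(0.0, d * (X[:, v] - t))

    def _design(self, X: np.ndarray, terms: list[tuple[int, float, int]]) -> np.ndarray:
        cols = [np.ones(X.shape[0])]
        cols += [self._hinge(X, *term) for term in terms]
        return np.column_stack(cols)

    def _gcv(self, sse: float, n: int, n_terms: int) -> float:
        c = 1 + n_terms + self.penalty * n_terms / 2.0  # effective parameters
        denom = (1.0 - min(c / n, 0.99)) ** 2
        return (sse / n) / denom

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Mars":
        y = y.astype(float)
        n = X.shape[0]
        catalog = self._basis_catalog(X)
        terms: list[tuple[int, float, int]] = []
        max_terms = min(self.max_terms, max(2, n // 4))
        B = np.ones((n, 1))
        coef, sse = _lstsq(B, y)
        while len(terms) < max_terms and catalog:
            best = None
            for cand in catalog:
                col = self._hinge(X, *cand)
                Bc = np.column_stack([B, col])
                _, cand_sse = _lstsq(Bc, y)
                if best is None or cand_sse < best[1] - 1e-12:
                    best = (cand, cand_sse)
            cand, cand_sse = best
            if sse - cand_sse <= 1e-10 * max(sse, 1.0):
                break
            terms.append(cand)
            catalog.remove(cand)
            B = np.column_stack([B, self._hinge(X, *cand)])
            sse = cand_sse
        # backward pruning by GCV
        best_terms = list(terms)
        best_gcv = self._gcv(sse, n, len(terms))
        current = list(terms)
        while current:
            candidates = []
            for i in range(len(current)):
                trial = current[:i] + current[i + 1 :]
                _, trial_sse = _lstsq(self._design(X, trial), y)
                candidates.append((self._gcv(trial_sse, n, len(trial)), trial))
            gcv, trial = min(candidates, key=lambda c: c[0])
            current = trial
            if gcv <= best_gcv:
                best_gcv, best_terms = gcv, list(trial)
        self._terms = best_terms
        B = self._design(X, best_terms)
        self._coef, _ = _lstsq(B, y)
        eta = B @ self._coef
        # logistic calibration of the linear predictor
        if eta.std() > 1e-12:
            self._cal = LogisticRegression(C=1e4, max_iter=2000).fit(eta[:, None], y.astype(int))
        else:
            self._cal = None
            self._const = float(y.mean())
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self._design(X, self._terms) @ self._coef
        if self._cal is None:
            return np.full(X.shape[0], self._const)
        proba = self._cal.predict_proba(eta[:, None])
        return proba[:, list(self._cal.classes_).index(1)]


def _lstsq(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


# ---------------------------------------------------------------------------
# machine-learning methods


class RandomForest(_SklearnScorer):
    """Bagged classification trees; score = fraction of trees voting presence."""

    def __init__(self, n_estimators: int = 100, random_state: int = 0, **_: object) -> None:
        super().__init__()
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        self._clf = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1
        )
        self._clf.fit(X, y)
        return self


class NeuralNet(_SklearnScorer):
    """Single-hidden-layer feed-forward classifier on standardized inputs."""

    def __init__(self, hidden_units: int = 8, random_state: int = 0, **_: object) -> None:
        super().__init__()
        self.hidden_units = hidden_units
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NeuralNet":
        self._scaler = StandardScaler().fit(X)
        self._clf = MLPClassifier(
            hidden_layer_sizes=(self.hidden_units,),
            solver="lbfgs",
            alpha=1e-3,
            max_iter=1000,
            random_state=self.random_state,
        )
        self._expand = self._scaler.transform
        self._clf.fit(self._expand(X), y)
        return self


class Maxent(_SklearnScorer):
    """Presence-background exponential model via its logistic equivalence.

    An L1-regularized logistic regression on linear + quadratic + hinge
    features of the (standardized) climate variables — the feature classes
    of the original maximum-entropy formulation, with the lasso penalty
    playing the role of its feature regularization.
    """

    def __init__(self, C: float = 1.0, n_knots: int = 5, random_state: int = 0, **_: object) -> None:
        super().__init__()
        self.C = C
        self.n_knots = n_knots
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Maxent":
        self._scaler = StandardScaler().fit(X)
        knots = [
            np.unique(np.quantile(self._scaler.transform(X)[:, v], np.linspace(0.15, 0.85, self.n_knots)))
            for v in range(X.shape[1])
        ]
        self._knots = knots

        def expand(A: np.ndarray) -> np.ndarray:
            Z = self._scaler.transform(A)
            feats = [Z, Z**2]
            for v, ks in enumerate(self._knots):
                col = Z[:, v][:, None]
                feats.append(np.maximum(0.0, col - ks[None, :]))
                feats.append(np.maximum(0.0, ks[None, :] - col))
            return np.hstack(feats)

        self._expand = expand
        # liblinear shuffles internally: seed it for reproducible fits
        self._clf = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=self.C, max_iter=2000,
            random_state=self.random_state,
        )
        self._clf.fit(self._expand(X), y)
        return self


_REGISTRY: dict[str, type] = {
    "bioclim": Bioclim,
    "euclid": EuclideanDistance,
    "enfa": Enfa,
    "glm": Glm,
    "gam": Gam,
    "mars": Mars,
    "rndfor": RandomForest,
    "nnet": NeuralNet,
    "maxent": Maxent,
}


def make_algorithm(method_id: str, hyperparameters: dict | None = None):
    """Instantiate one of the nine algorithms by its method id."""
    try:
        cls = _REGISTRY[method_id]
    except KeyError:
        raise ValueError(
            f"unknown method {method_id!r}; choose from {sorted(_REGISTRY)}"
        ) from None
    return cls(**(hyperparameters or {}))
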