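"""Genetic-function-approximation search over descriptor subsets, fitted by PLS.

Candidate models are small descriptor subsets (here at most nine linear
terms).  Each candidate is fitted by partial least squares regression and
scored by Friedman's lack-of-fit (LOF), which penalizes the least-squares
error by model size:

    LOF = (LSE / M) / (1 - (c + d p) / M)^2

with M training samples, p selected descriptors, c = p + 1 regression
parameters for a linear model (intercept counted), and smoothing factor d
controlling how strongly extra terms are punished.  A genetic algorithm
recombines the descriptor sets of better-scored models: rank tournaments pick
two parents, the child draws its terms from the parents' union, and every
offspring is mutated (descriptor swap / insert / delete) with a configurable
probability - 1.0 in the original protocol, i.e. always.

``GfaPlsRegressor`` exposes the search as a scikit-learn regressor with
``support_`` / ``coef_`` / ``intercept_`` fitted attributes; ``evolve``,
``fit_pls``, ``lof``, and ``size_sweep`` are the operation-level surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "InfeasibleModelError",
    "GfaConfig",
    "ModelCandidate",
    "lof",
    "fit_pls",
    "evolve",
    "size_sweep",
    "GfaPlsRegressor",
]


class InfeasibleModelError(ValueError):
    """Model size incompatible with the sample count (LOF penalty denominator <= 0)."""


def lof(lse: float, n_terms: int, n_samples: int, smoothing_d: float = 1.0) -> float:
    """Friedman lack-of-fit for a linear model with ``n_terms`` descriptors.

    Counts c = n_terms + 1 fitted parameters (intercept included) and
    p = n_terms basis functions; requires n_samples > c + d p.
    """
    c = n_terms + 1
    p = n_terms
    m = n_samples
    penalty = 1.0 - (c + smoothing_d * p) / m
    if penalty <= 0:
        raise InfeasibleModelError(
            f"{n_terms} terms with d={smoothing_d} infeasible for {m} samples"
        )
    return (lse / m) / penalty**2


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
) -> tuple[float, np.ndarray, float]:
    """PLS regression reporting (intercept, coefficients, training LSE).

    Coefficients are in original descriptor units so the model prints as a
    plain linear equation.  ``n_components`` defaults to the maximum feasible
    (min of the column count, rank, and n-1), in which case PLS coincides with
    ordinary least squares on full-rank problems.  Degenerate inputs (constant
    y, all-zero columns after centering) yield zero loadings rather than
    failure.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on sample count")

    xc = X - X.mean(axis=0)
    if np.allclose(y, y[0]) or not np.any(xc):
        return float(y.mean()), np.zeros(m), float(np.sum((y - y.mean()) ** 2))

    rank = np.linalg.matrix_rank(xc)
    k_max = max(1, min(m, rank, n - 1))
    k = k_max if n_components is None else min(n_components, k_max)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(X, y)
        coef = np.asarray(pls.coef_).reshape(-1)
        coef = np.nan_to_num(coef, nan=0.0)
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    pred = X @ coef + intercept
    lse = float(np.sum((pred - y) ** 2))
    return intercept, coef, lse


@dataclass(frozen=True)
class GfaConfig:
    population_size: int = 50
    n_crossovers: int = 6000  # published protocol explored 6,000-20,000
    mutation_prob: float = 1.0
    smoothing_d: float = 1.0  # published range 0.5-3.0
    max_terms: int = 9
    min_terms: int = 1
    pls_components: int | str = "full"  # "full", "auto", or an int
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.max_terms < 1 or self.min_terms < 1 or self.min_terms > self.max_terms:
            raise ValueError("term bounds must satisfy 1 <= min_terms <= max_terms")
        if self.n_crossovers < self.population_size:
            raise ValueError("n_crossovers must be at least population_size")


@dataclass(frozen=True)
class ModelCandidate:
    """A descriptor subset with its fitted linear equation and fitness."""

    descriptor_idx: tuple[int, ...]
    descriptor_keys: tuple
    intercept: float
    coefficients: tuple[float, ...]
    lse: float
    lof: float
    q2: float | None = None
    q2_adj: float | None = None

    @property
    def n_terms(self) -> int:
        return len(self.descriptor_idx)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X[:, list(self.descriptor_idx)] @ np.asarray(self.coefficients) + self.intercept

    def equation(self) -> str:
        """Printable linear equation in the published table style."""
        parts = [f"pIC50 = {self.intercept:.2f}"]
        for key, c in zip(self.descriptor_keys, self.coefficients):
            if isinstance(key, tuple) and len(key) == 4:
                label = f"({key[0]},{key[1]},{key[2]})({key[3]})"
            else:
                label = str(key)
            parts.append(f"{'-' if c < 0 else '+'} {abs(c):.2f} {label}")
        return " ".join(parts)


def _as_matrix(pool) -> tuple[np.ndarray, list]:
    from .align_grid import OccupancyMatrix

    if isinstance(pool, OccupancyMatrix):
        pool = pool.values
    if isinstance(pool, pd.DataFrame):
        return pool.to_numpy(dtype=float), list(pool.columns)
    arr = np.asarray(pool, dtype=float)
    return arr, list(range(arr.shape[1]))


def _align_y(pool, activities) -> np.ndarray:
    """Activity vector in the pool's row order (Series are index-aligned)."""
    from .align_grid import OccupancyMatrix

    if isinstance(activities, pd.Series):
        if isinstance(pool, OccupancyMatrix):
            return activities.loc[pool.values.index].to_numpy(dtype=float)
        if isinstance(pool, pd.DataFrame):
            return activities.loc[pool.index].to_numpy(dtype=float)
    return np.asarray(activities, dtype=float).ravel()


def auto_components(X: np.ndarray, y: np.ndarray, k_max: int = 5) -> int:
    """Component count maximizing LOO Q² over 1..min(k_max, p, n-1)."""
    from .validation import loo_q2

    X = np.asarray(X, dtype=float)
    upper = max(1, min(k_max, X.shape[1], X.shape[0] - 1))
    best_k, best_q2 = 1, -np.inf
    for k in range(1, upper + 1):
        def fitter(Xt, yt, _k=k):
            intercept, coef, _ = fit_pls(Xt, yt, n_components=_k)
            return intercept, coef

        q2, _ = loo_q2(X, y, fitter)
        if q2 > best_q2:
            best_k, best_q2 = k, q2
    return best_k


def _evaluate(
    subset: tuple[int, ...],
    X: np.ndarray,
    y: np.ndarray,
    keys: list,
    config: GfaConfig,
) -> ModelCandidate:
    cols = list(subset)
    if config.pls_components == "full":
        k = None
    elif config.pls_components == "auto":
        k = auto_components(X[:, cols], y)
    else:
        k = int(config.pls_components)
    intercept, coef, lse = fit_pls(X[:, cols], y, n_components=k)
    try:
        fitness = lof(lse, len(cols), X.shape[0], config.smoothing_d)
    except InfeasibleModelError:
        fitness = np.inf
    return ModelCandidate(
        descriptor_idx=tuple(subset),
        descriptor_keys=tuple(keys[i] for i in subset),
        intercept=intercept,
        coefficients=tuple(float(c) for c in coef),
        lse=lse,
        lof=fitness,
    )


def evolve(pool, activities, config: GfaConfig = GfaConfig()) -> list[ModelCandidate]:
    """GA search over descriptor subsets; returns candidates sorted by ascending LOF.

    The population is initialized with random subsets, then ``n_crossovers``
    steady-state crossover operations recombine tournament-selected parents
    (k = 2, rank-based) with elitism of the two best.  Bit-reproducible for a
    fixed ``config.seed``.
    """
    X, keys = _as_matrix(pool)
    y = _align_y(pool, activities)
    n, m = X.shape
    if m == 0:
        raise ValueError("descriptor pool is empty")
    if n < config.max_terms + 2:
        raise InfeasibleModelError(
            f"max_terms={config.max_terms} needs at least {config.max_terms + 2} samples"
        )
    max_terms = min(config.max_terms, m)
    min_terms = min(config.min_terms, max_terms)
    rng = np.random.default_rng(config.seed)

    cache: dict[tuple[int, ...], ModelCandidate] = {}

    def score(subset: tuple[int, ...]) -> ModelCandidate:
        if subset not in cache:
            cache[subset] = _evaluate(subset, X, y, keys, config)
        return cache[subset]

    def random_subset() -> tuple[int, ...]:
        k = int(rng.integers(min_terms, max_terms + 1))
        return tuple(sorted(rng.choice(m, size=k, replace=False)))

    population = [score(random_subset()) for _ in range(config.population_size)]
    population.sort(key=lambda c: c.lof)

    def tournament() -> ModelCandidate:
        i, j = rng.integers(len(population)), rng.integers(len(population))
        return population[min(i, j)]  # population is rank-sorted

    def mutate(subset: list[int]) -> list[int]:
        unused = [i for i in range(m) if i not in subset]
        op = rng.random()
        if op < 0.8 or (len(subset) >= max_terms and len(subset) <= min_terms):
            if unused:  # swap one member for an unused descriptor
                pos = int(rng.integers(len(subset)))
                subset[pos] = int(unused[rng.integers(len(unused))])
        elif op < 0.9:
            if len(subset) < max_terms and unused:
                subset.append(int(unused[rng.integers(len(unused))]))
            elif unused:
                pos = int(rng.integers(len(subset)))
                subset[pos] = int(unused[rng.integers(len(unused))])
        else:
            if len(subset) > min_terms:
                subset.pop(int(rng.integers(len(subset))))
            elif unused:
                pos = int(rng.integers(len(subset)))
                subset[pos] = int(unused[rng.integers(len(unused))])
        return subset

    for _ in range(config.n_crossovers):
        p1, p2 = tournament(), tournament()
        union = sorted(set(p1.descriptor_idx) | set(p2.descriptor_idx))
        k = int(rng.integers(min_terms, min(max_terms, len(union)) + 1))
        child = sorted(rng.choice(union, size=k, replace=False).tolist())
        if rng.random() < config.mutation_prob:
            child = sorted(mutate(list(child)))
        cand = score(tuple(int(i) for i in child))
        # steady-state: the child displaces the current worst if it beats it,
        # which leaves the best (elite) members untouched by construction
        if cand.lof < population[-1].lof and cand.descriptor_idx not in {
            c.descriptor_idx for c in population
        }:
            population[-1] = cand
            population.sort(key=lambda c: c.lof)

    ranked = sorted(
        {c.descriptor_idx: c for c in population}.values(), key=lambda c: c.lof
    )
    return ranked


def size_sweep(
    pool,
    activities,
    config: GfaConfig = GfaConfig(),
    sizes: Sequence[int] = (7, 8, 9),
    top_k: int = 10,
) -> dict[int, ModelCandidate]:
    """Best model per fixed term count, ranked by adjusted LOO Q².

    For each size the GA runs with ``min_terms = max_terms = size``; the
    ``top_k`` LOF-best candidates are cross-validated and the one with the
    highest adjusted Q² is returned.  This is the model-size table one plots
    to pick how many terms a defensible model should carry.
    """
    from .validation import adjusted, loo_q2

    X, _ = _as_matrix(pool)
    y = _align_y(pool, activities)
    out: dict[int, ModelCandidate] = {}
    for size in sizes:
        cfg = replace(config, min_terms=size, max_terms=size, seed=config.seed + size)
        ranked = evolve(pool, activities, cfg)
        best = None
        for cand in ranked[:top_k]:
            cols = list(cand.descriptor_idx)
            q2, _press = loo_q2(X[:, cols], y)
            q2a = adjusted(q2, len(y), len(cols))
            scored = replace(cand, q2=q2, q2_adj=q2a)
            if best is None or (scored.q2_adj, -scored.lof) > (best.q2_adj, -best.lof):
                best = scored
        out[size] = best
    return out


class GfaPlsRegressor(RegressorMixin, BaseEstimator):
    """Sparse linear QSAR model found by GA subset search with PLS fitting.

    ``fit(X, y)`` runs the evolutionary search and keeps the LOF-best
    candidate.  Fitted attributes follow scikit-learn conventions:
    ``support_`` (boolean column mask), ``coef_`` (dense, zeros off-support),
    ``intercept_``, plus ``candidates_`` (the ranked survivors), ``lse_`` and
    ``lof_``.  ``X`` may be a DataFrame, in which case column labels become
    descriptor keys in ``best_candidate_``.
    """

    def __init__(
        self,
        max_terms: int = 9,
        min_terms: int = 1,
        population_size: int = 50,
        n_crossovers: int = 6000,
        mutation_prob: float = 1.0,
        smoothing_d: float = 1.0,
        pls_components: int | str = "full",
        random_state: int = 0,
    ):
        self.max_terms = max_terms
        self.min_terms = min_terms
        self.population_size = population_size
        self.n_crossovers = n_crossovers
        self.mutation_prob = mutation_prob
        self.smoothing_d = smoothing_d
        self.pls_components = pls_components
        self.random_state = random_state

    def _config(self) -> GfaConfig:
        return GfaConfig(
            population_size=self.population_size,
            n_crossovers=self.n_crossovers,
            mutation_prob=self.mutation_prob,
            smoothing_d=self.smoothing_d,
            max_terms=self.max_terms,
            min_terms=self.min_terms,
            pls_components=self.pls_components,
            seed=self.random_state,
        )

    def fit(self, X, y):
        frame = pd.DataFrame(X)
        self.candidates_ = evolve(frame, np.asarray(y, dtype=float), self._config())
        best = self.candidates_[0]
        m = frame.shape[1]
        self.n_features_in_ = m
        self.best_candidate_ = best
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[list(best.descriptor_idx)] = True
        self.coef_ = np.zeros(m)
        self.coef_[list(best.descriptor_idx)] = best.coefficients
        self.intercept_ = best.intercept
        self.lse_ = best.lse
        self.lof_ = best.lof
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = pd.DataFrame(X).to_numpy(dtype=float)
        return X @ self.coef_ + self.intercept_
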