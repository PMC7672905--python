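"""LC-Opt: search for the k-variable combination minimizing the LC statistic.

The optimization is over diagonal 0/1 indicator matrices with trace k,
equivalently over k-subsets of the p nutrient columns:

    min_{|S| = k}  LC(S; G)

solved either by exhaustive enumeration of all C(p, k) subsets, or — when that
is infeasible — by a genetic algorithm over length-p bit vectors with a
penalty proportional to the deviation | |S| - k | from the cardinality
constraint, followed by a repair step that guarantees a feasible result.

``LCOpt`` is a scikit-learn-compatible feature selector: ``fit(X, y)`` finds
the best combination and ``transform(X)`` returns the selected columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import (
    compute_diff_matrix,
    compute_weight_matrix,
    validate_nutrients,
    validate_response,
)

__all__ = ["LCRankResult", "LCOpt", "enumerate_combinations", "lc_opt_exhaustive", "lc_opt_ga"]

EXHAUSTIVE_CAP = 100_000


@dataclass
class LCRankResult:
    """One ranked combination: selected column indices (0-based), LC value,
    1-based rank, and an optional permutation p-value."""

    combination: tuple[int, ...]
    lc_value: float
    rank: int
    p_value: float | None = None


def enumerate_combinations(p: int, k: int) -> list[tuple[int, ...]]:
    """All C(p, k) k-subsets of {0, ..., p-1} in lexicographic order."""
    if not 1 <= k <= p:
        raise ValueError(f"require 1 <= k <= p, got k={k}, p={p}")
    return list(itertools.combinations(range(p), k))


def _lc_all_combinations(X, G, combos):
    """LC value per combination with D(G) computed once and reused."""
    D = compute_diff_matrix(G)
    values = np.empty(len(combos))
    for i, combo in enumerate(combos):
        W = compute_weight_matrix(X, combo)
        values[i] = np.sum(W * D)
    return values


def _rank(combos, values) -> list[LCRankResult]:
    # ties broken lexicographically on the index tuple for determinism
    order = sorted(range(len(combos)), key=lambda i: (values[i], combos[i]))
    return [
        LCRankResult(combination=tuple(combos[i]), lc_value=float(values[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]


class LCOpt(BaseEstimator, TransformerMixin):
    """Select the k nutrient variables over which a response is locally smoothest.

    Parameters
    ----------
    k : int, default=2
        Number of variables to select (the trace constraint on the indicator).
    method : {"exhaustive", "ga"}, default="exhaustive"
        Exhaustive enumeration of all C(p, k) subsets, or a genetic algorithm
        for large p.
    population_size, generations, crossover_rate, mutation_rate : GA controls.
        ``mutation_rate=None`` uses the per-bit rate 1/p.
    penalty_weight : float or None
        Weight of the cardinality penalty in the GA fitness; ``None`` picks
        ``10 * n^2 * max|G_i - G_j|``, large enough that an infeasible bit
        vector can never outscore a feasible one.
    exhaustive_cap : int
        Refuse exhaustive search beyond this many combinations.
    random_state : int or None
        Seed for the GA.

    Attributes
    ----------
    combination_ : tuple of int
        0-based indices of the best combination found.
    lc_value_ : float
        Its LC statistic.
    results_ : list of LCRankResult
        Full ranked list (exhaustive mode only; GA keeps the single best).
    n_features_in_ : int
    """

    def __init__(
        self,
        k: int = 2,
        method: str = "exhaustive",
        population_size: int = 50,
        generations: int = 100,
        crossover_rate: float = 0.8,
        mutation_rate: float | None = None,
        penalty_weight: float | None = None,
        exhaustive_cap: int = EXHAUSTIVE_CAP,
        random_state: int | None = None,
    ):
        self.k = k
        self.method = method
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.penalty_weight = penalty_weight
        self.exhaustive_cap = exhaustive_cap
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_nutrients(X)
        G = validate_response(y, n=X.shape[0])
        p = X.shape[1]
        if not 1 <= self.k <= p:
            raise ValueError(f"require 1 <= k <= p, got k={self.k}, p={p}")
        self.n_features_in_ = p
        if self.method == "exhaustive":
            self._fit_exhaustive(X, G, p)
        elif self.method == "ga":
            self._fit_ga(X, G, p)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    def _fit_exhaustive(self, X, G, p):
        from math import comb

        n_comb = comb(p, self.k)
        if n_comb > self.exhaustive_cap:
            raise ValueError(
                f"C({p},{self.k}) = {n_comb} exceeds the exhaustive cap "
                f"({self.exhaustive_cap}); use method='ga'"
            )
        combos = enumerate_combinations(p, self.k)
        values = _lc_all_combinations(X, G, combos)
        self.results_ = _rank(combos, values)
        best = self.results_[0]
        self.combination_ = best.combination
        self.lc_value_ = best.lc_value

    # ---- genetic algorithm -------------------------------------------------

    def _fit_ga(self, X, G, p):
        rng = np.random.default_rng(self.random_state)
        D = compute_diff_matrix(G)
        n = X.shape[0]
        mut = self.mutation_rate if self.mutation_rate is not None else 1.0 / p
        penalty = self.penalty_weight
        if penalty is None:
            penalty = 10.0 * n * n * max(float(D.max()), 1.0)

        def lc_of_bits(bits: np.ndarray) -> float:
            sel = np.flatnonzero(bits)
            W = compute_weight_matrix(X, sel)
            return float(np.sum(W * D))

        def fitness(bits: np.ndarray) -> float:
            return lc_of_bits(bits) + penalty * abs(int(bits.sum()) - self.k)

        # initial population: random exact-k subsets plus random bit vectors
        pop = np.zeros((self.population_size, p), dtype=bool)
        for i in range(self.population_size):
            if i < self.population_size // 2:
                pop[i, rng.choice(p, size=self.k, replace=False)] = True
            else:
                pop[i] = rng.random(p) < self.k / p
        fit = np.array([fitness(ind) for ind in pop])

        for _ in range(self.generations):
            children = np.empty_like(pop)
            for i in range(self.population_size):
                # binary tournament selection
                a, b = rng.integers(self.population_size, size=2)
                pa = pop[a] if fit[a] <= fit[b] else pop[b]
                a, b = rng.integers(self.population_size, size=2)
                pb = pop[a] if fit[a] <= fit[b] else pop[b]
                if rng.random() < self.crossover_rate:
                    mask = rng.random(p) < 0.5
                    child = np.where(mask, pa, pb)
                else:
                    child = pa.copy()
                flip = rng.random(p) < mut
                child = child ^ flip
                children[i] = child
            child_fit = np.array([fitness(ind) for ind in children])
            # elitism: keep the best parent
            worst = int(np.argmax(child_fit))
            best_parent = int(np.argmin(fit))
            if fit[best_parent] < child_fit[worst]:
                children[worst] = pop[best_parent]
                child_fit[worst] = fit[best_parent]
            pop, fit = children, child_fit

        best = pop[int(np.argmin(fit))].copy()
        best = self._repair(best, X, D, lc_of_bits, rng)
        if int(best.sum()) != self.k:
            raise RuntimeError("GA failed to produce a feasible combination")
        self.combination_ = tuple(int(i) for i in np.flatnonzero(best))
        self.lc_value_ = lc_of_bits(best)
        self.results_ = [LCRankResult(self.combination_, self.lc_value_, rank=1)]

    def _repair(self, bits, X, D, lc_of_bits, rng):
        """Project to exactly k selected bits, then greedy single-bit swaps."""
        bits = bits.copy()
        p = bits.size
        # adjust cardinality by greedy add/remove of the single best bit
        while bits.sum() > self.k:
            on = np.flatnonzero(bits)
            trials = []
            for j in on:
                b = bits.copy()
                b[j] = False
                trials.append((lc_of_bits(b), j))
            _, j = min(trials)
            bits[j] = False
        while bits.sum() < self.k:
            off = np.flatnonzero(~bits)
            trials = []
            for j in off:
                b = bits.copy()
                b[j] = True
                trials.append((lc_of_bits(b), j))
            _, j = min(trials)
            bits[j] = True
        # local search: swap one selected bit for one unselected while improving
        improved = True
        current = lc_of_bits(bits)
        while improved:
            improved = False
            for j_out in np.flatnonzero(bits):
                for j_in in np.flatnonzero(~bits):
                    b = bits.copy()
                    b[j_out], b[j_in] = False, True
                    v = lc_of_bits(b)
                    if v < current - 1e-12:
                        bits, current = b, v
                        improved = True
                        break
                if improved:
                    break
        return bits

    def transform(self, X):
        check_is_fitted(self, "combination_")
        X = np.asarray(X)
        return X[:, list(self.combination_)]

    def _more_tags(self):
        return {"requires_y": True}


def lc_opt_exhaustive(X, G, k: int, *, exhaustive_cap: int = EXHAUSTIVE_CAP) -> list[LCRankResult]:
    """Rank all C(p, k) combinations by ascending LC statistic."""
    est = LCOpt(k=k, method="exhaustive", exhaustive_cap=exhaustive_cap).fit(X, G)
    return est.results_


def lc_opt_ga(X, G, k: int, *, seed: int | None = None, **ga_params) -> LCRankResult:
    """Genetic-algorithm search for the best k-combination."""
    est = LCOpt(k=k, method="ga", random_state=seed, **ga_params).fit(X, G)
    return est.results_[0]
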