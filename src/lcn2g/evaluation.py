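"""Simulation experiments: LC distributions by combination group, and the
true/false-positive-rate study comparing LC-Test with two regression F-tests.

Combinations of k variables are grouped by how many of the model's informative
variables they contain (group A_1 contains them all, the last group none);
over replicated datasets the LC statistic should be smallest for A_1 and grow
as informative variables are dropped.  The power study rejects at p <= alpha
(permutation p-values sit on a 1/B grid that includes 0, so a strict rule
would discard exact zeros).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .application import zscore
from .core import compute_diff_matrix, compute_weight_matrix
from .inference import _permuted_lc_values, f_test1, f_test2
from .simulation import SimulationConfig, null_pair, simulate_dataset

__all__ = [
    "CombinationGrouping",
    "group_combinations",
    "lc_distribution_study",
    "run_power_study",
]


@dataclass
class CombinationGrouping:
    """Partition of all C(d, k) combinations by informative-variable count.

    ``groups[0]`` (A_1) holds combinations containing every informative
    variable that a k-subset can (min(k, m) of them, m = number of informative
    variables); the last group holds combinations containing none.
    """

    groups: list[list[tuple[int, ...]]]
    informative: frozenset[int]
    k: int
    d: int

    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]


def group_combinations(d: int, k: int, informative) -> CombinationGrouping:
    """Group all k-subsets of {0..d-1} by |subset ∩ informative|, descending."""
    informative = frozenset(informative)
    if not informative <= set(range(d)):
        raise ValueError("informative set must be a subset of the columns")
    max_overlap = min(k, len(informative))
    buckets: dict[int, list[tuple[int, ...]]] = {
        c: [] for c in range(max_overlap, -1, -1)
    }
    for combo in itertools.combinations(range(d), k):
        buckets[len(informative.intersection(combo))].append(combo)
    groups = [buckets[c] for c in range(max_overlap, -1, -1)]
    return CombinationGrouping(groups=groups, informative=informative, k=k, d=d)


def lc_distribution_study(cfg: SimulationConfig, k: int, reps: int = 100) -> pd.DataFrame:
    """LC statistic for every combination over replicated datasets.

    Returns a tidy frame with columns ``replicate``, ``combination``,
    ``group`` (1 = contains all informative variables the subset can), and
    ``lc``.  Box-plotting ``lc`` by ``group`` reproduces the grouped-LC view
    of the simulation study.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = simulate_dataset(cfg)
    grouping = group_combinations(cfg.d, k, base.informative_set)
    combo_group = {
        combo: gi + 1 for gi, g in enumerate(grouping.groups) for combo in g
    }
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(reps):
        ds = simulate_dataset(cfg, rng=rng)
        Xz = zscore(ds.X)
        D = compute_diff_matrix(ds.G)
        for combo, gi in combo_group.items():
            W = compute_weight_matrix(Xz, combo)
            rows.append((rep, combo, gi, float(np.sum(W * D))))
    return pd.DataFrame(rows, columns=["replicate", "combination", "group", "lc"])


def _lc_reject(X, sel, G, B, alpha, rng) -> bool:
    W = compute_weight_matrix(X, sel)
    D = np.abs(G[:, None] - G[None, :])
    observed = float(np.sum(W * D))
    null_vals = _permuted_lc_values(W, G, B, rng)
    p = np.sum(null_vals < observed) / B
    return p <= alpha


def run_power_study(
    models=(1, 2, 3),
    n_grid=(20, 50, 100),
    tests=("lc_test", "f_test1", "f_test2"),
    reps: int = 200,
    B: int = 1000,
    alpha: float = 0.05,
    d: int = 10,
    r: float = 0.1,
    k_null: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical TPR and FPR of each test across models and sample sizes.

    For each replicate one dataset is drawn; the TPR scenario tests the
    model's informative variable set, the FPR scenario a random subset of the
    non-informative columns (``k_null`` variables; default the informative
    set's size, so the null combination mirrors the alternative's).  Returns
    a frame with one row per (model, n, test) cell, columns ``tpr``, ``fpr``,
    ``n_replicates``, ``alpha``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(tests) - {"lc_test", "f_test1", "f_test2"}
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        for n in n_grid:
            cfg = SimulationConfig(model=model, n=n, d=d, r=r)
            hits = {t: [0, 0] for t in tests}  # test -> [tpr_count, fpr_count]
            for _ in range(reps):
                ds = simulate_dataset(cfg, rng=rng)
                Xz = zscore(ds.X)
                sel_alt = ds.informative_set
                kn = k_null if k_null is not None else len(sel_alt)
                sel_null = null_pair(cfg, k=kn, rng=rng)
                for t in tests:
                    for j, sel in enumerate((sel_alt, sel_null)):
                        if t == "lc_test":
                            rej = _lc_reject(Xz, sel, ds.G, B, alpha, rng)
                        else:
                            f = f_test1 if t == "f_test1" else f_test2
                            rej = f(Xz[:, list(sel)], ds.G) <= alpha
                        hits[t][j] += rej
            for t in tests:
                rows.append(
                    dict(model=model, n=n, test=t,
                         tpr=hits[t][0] / reps, fpr=hits[t][1] / reps,
                         n_replicates=reps, alpha=alpha)
                )
    return pd.DataFrame(rows)
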