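"""LC-Test permutation inference and comparator F-tests.

LC-Test asks whether a chosen nutrient combination has a non-random smooth
relationship with a response: the observed LC statistic is compared against
the LC values of B random permutations of the response, and

    p_perm = (1/B) * #{ b : LC(M; G_b) < LC(M; G) }.

A small p-value means the observed response is smoother over the selected
nutrient subspace than almost all permuted responses.  The strict "<" is kept
as-is (ties count against significance) and p = 0 is attainable; a
conservative (+1)/(B+1) variant is available via ``conservative=True``.

The comparators are the overall-regression F-tests of a main-effects linear
model (``f_test1``) and a linear model with all pairwise interactions among
the selected variables (``f_test2``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core import (
    compute_weight_matrix,
    validate_nutrients,
    validate_response,
    validate_selection,
)

__all__ = ["PermutationTestResult", "lc_test", "f_test1", "f_test2"]


@dataclass
class PermutationTestResult:
    observed_lc: float
    p_value: float
    n_permutations: int
    seed: int | None
    null_lc_values: np.ndarray | None = None


def _permuted_lc_values(W: np.ndarray, G: np.ndarray, B: int, rng: np.random.Generator,
                        batch: int = 250) -> np.ndarray:
    """LC(M; G_b) for B independent uniform permutations of G.

    W is computed once by the caller; each batch builds the (b, n, n) tensor of
    absolute response differences and contracts it against W, so the whole test
    costs O(B n^2) time and O(batch n^2) memory.
    """
    n = G.shape[0]
    out = np.empty(B)
    done = 0
    while done < B:
        m = min(batch, B - done)
        perms = np.empty((m, n), dtype=np.intp)
        for i in range(m):
            perms[i] = rng.permutation(n)
        Gp = G[perms]  # (m, n)
        Dp = np.abs(Gp[:, :, None] - Gp[:, None, :])
        out[done:done + m] = np.tensordot(Dp, W, axes=([1, 2], [0, 1]))
        done += m
    return out


def lc_test(
    X,
    selected,
    G,
    B: int = 1000,
    seed: int | None = None,
    *,
    conservative: bool = False,
    return_null: bool = False,
    rng: np.random.Generator | None = None,
) -> PermutationTestResult:
    """Permutation test of the LC statistic for one nutrient combination.

    Parameters
    ----------
    X : (n, p) nutrient matrix.
    selected : 0-based column indices of the tested combination.
    G : length-n response vector; must not be constant (a constant response
        makes every permuted LC equal to 0 = observed, and the literal
        p-value formula would report spurious significance).
    B : number of permutations (>= 1).
    seed : seed for the permutation stream; ignored when ``rng`` is given.
    conservative : use (count + 1) / (B + 1) instead of count / B.
    return_null : attach the B permuted LC values to the result.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = validate_nutrients(X)
    G = validate_response(G, n=X.shape[0])
    sel = validate_selection(selected, X.shape[1])
    if np.ptp(G) == 0:
        raise ValueError("degenerate response: G is constant, LC-Test undefined")
    if rng is None:
        rng = np.random.default_rng(seed)
    W = compute_weight_matrix(X, sel)
    D = np.abs(G[:, None] - G[None, :])
    observed = float(np.sum(W * D))
    null_vals = _permuted_lc_values(W, G, B, rng)
    count = int(np.sum(null_vals < observed))
    p = (count + 1) / (B + 1) if conservative else count / B
    return PermutationTestResult(
        observed_lc=observed,
        p_value=float(p),
        n_permutations=B,
        seed=seed,
        null_lc_values=null_vals if return_null else None,
    )


def _overall_f_pvalue(design: np.ndarray, G: np.ndarray) -> float:
    n, q = design.shape
    if n <= q + 1:
        raise ValueError(f"need n > {q + 1} samples for {q} model terms")
    Xd = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(G, Xd).fit()
    return float(res.f_pvalue)


def f_test1(X_sel, G) -> float:
    """Overall F-test p-value for the main-effects linear model of G on X_sel."""
    X_sel = validate_nutrients(X_sel)
    G = validate_response(G, n=X_sel.shape[0])
    return _overall_f_pvalue(X_sel, G)


def f_test2(X_sel, G) -> float:
    """Overall F-test p-value for main effects plus all pairwise interactions."""
    X_sel = validate_nutrients(X_sel)
    G = validate_response(G, n=X_sel.shape[0])
    cols = [X_sel]
    for a, b in itertools.combinations(range(X_sel.shape[1]), 2):
        cols.append((X_sel[:, a] * X_sel[:, b])[:, None])
    design = np.hstack(cols)
    return _overall_f_pvalue(design, G)
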