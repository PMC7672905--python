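"""Local Consistency (LC) statistic and its constituent pairwise matrices.

The LC statistic quantifies how smoothly a scalar response ``G`` (typically one
gene's expression across samples) varies over a selected subspace of nutrient
variables.  For a nutrient matrix ``X`` (n samples x p nutrients) and a diagonal
0/1 indicator ``M`` selecting a subset of columns,

    LC(M; G) = tr{ W(M) D(G) } = sum_ij W_ij * D_ij,

where ``W_ij = exp(-(x_i - x_j) M (x_i - x_j)^T)`` is a Gaussian-kernel
similarity restricted to the selected columns and ``D_ij = |G_i - G_j|``.
Small LC means nearby samples (in the selected nutrient subspace) have similar
expression, i.e. the response surface over those nutrients is locally smooth.

No kernel bandwidth appears in the similarity: the quadratic form is used with
unit scale, which is why z-scoring nutrient columns measured in heterogeneous
units matters before computing LC (see :func:`lcn2g.application.standardize`).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "validate_nutrients",
    "validate_response",
    "validate_selection",
    "compute_weight_matrix",
    "compute_diff_matrix",
    "lc_stat",
]


def validate_nutrients(X) -> np.ndarray:
    """Coerce ``X`` to a finite 2-D float array with n >= 2 samples."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"nutrient matrix must be 2-D, got shape {X.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if X.shape[1] < 1:
        raise ValueError("need at least 1 nutrient column")
    if not np.all(np.isfinite(X)):
        raise ValueError("nutrient matrix contains non-finite values")
    return X


def validate_response(G, n: int | None = None) -> np.ndarray:
    """Coerce ``G`` to a finite 1-D float vector, optionally of length ``n``."""
    G = np.asarray(G, dtype=float).ravel()
    if not np.all(np.isfinite(G)):
        raise ValueError("response vector contains non-finite values")
    if n is not None and G.shape[0] != n:
        raise ValueError(
            f"response length {G.shape[0]} does not match sample count {n}"
        )
    return G


def validate_selection(selected: Iterable[int], p: int) -> np.ndarray:
    """Validate 0-based column indices against ``p`` total columns.

    Returns the indices as an int array in the order supplied.  An empty
    selection is allowed (the similarity matrix degenerates to all ones).
    """
    sel = np.asarray(list(selected), dtype=int)
    if sel.size and (sel.min() < 0 or sel.max() >= p):
        raise IndexError(f"selected columns {sel.tolist()} out of range for p={p}")
    if len(set(sel.tolist())) != sel.size:
        raise ValueError("selected columns must be distinct")
    return sel


def compute_weight_matrix(X, selected: Sequence[int]) -> np.ndarray:
    """Gaussian similarity ``W_ij = exp(-sum_{c in selected}(x_ic - x_jc)^2)``.

    ``selected`` holds the 0-based indices where the diagonal indicator M is 1.
    Symmetric, entries in (0, 1], unit diagonal.  An empty selection yields the
    all-ones matrix (empty sum in the exponent).
    """
    X = validate_nutrients(X)
    sel = validate_selection(selected, X.shape[1])
    n = X.shape[0]
    if sel.size == 0:
        return np.ones((n, n))
    Xs = X[:, sel]
    # squared Euclidean distances in the selected subspace, clipped to >= 0
    # against floating-point cancellation
    sq = np.sum(Xs**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Xs @ Xs.T)
    np.maximum(d2, 0.0, out=d2)
    W = np.exp(-d2)
    np.fill_diagonal(W, 1.0)
    return W


def compute_diff_matrix(G) -> np.ndarray:
    """Absolute response differences ``D_ij = |G_i - G_j|``."""
    G = validate_response(G)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return np.abs(G[:, None] - G[None, :])


def lc_stat(X, selected: Sequence[int], G) -> float:
    """Local consistency statistic ``LC = tr{W D} = sum_ij W_ij D_ij``.

    Because D is symmetric, the trace of the matrix product equals the
    elementwise sum, so the computation is O(n^2) and never forms W @ D.
    """
    X = validate_nutrients(X)
    G = validate_response(G, n=X.shape[0])
    W = compute_weight_matrix(X, selected)
    D = compute_diff_matrix(G)
    return float(np.sum(W * D))


def lc_stat_from_weights(W: np.ndarray, G: np.ndarray) -> float:
    """LC given a precomputed similarity matrix (used by permutation loops)."""
    D = np.abs(G[:, None] - G[None, :])
    return float(np.sum(W * D))
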