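"""Separation quality via the Amari performance index.

For true mixing ``H`` and estimated unmixing ``W`` the global matrix
``G = W H`` should be a permutation of a diagonal matrix when separation is
perfect.  The Amari index of a matrix is

    PI(G) = 1 / (2 N (N-1)) * [ sum_i ( sum_j |g_ij| / max_k |g_ik| - 1 )
                              + sum_j ( sum_i |g_ij| / max_k |g_kj| - 1 ) ]

Evaluated directly, this expression is invariant to permutations but only
approximately invariant to row/column rescaling (rescaling a row can change
which entry is a column maximum).  Because the global matrix of a blind
separator is only ever defined up to diagonal scaling, we evaluate the
expression on the *canonical representative* of G's diagonal-equivalence
class.  For N = 2 that class is fully characterized by the single invariant

    r = |g12 g21| / |g11 g22|,

whose balanced representative is [[1, s], [s, 1]] with
``s = sqrt(min(r, 1/r))``; the Amari expression on it equals ``s``.  The
result is exactly invariant to row/column rescaling and permutation, zero
exactly on (all-nonzero) permutation-scaling matrices, equal to the plain
Amari value for symmetric leakage, and 1 for the maximally mixed all-ones
matrix.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError, UndefinedIndexError

__all__ = ["performance_index", "evaluate_separation"]


def _amari_expression(A: np.ndarray) -> float:
    n = A.shape[0]
    rows = (A / A.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (A / A.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))


def performance_index(G: np.ndarray) -> float:
    """Amari performance index of a 2x2 global (unmixing x mixing) matrix,
    evaluated on the canonical representative of its diagonal-equivalence
    class (see module docstring)."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape != (2, 2):
        raise InvalidArgumentError("G must be a 2x2 matrix")
    if not np.all(np.isfinite(G)):
        raise InvalidArgumentError("G contains non-finite entries")
    A = np.abs(G)
    if np.any(A.max(axis=1) == 0) or np.any(A.max(axis=0) == 0):
        raise UndefinedIndexError("|G| has a zero row or column")
    diag = A[0, 0] * A[1, 1]
    anti = A[0, 1] * A[1, 0]
    if diag == 0.0 and anti == 0.0:
        raise UndefinedIndexError("both diagonals of |G| vanish")
    small, large = sorted((diag, anti))
    s = np.sqrt(small / large)  # invariant of the equivalence class
    return _amari_expression(np.array([[1.0, s], [s, 1.0]]))


def evaluate_separation(result, truth_H: np.ndarray) -> float:
    """Performance index of ``W @ H_true`` for a separation result."""
    truth_H = np.asarray(truth_H, dtype=float)
    if abs(np.linalg.det(truth_H)) <= 1e-12:
        raise InvalidArgumentError("truth mixing matrix is singular")
    return performance_index(result.W @ truth_H)
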