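"""Identification of pattern-constrained loadings via the LQ decomposition.

A factor expansion ``Gamma @ F`` is invariant under ``(Gamma H, H' F)`` for
any orthogonal H, so neither the loadings nor the factors are identified by
the likelihood alone.  Writing ``Gamma = L Q`` with L lower triangular
(leading block, positive diagonal) and Q orthogonal makes the pair
``(L, F_tilde = Q F)`` identified: L is the unique triangular representative
of the rotation orbit and F_tilde inherits the unit conditional variance of
F because ``Q Var(F) Q' = I``.

The decomposition is built from the transposed loadings: split
``Gamma' = [A1 | A2]`` where A1 is the (generically invertible) m x m block
from the first m outcomes, QR-factorise ``A1 = Qg R1`` by modified
Gram-Schmidt with a positive-diagonal sign convention, set
``R2 = Qg' A2`` and ``R = [R1 | R2]``.  Then ``L = R'`` and ``Q = Qg'``
satisfy ``Gamma = L Q`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .model import LoadingsMatrix, LoadingsPattern

#: Scale-free rank tolerance: a pivot column whose post-projection norm falls
#: below RANK_RTOL times the largest column norm is declared rank deficient.
RANK_RTOL = 1e-12


class RankDeficientError(ValueError):
    """Raised when the leading loadings block is numerically rank deficient."""

    def __init__(self, column: int):
        self.column = column
        super().__init__(f"leading block is rank deficient at pivot column {column}")


@dataclass
class LQPair:
    """Result of the decomposition: Gamma = L @ Q.

    L is K x m with lower-triangular leading m x m block and strictly
    positive diagonal; Q is m x m orthogonal.
    """

    L: np.ndarray
    Q: np.ndarray


@dataclass
class PatternDiagnostic:
    """Outcome of structural validation of a loadings pattern."""

    ok: bool
    message: str = "ok"
    suggested_order: tuple | None = None

    def __bool__(self):
        return self.ok


def _generically_invertible(block_mask: np.ndarray, rng=None, trials: int = 3) -> bool:
    """Whether a 0/1 sparsity block admits an invertible matrix generically.

    Random values are assigned to the free entries; with probability one a
    generically invertible pattern yields a full-rank draw, so a few draws
    decide the question robustly.
    """
    m = block_mask.shape[0]
    rng = np.random.default_rng(0) if rng is None else rng
    for _ in range(trials):
        A = np.where(block_mask, rng.standard_normal(block_mask.shape), 0.0)
        if np.linalg.matrix_rank(A) == m:
            return True
    return False


def validate_pattern(pattern: LoadingsPattern) -> PatternDiagnostic:
    """Check that the pattern supports the LQ identification.

    Requirements on the leading m x m block (rows taken in
    ``pattern.outcome_order``): a free entry in every row and every column,
    and generic invertibility.  Each factor column must carry exactly one
    positivity anchor (enforced at construction).  When the leading block
    fails, a row permutation of the outcomes that repairs it is searched for
    and proposed in the diagnostic.
    """
    K, m = pattern.mask.shape
    ordered = pattern.mask[list(pattern.outcome_order), :]
    block = ordered[:m, :]
    for j in range(m):
        if not block[:, j].any():
            return PatternDiagnostic(False, f"empty column {j} in leading block",
                                     _propose_order(pattern))
    for r in range(m):
        if not block[r, :].any():
            return PatternDiagnostic(False, f"empty row {r} in leading block",
                                     _propose_order(pattern))
    if not _generically_invertible(block):
        return PatternDiagnostic(False,
                                 "leading block is generically rank deficient",
                                 _propose_order(pattern))
    return PatternDiagnostic(True)


def _propose_order(pattern: LoadingsPattern) -> tuple | None:
    """Brute-force search for an outcome order with an invertible leading block."""
    K, m = pattern.mask.shape
    for perm in permutations(range(K)):
        block = pattern.mask[list(perm), :][:m, :]
        if not (block.any(axis=0).all() and block.any(axis=1).all()):
            continue
        if _generically_invertible(block):
            return tuple(perm)
    return None


def partition(loadings: LoadingsMatrix, pattern: LoadingsPattern):
    """Split the transposed loadings into (A1, A2) per the outcome order.

    A1 is m x m from the first m (ordered) outcomes; A2 is m x (K - m) from
    the rest; ``np.hstack([A1, A2])`` equals the ordered Gamma transposed.
    """
    diag = validate_pattern(pattern)
    if not diag:
        raise ValueError(f"invalid pattern: {diag.message}")
    K, m = pattern.mask.shape
    gt = loadings.values[list(pattern.outcome_order), :].T
    return gt[:, :m].copy(), gt[:, m:].copy()


def gram_schmidt_qr(A: np.ndarray):
    """QR factorisation of a square matrix by modified Gram-Schmidt.

    Returns (Qg, R1) with A = Qg @ R1, Qg orthogonal and R1 upper triangular
    with strictly positive diagonal (a negative pivot flips the paired Qg
    column and R1 row).  Raises RankDeficientError when a pivot column's
    post-projection norm falls below ``RANK_RTOL`` times the largest column
    norm of A.
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    if m != n:
        raise ValueError("gram_schmidt_qr expects a square matrix")
    V = A.copy()
    Qg = np.zeros((m, m))
    R1 = np.zeros((m, m))
    col_norms = np.linalg.norm(A, axis=0)
    tol = RANK_RTOL * (col_norms.max() if col_norms.size else 0.0)
    for j in range(m):
        norm = np.linalg.norm(V[:, j])
        if norm <= tol:
            raise RankDeficientError(j)
        R1[j, j] = norm
        Qg[:, j] = V[:, j] / norm
        if j + 1 < m:
            proj = Qg[:, j] @ V[:, j + 1:]
            R1[j, j + 1:] = proj
            V[:, j + 1:] -= np.outer(Qg[:, j], proj)
    # positive-diagonal sign convention
    for j in range(m):
        if R1[j, j] < 0:  # cannot happen here (norms), kept for clarity
            Qg[:, j] = -Qg[:, j]
            R1[j, :] = -R1[j, :]
    return Qg, R1


def lq_decompose(loadings: LoadingsMatrix, pattern: LoadingsPattern | None = None) -> LQPair:
    """Decompose Gamma (ordered by the pattern) into L @ Q.

    Returns the identified pair: L with lower-triangular positive-diagonal
    leading block, Q orthogonal (the transpose of the Gram-Schmidt factor of
    the transposed leading block, so that ``Gamma = L @ Q`` holds exactly).
    """
    pattern = loadings.pattern if pattern is None else pattern
    A1, A2 = partition(loadings, pattern)
    Qg, R1 = gram_schmidt_qr(A1)
    R2 = Qg.T @ A2
    R = np.hstack([R1, R2])
    return LQPair(L=R.T, Q=Qg.T)


def lq_from_values(gamma_ordered: np.ndarray, m: int) -> LQPair:
    """LQ decomposition of an already outcome-ordered (K, m) loadings array.

    Fast path used inside the sampler, bypassing pattern revalidation.
    """
    gt = gamma_ordered.T
    Qg, R1 = gram_schmidt_qr(gt[:, :m])
    R2 = Qg.T @ gt[:, m:]
    return LQPair(L=np.hstack([R1, R2]).T, Q=Qg.T)


def identified_quantities(loadings: LoadingsMatrix, pattern: LoadingsPattern,
                          factors: np.ndarray):
    """Map (Gamma, F) to the identified pair (L, F_tilde = Q F).

    ``factors`` has shape (I, J, m); the returned F_tilde has the same shape
    and satisfies ``L @ F_tilde[i,j] == Gamma_ordered @ F[i,j]`` up to float
    round-off.
    """
    pair = lq_decompose(loadings, pattern)
    factors = np.asarray(factors, dtype=float)
    f_tilde = np.einsum("ab,ijb->ija", pair.Q, factors)
    return pair.L, f_tilde
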