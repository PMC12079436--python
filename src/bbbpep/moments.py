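"""Square-matrix reshaping and raw / central / discrete Hahn moments.

A peptide of length n is mapped to residue ordinals 1..20 and laid out
row-major into a k x k matrix with k = ceil(sqrt(n)), zero-padded. Each
square matrix (this sequence matrix, or a 20x20 incidence matrix) is then
compressed to the 10 moments of aggregate order <= 3 per family:

* raw moments      U_ab = sum_e sum_f e^a f^b M[e, f]   (1-based e, f)
* central moments  v_ab = the same about the mass centroid (x_bar, y_bar)
* Hahn moments     H_pq = sum_i sum_j M[i, j] h_p(j) h_q(i) with h_n the
  orthonormal zero-parameter discrete Hahn polynomials on {0, ..., k-1}

The zero-parameter Hahn family has uniform weight, so the orthonormal basis
coincides with the discrete Chebyshev polynomials. It is computed by the
orthonormal three-term recurrence (Jacobi coefficients b_n = (N-1)/2 and
a_n^2 = n^2 (N^2 - n^2) / (4 (4 n^2 - 1))), which is numerically stable,
rather than by the factorial closed form. Because the basis is orthonormal,
keeping all k x k coefficients makes the transform exactly invertible —
``inverse_hahn`` exposes that reconstruction as a correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np

from bbbpep.sequences import AA_INDEX, Peptide

#: Fixed (a, b) order of the 10 moments of aggregate order <= 3.
ORDER_PAIRS = ((0, 0), (0, 1), (1, 0), (1, 1), (0, 2), (2, 0), (1, 2), (2, 1), (0, 3), (3, 0))

#: Largest supported Hahn grid; the recurrence is stable well past the
#: k <= 20 matrices this package produces, but refuse unbounded requests.
MAX_HAHN_ORDER = 128

_CENTRAL_TOL = 1e-9


@dataclass(frozen=True)
class MomentSet:
    """The 10 moments of one family for one square matrix.

    values[m] corresponds to ORDER_PAIRS[m]; family is one of
    {"raw", "central", "hahn"}.
    """

    family: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.family not in ("raw", "central", "hahn"):
            raise ValueError(f"unknown moment family {self.family!r}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (10,):
            raise ValueError(f"expected 10 moments, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple) -> float:
        return float(self.values[ORDER_PAIRS.index(pair)])


def sequence_to_matrix(p: Peptide) -> np.ndarray:
    """Residue ordinals (A=1 .. Y=20) laid out row-major into k x k, k = ceil(sqrt(n))."""
    ordinals = np.fromiter((AA_INDEX[ch] + 1 for ch in p.sequence), dtype=float, count=len(p))
    k = ceil(sqrt(len(p)))
    out = np.zeros(k * k)
    out[: len(p)] = ordinals
    return out.reshape(k, k)


def _as_square(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 1:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    return M


def raw_moments(M: np.ndarray) -> MomentSet:
    """U_ab = sum_e sum_f e^a f^b M[e, f] with 1-based row index e, column index f."""
    M = _as_square(M)
    k = M.shape[0]
    g = np.arange(1, k + 1, dtype=float)
    vals = [np.einsum("e,f,ef->", g**a, g**b, M) for a, b in ORDER_PAIRS]
    return MomentSet("raw", np.array(vals))


def central_moments(M: np.ndarray) -> MomentSet:
    """v_ab about the centroid (x_bar = U10/U00, y_bar = U01/U00).

    A zero-mass matrix (U00 = 0) has all central moments defined as 0.
    """
    M = _as_square(M)
    k = M.shape[0]
    g = np.arange(1, k + 1, dtype=float)
    u00 = M.sum()
    if u00 == 0.0:
        return MomentSet("central", np.zeros(10))
    x_bar = np.einsum("e,ef->", g, M) / u00
    y_bar = np.einsum("f,ef->", g, M) / u00
    e = g - x_bar
    f = g - y_bar
    vals = [np.einsum("e,f,ef->", e**a, f**b, M) for a, b in ORDER_PAIRS]
    return MomentSet("central", np.array(vals))


def hahn_basis(Q: int) -> np.ndarray:
    """Orthonormal zero-parameter discrete Hahn basis on the grid {0, ..., Q-1}.

    Returns a (Q, Q) array B with B[n, p] = h_n(p), satisfying
    B @ B.T = identity (within 1e-8 for Q <= 16). Sign convention: positive
    leading coefficient, so h_0 = 1/sqrt(Q) and h_1 increases with p.
    """
    if Q < 1:
        raise ValueError(f"Q must be >= 1, got {Q}")
    if Q > MAX_HAHN_ORDER:
        raise ValueError(f"Q = {Q} exceeds the supported cap {MAX_HAHN_ORDER}")
    x = np.arange(Q, dtype=float)
    B = np.zeros((Q, Q))
    B[0] = 1.0 / sqrt(Q)
    if Q == 1:
        return B
    b_centre = (Q - 1) / 2.0  # grid centre; constant for the uniform weight

    def a_coef(n: int) -> float:
        return (n / 2.0) * sqrt((Q * Q - n * n) / (4.0 * n * n - 1.0))

    B[1] = (x - b_centre) * B[0] / a_coef(1)
    for n in range(2, Q):
        B[n] = ((x - b_centre) * B[n - 1] - a_coef(n - 1) * B[n - 2]) / a_coef(n)
    return B


def hahn_moments(M: np.ndarray) -> MomentSet:
    """H_pq = sum_i sum_j M[i, j] h_p(j) h_q(i), the 10 orders with p + q <= 3.

    For k < 4 the orders that exceed the basis (p or q > k - 1) are 0.
    """
    M = _as_square(M)
    k = M.shape[0]
    B = hahn_basis(k)
    # full[p, q] = sum_i sum_j M[i, j] B[p, j] B[q, i]
    full = B @ M.T @ B.T
    vals = [full[p, q] if (p < k and q < k) else 0.0 for p, q in ORDER_PAIRS]
    return MomentSet("hahn", np.array(vals))


def hahn_full(M: np.ndarray) -> np.ndarray:
    """All k x k Hahn coefficients of a k x k matrix (for reconstruction)."""
    M = _as_square(M)
    B = hahn_basis(M.shape[0])
    return B @ M.T @ B.T


def inverse_hahn(full_moments: np.ndarray, k: int) -> np.ndarray:
    """Reconstruct the original k x k matrix from its complete Hahn coefficients.

    Exact inverse of :func:`hahn_full` by orthonormality of the basis;
    max-abs reconstruction error stays below 1e-6 for k <= 12.
    """
    H = np.asarray(full_moments, dtype=float)
    if H.shape != (k, k):
        raise ValueError(f"need the complete {k}x{k} coefficient set, got shape {H.shape}")
    B = hahn_basis(k)
    # H = B M^T B^T  =>  M = (B^T H B)^T
    return (B.T @ H @ B).T


def matrix_moment_features(M: np.ndarray) -> np.ndarray:
    """The 30-feature compression of one square matrix: raw(10) | central(10) | hahn(10)."""
    return np.concatenate(
        [raw_moments(M).values, central_moments(M).values, hahn_moments(M).values]
    )
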