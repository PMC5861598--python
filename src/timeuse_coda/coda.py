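"""Aitchison-geometry primitives for compositional data.

A composition is a vector of strictly positive parts carrying only relative
information; it lives on the simplex, where closure to a constant total
(``kappa``: 1, 100 or, for a day of time use, 1440 minutes) removes the
absolute scale.  The operations here — closure, perturbation, powering,
geometric/compositional means, the pairwise-log-ratio variation matrix and
the isometric log-ratio (ilr) transform with its inverse — are the complete
toolkit the rest of the package builds on.

All functions accept either a single composition (1-d array) or a matrix of
row compositions (2-d array) where that makes sense, and always return
``float64`` numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "close",
    "perturb",
    "power",
    "geometric_mean_parts",
    "compositional_mean",
    "variation_matrix",
    "make_ilr_basis",
    "ilr",
    "ilr_inverse",
]


def _as_positive(x: np.ndarray, what: str = "composition") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"empty {what}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what} contains non-finite entries")
    if np.any(x <= 0):
        raise ValueError(
            f"{what} must be strictly positive; zeros must be handled by "
            "rounded-zero imputation before log-ratio operations"
        )
    return x


def close(x: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    """Close a positive vector (or row matrix) so parts sum to ``kappa``.

    Closure rescales each row to a constant total, preserving every ratio
    between parts exactly.  ``kappa`` defaults to 1 (proportions); use 1440
    for minutes per day.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    x = _as_positive(x)
    total = x.sum(axis=-1, keepdims=True)
    return kappa * x / total


def perturb(x: np.ndarray, y: np.ndarray, kappa: float | None = None) -> np.ndarray:
    """Perturbation x ⊕ y: component-wise product, closed.

    Plays the role of addition in the simplex.  The uniform composition is
    the neutral element.  If ``kappa`` is None, the total of ``x`` is kept.
    """
    x = _as_positive(x, "x")
    y = _as_positive(y, "y")
    if x.shape[-1] != y.shape[-1]:
        raise ValueError("perturb: dimension mismatch")
    if kappa is None:
        kappa = float(np.atleast_2d(x).sum(axis=-1)[0])
    return close(x * y, kappa)


def power(x: np.ndarray, a: float, kappa: float | None = None) -> np.ndarray:
    """Powering a ⊙ x: raise each part to scalar power ``a``, then close.

    Plays the role of scalar multiplication in the simplex; ``a = 0`` yields
    the uniform composition.
    """
    x = _as_positive(x)
    if kappa is None:
        kappa = float(np.atleast_2d(x).sum(axis=-1)[0])
    return close(x**a, kappa)


def geometric_mean_parts(X: np.ndarray) -> np.ndarray:
    """Per-part geometric mean of a matrix of row compositions (NOT closed).

    The geometric mean is the appropriate measure of central tendency for
    relative data: the column-wise exp of mean logs.  A single row is
    returned unchanged.
    """
    X = np.atleast_2d(_as_positive(X, "composition matrix"))
    return np.exp(np.log(X).mean(axis=0))


def compositional_mean(X: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    """Compositional mean (centre): geometric means of parts closed to kappa.

    Ratios between parts are identical to those of the unclosed geometric
    means — closure only restores the interpretable total.
    """
    return close(geometric_mean_parts(X), kappa)


def variation_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise log-ratio variance matrix T, T_ij = var(ln(x_i / x_j)).

    An indicator of dispersion coherent with the simplex: small entries mark
    pairs that move in near-constant proportion, large entries mark freely
    interchangeable parts.  Uses the unbiased (N-1) denominator; requires at
    least two rows.  Scale invariant: closure of the input does not change it.
    """
    X = np.atleast_2d(_as_positive(X, "composition matrix"))
    n = X.shape[0]
    if n < 2:
        raise ValueError("variation_matrix requires at least 2 rows")
    L = np.log(X)
    C = np.cov(L, rowvar=False, ddof=1)
    d = np.diag(C)
    T = d[:, None] + d[None, :] - 2.0 * C
    np.fill_diagonal(T, 0.0)
    return np.maximum(T, 0.0)


def make_ilr_basis(D: int) -> np.ndarray:
    """Contrast matrix ((D-1) x D) of pivot ilr coordinates.

    Sequential binary partition in which coordinate j contrasts part j
    against the geometric mean of the remaining parts j+1..D, with
    normalising constant sqrt((D-j)/(D-j+1)).  Rows sum to zero and are
    orthonormal (V V' = I), so the transform is an isometry.  Coordinate j
    is positive exactly when part j exceeds the geometric mean of the parts
    after it.
    """
    if D < 2:
        raise ValueError("need at least 2 parts")
    V = np.zeros((D - 1, D))
    for j in range(D - 1):  # 0-based; contrasts part j vs parts j+1..D-1
        r = D - j - 1  # number of parts in the denominator group
        a = np.sqrt(r / (r + 1.0))
        V[j, j] = a
        V[j, j + 1 :] = -a / r
    return V


def _check_basis(basis: np.ndarray, D: int) -> np.ndarray:
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (D - 1, D):
        raise ValueError(f"basis shape {basis.shape} incompatible with D={D}")
    return basis


def ilr(x: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates z = V ln(x) of a composition.

    Produces D-1 unconstrained real coordinates; closure invariant (any
    positive rescaling of ``x`` gives identical coordinates because basis
    rows sum to zero).
    """
    x = _as_positive(x)
    D = x.shape[-1]
    V = make_ilr_basis(D) if basis is None else _check_basis(basis, D)
    return np.log(x) @ V.T


def ilr_inverse(
    z: np.ndarray, basis: np.ndarray | None = None, kappa: float = 1.0
) -> np.ndarray:
    """Back-transform ilr coordinates to a composition closed to ``kappa``.

    Inverse of :func:`ilr`: close(exp(V' z), kappa).  Round trip with
    :func:`ilr` is the identity on the simplex.
    """
    z = np.asarray(z, dtype=float)
    Dm1 = z.shape[-1]
    V = make_ilr_basis(Dm1 + 1) if basis is None else _check_basis(basis, Dm1 + 1)
    return close(np.exp(z @ V), kappa)
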