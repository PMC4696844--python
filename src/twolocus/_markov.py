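"""Finite-state Markov chain utilities: primitivity tests and stationary vectors.

Used both for mutation transition matrices (stationary allele frequencies
pi^A, pi^B) and for backward migration matrices (stationary deme weights xi).
"""
from __future__ import annotations

import numpy as np

from .exceptions import ParameterError

_ROW_TOL = 1e-12


def check_stochastic(M: np.ndarray, name: str = "matrix", tol: float = _ROW_TOL) -> np.ndarray:
    """Validate a row-stochastic matrix and return it as a float array."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ParameterError(f"{name} must be a square matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ParameterError(f"{name} has non-finite entries")
    if np.any(M < 0):
        raise ParameterError(f"{name} has negative entries")
    dev = np.max(np.abs(M.sum(axis=1) - 1.0))
    if dev > tol:
        raise ParameterError(f"rows of {name} must sum to 1 (max deviation {dev:.3e})")
    return M


def is_primitive(M: np.ndarray) -> bool:
    """True iff the non-negative matrix is primitive (irreducible and aperiodic).

    Checks strict positivity of M^k for k up to Wielandt's primitivity
    exponent bound (n-1)^2 + 1, on the boolean sparsity pattern only.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n == 1:
        return bool(M[0, 0] > 0)
    pattern = (M > 0).astype(np.int64)
    power = pattern.copy()
    for _ in range((n - 1) ** 2 + 1):
        if power.all():
            return True
        power = np.minimum(power @ pattern, 1)
    return bool(power.all())


def check_primitive(M: np.ndarray, name: str = "matrix") -> None:
    if not is_primitive(M):
        raise ParameterError(
            f"{name} must be irreducible and aperiodic "
            "(no power of its sparsity pattern is strictly positive)"
        )


def _power_iteration(M: np.ndarray, tol: float = 1e-13, start: np.ndarray | None = None,
                     max_iter: int = 1_000_000) -> np.ndarray:
    n = M.shape[0]
    x = np.full(n, 1.0 / n) if start is None else np.asarray(start, dtype=float)
    for _ in range(max_iter):
        nxt = x @ M
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - x)) < tol:
            return nxt
        x = nxt
    return x


def stationary_distribution(M: np.ndarray, tol: float = 1e-13, check: bool = True) -> np.ndarray:
    """Left stationary probability vector of a primitive row-stochastic matrix.

    Solves the left-eigenvector problem xi (M - I) = 0 with the normalisation
    sum(xi) = 1 by a direct linear solve; falls back to power iteration for
    ill-conditioned inputs.
    """
    M = np.asarray(M, dtype=float)
    if check:
        M = check_stochastic(M, "M")
        check_primitive(M, "M")
    n = M.shape[0]
    if n == 1:
        return np.array([1.0])
    A = M.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        xi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        xi = None
    if xi is None or not np.all(np.isfinite(xi)) or np.any(xi < -1e-10):
        xi = _power_iteration(M, tol)
    xi = np.clip(xi, 0.0, None)
    xi = xi / xi.sum()
    if np.max(np.abs(xi @ M - xi)) > 1e-12:
        xi = _power_iteration(M, tol, start=xi)
        xi = xi / xi.sum()
    return xi
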