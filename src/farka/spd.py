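"""Primitives on symmetric positive-definite (SPD) matrices.

Covariance matrices of multichannel EEG epochs are SPD and live on a
Riemannian manifold. This module provides the matrix functions (log, exp,
fractional powers), the affine-invariant Riemannian distance, and three
notions of mean (Euclidean, log-Euclidean, and the Karcher/Riemannian mean)
that the alignment and tangent-space stages are built on.

All eigendecompositions symmetrize their input as ``(M + M.T) / 2`` first to
suppress asymmetric floating-point residue. Inputs whose smallest eigenvalue
falls below a relative positivity floor are rejected rather than repaired:
silent repair hides upstream covariance-estimation bugs (shrinkage is the
caller's job, see :mod:`farka.alignment`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SPDError",
    "MeanSpec",
    "sym_eig",
    "sym_log",
    "sym_exp",
    "sym_power",
    "riemannian_distance",
    "mean_spd",
]

#: relative floor under the largest eigenvalue below which a matrix is
#: rejected as not positive definite
EPS_SPD_RATIO = 1e-10


class SPDError(ValueError):
    """Raised when an input violates the SPD contract."""


class ConvergenceWarning(UserWarning):
    """Karcher-mean fixed point hit its iteration cap before converging."""


@dataclass(frozen=True)
class MeanSpec:
    """Which matrix mean to compute and how hard to try.

    Parameters
    ----------
    space:
        ``"riemannian"`` (Karcher mean), ``"log_euclidean"``, or
        ``"euclidean"`` (arithmetic mean).
    tol:
        Convergence tolerance on the Frobenius norm of the mean tangent
        update (Riemannian mean only).
    max_iter:
        Iteration cap for the Karcher fixed point.
    """

    space: str = "riemannian"
    tol: float = 1e-8
    max_iter: int = 50

    _SPACES = ("riemannian", "log_euclidean", "euclidean")

    def __post_init__(self) -> None:
        if self.space not in self._SPACES:
            raise ValueError(f"space must be one of {self._SPACES}, got {self.space!r}")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _symmetrize(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise SPDError(f"expected a square matrix, got shape {M.shape}")
    return (M + M.T) / 2.0


def sym_eig(M: np.ndarray, *, require_spd: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetrized matrix.

    Returns ``(eigenvalues, eigenvectors)`` in ascending eigenvalue order.
    With ``require_spd`` the smallest eigenvalue must exceed the relative
    positivity floor ``EPS_SPD_RATIO * max(eigenvalue)``.
    """
    S = _symmetrize(M)
    w, U = np.linalg.eigh(S)
    if require_spd:
        floor = EPS_SPD_RATIO * max(w[-1], 0.0)
        if w[0] <= floor:
            raise SPDError(
                f"matrix is not positive definite: smallest eigenvalue "
                f"{w[0]:.3e} <= floor {floor:.3e}"
            )
    return w, U


def _apply_spectral(M: np.ndarray, fn) -> np.ndarray:
    w, U = sym_eig(M)
    return (U * fn(w)) @ U.T


def sym_log(M: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix (symmetric result)."""
    return _apply_spectral(M, np.log)


def sym_exp(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    S = _symmetrize(S)
    w, U = np.linalg.eigh(S)
    return (U * np.exp(w)) @ U.T


def sym_power(M: np.ndarray, p: float) -> np.ndarray:
    """Fractional power ``M**p`` of an SPD matrix via its eigensystem.

    ``sym_power(M, -0.5)`` is the whitening transform: ``W @ M @ W = I``.
    """
    if p == 0:
        raise ValueError("p must be nonzero")
    return _apply_spectral(M, lambda w: np.power(w, p))


def riemannian_distance(M1: np.ndarray, M2: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    Computed as ``sqrt(sum(log(lambda_i)^2))`` over the generalized
    eigenvalues of ``(M2, M1)``, which equals the Frobenius norm of
    ``log(M1^{-1/2} M2 M1^{-1/2})``. Symmetric in its arguments, zero iff
    ``M1 == M2``, and invariant under congruence ``M -> A M A.T``.
    """
    S1 = _symmetrize(M1)
    S2 = _symmetrize(M2)
    if S1.shape != S2.shape:
        raise SPDError(f"dimension mismatch: {S1.shape} vs {S2.shape}")
    # validate SPD on both (eigh(B, A) requires A SPD anyway)
    sym_eig(S1)
    sym_eig(S2)
    w = scipy.linalg.eigh(S2, S1, eigvals_only=True)
    if np.any(w <= 0):
        raise SPDError("generalized eigenvalues not positive; inputs not SPD")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def _check_stack(matrices) -> np.ndarray:
    A = np.asarray(matrices, dtype=float)
    if A.ndim != 3 or A.shape[0] == 0:
        raise ValueError("need a non-empty list of square matrices")
    if A.shape[1] != A.shape[2]:
        raise SPDError("matrices must be square with a common dimension")
    return A


def mean_spd(matrices, spec: MeanSpec | None = None) -> np.ndarray:
    """Mean of a set of SPD matrices in the requested space.

    euclidean
        Arithmetic mean.
    log_euclidean
        ``exp(mean(log(M_i)))``.
    riemannian
        Karcher mean by the fixed-point iteration
        ``N <- N^{1/2} exp(mean_i log(N^{-1/2} M_i N^{-1/2})) N^{1/2}``,
        initialized at the arithmetic mean; converged when the Frobenius
        norm of the mean tangent update drops below ``spec.tol``. Emits a
        :class:`ConvergenceWarning` if ``spec.max_iter`` is reached first.
    """
    spec = spec or MeanSpec()
    A = _check_stack(matrices)

    if spec.space == "euclidean":
        return A.mean(axis=0)
    if spec.space == "log_euclidean":
        logs = np.stack([sym_log(M) for M in A])
        return sym_exp(logs.mean(axis=0))

    N = A.mean(axis=0)
    for _ in range(spec.max_iter):
        N_isqrt = sym_power(N, -0.5)
        N_sqrt = sym_power(N, 0.5)
        T = np.stack([sym_log(N_isqrt @ M @ N_isqrt) for M in A]).mean(axis=0)
        if np.linalg.norm(T, "fro") < spec.tol:
            return N
        N = N_sqrt @ sym_exp(T) @ N_sqrt
    warnings.warn(
        f"Karcher mean did not converge in {spec.max_iter} iterations",
        ConvergenceWarning,
        stacklevel=2,
    )
    return N
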