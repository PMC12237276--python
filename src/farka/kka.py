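"""Knowledge Kernel Adaptation: learning a field-agnostic kernel.

Given tangent-space feature sets for a labelled source field and an
unlabelled target field, KKA builds a shared kernel in four steps:

1. eigendecompose the target kernel ``K_t = phi_t Delta_t phi_t.T`` and
   retain the leading eigenpairs;
2. extrapolate the target eigenvectors to the source rows by the Nystrom
   formula ``phi_s_tilde = K_cross phi_t Delta_t^{-1}`` (the extrapolated
   columns are deliberately NOT re-orthonormalized);
3. re-fit the spectrum: find nonnegative eigenvalues ``sigma`` minimizing
   ``|| phi_s_tilde diag(sigma) phi_s_tilde.T - K_s ||_F^2`` subject to the
   power-law decay constraint ``sigma_i >= mu * sigma_{i+1}`` (``mu >= 1``),
   a convex quadratic program;
4. assemble the field-agnostic kernel ``K_union = Phi Delta* Phi.T`` with
   ``Phi`` the extrapolated source eigenvectors stacked above the target
   eigenvectors — symmetric PSD by construction.

The QP is solved exactly: the constraint cone ``sigma_i >= mu sigma_{i+1}
>= 0`` is reparameterized as ``sigma = L t`` with ``t >= 0`` (``L`` unit
upper-triangular in the geometric progression of ``mu``), reducing the
problem to nonnegative least squares on the Cholesky factor of the
quadratic form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
from sklearn.metrics.pairwise import laplacian_kernel, linear_kernel, rbf_kernel

__all__ = [
    "KernelSpec",
    "EigenSystem",
    "KernelBundle",
    "kernel_matrix",
    "default_gamma",
    "target_eigensystem",
    "nystrom_extrapolate",
    "solve_spectrum_qp",
    "build_union_kernel",
    "kka_adapt",
]

_FAMILIES = ("rbf", "linear", "laplacian")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and bandwidth.

    rbf:        k(x, y) = exp(-gamma ||x - y||^2)
    linear:     k(x, y) = x.T y
    laplacian:  k(x, y) = exp(-gamma ||x - y||_1)

    ``gamma=None`` defers to :func:`default_gamma` at evaluation sites that
    have access to the data; ``gamma`` is ignored for the linear kernel.
    """

    family: str = "rbf"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass
class EigenSystem:
    """Retained eigenpairs of the target kernel plus Nystrom extrapolation.

    ``phi_t`` (n_t x r) has orthonormal columns and ``delta_t`` (r,) is
    strictly positive, descending. ``phi_s_tilde`` (n_s x r) is filled by
    :func:`nystrom_extrapolate` and is generally not orthonormal.
    """

    phi_t: np.ndarray
    delta_t: np.ndarray
    phi_s_tilde: np.ndarray | None = None

    @property
    def r(self) -> int:
        return self.phi_t.shape[1]


@dataclass
class KernelBundle:
    """All kernel matrices of one source-to-target adaptation."""

    K_s: np.ndarray
    K_t: np.ndarray
    K_cross: np.ndarray
    eigensystem: EigenSystem
    delta_star: np.ndarray
    K_s_tilde: np.ndarray
    K_union: np.ndarray
    mu: float
    spec: KernelSpec = field(default_factory=KernelSpec)

    @property
    def n_s(self) -> int:
        return self.K_s.shape[0]

    @property
    def n_t(self) -> int:
        return self.K_t.shape[0]


def default_gamma(X: np.ndarray) -> float:
    """Bandwidth ``1 / (n_features * var(X))``, the standard scale heuristic."""
    X = np.asarray(X, dtype=float)
    v = X.var()
    if v <= 0:
        v = 1.0
    return 1.0 / (X.shape[1] * v)


def kernel_matrix(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix ``K[i, j] = k(X[i], Y[j])`` for the chosen family."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.family == "linear":
        return linear_kernel(X, Y)
    gamma = spec.gamma if spec.gamma is not None else default_gamma(np.vstack([X, Y]))
    if spec.family == "rbf":
        return rbf_kernel(X, Y, gamma=gamma)
    return laplacian_kernel(X, Y, gamma=gamma)


def _fix_sign(U: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: first nonzero component positive."""
    U = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            U[:, j] = -col
    return U


def target_eigensystem(
    K_t: np.ndarray, r_max: int | None = None, floor_ratio: float = 1e-8
) -> EigenSystem:
    """Leading eigenpairs of the target kernel matrix.

    Retains the top ``r <= r_max`` eigenpairs whose eigenvalue is at least
    ``floor_ratio`` times the largest; near-zero eigenvalues must be dropped
    here because the Nystrom step divides by them.
    """
    K_t = np.asarray(K_t, dtype=float)
    n = K_t.shape[0]
    if r_max is None:
        r_max = n
    w, U = np.linalg.eigh((K_t + K_t.T) / 2.0)
    w, U = w[::-1], U[:, ::-1]  # descending
    if w[0] <= 0:
        raise ValueError("degenerate kernel: no positive eigenvalues")
    keep = w >= floor_ratio * w[0]
    keep[min(r_max, n):] = False
    r = int(np.count_nonzero(keep))
    if r == 0:
        raise ValueError("degenerate kernel: all eigenvalues below floor")
    return EigenSystem(phi_t=_fix_sign(U[:, :r]), delta_t=w[:r])


def nystrom_extrapolate(K_cross: np.ndarray, es: EigenSystem) -> EigenSystem:
    """Extrapolate target eigenvectors to the source rows.

    ``phi_s_tilde = K_cross phi_t Delta_t^{-1}``; when the source rows
    coincide with the target rows (``K_cross == K_t``) this reproduces
    ``phi_t`` exactly. No renormalization is applied.
    """
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.ndim != 2 or K_cross.shape[1] != es.phi_t.shape[0]:
        raise ValueError(
            f"K_cross must be (n_s, n_t={es.phi_t.shape[0]}), got {K_cross.shape}"
        )
    phi_s = K_cross @ es.phi_t / es.delta_t[None, :]
    return EigenSystem(phi_t=es.phi_t, delta_t=es.delta_t, phi_s_tilde=phi_s)


def _qp_form(es: EigenSystem, K_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic-form expansion of ``||A diag(s) A.T - K_s||_F^2``.

    With ``a_i`` the columns of ``A = phi_s_tilde``: ``G[i, j] =
    (a_i.T a_j)^2`` and ``h[i] = a_i.T K_s a_i``; the objective is
    ``s.T G s - 2 h.T s`` up to a constant. ``G`` is the Hadamard square of
    a Gram matrix, hence PSD; a small ridge keeps the Cholesky factor well
    defined.
    """
    A = es.phi_s_tilde
    inner = A.T @ A
    G = inner**2
    G = (G + G.T) / 2.0 + 1e-10 * np.eye(G.shape[0])
    h = np.einsum("ni,nm,mi->i", A, K_s, A)
    return G, h


def solve_spectrum_qp(es: EigenSystem, K_s: np.ndarray, mu: float = 1.0) -> np.ndarray:
    """Optimal power-law spectrum for the reconstructed source kernel.

    Minimizes ``||phi_s_tilde diag(sigma) phi_s_tilde.T - K_s||_F^2``
    subject to ``sigma_i >= mu * sigma_{i+1}`` and ``sigma >= 0``. Solved
    exactly by the cone substitution ``sigma = L t`` (``t >= 0``,
    ``L[i, j] = mu**(j - i)`` for ``j >= i``) followed by nonnegative least
    squares on the Cholesky-factored objective.
    """
    if mu < 1:
        raise ValueError("mu must be >= 1")
    if es.phi_s_tilde is None:
        raise ValueError("run nystrom_extrapolate first")
    K_s = np.asarray(K_s, dtype=float)
    r = es.r
    if r == 0 or es.phi_s_tilde.shape[0] == 0:
        return np.zeros(r)

    G, h = _qp_form(es, K_s)
    # sigma = L t with t >= 0 sweeps exactly the feasible cone; exponents are
    # capped so mu**e stays finite — capped columns force t_j = 0 at the
    # optimum anyway, since they would blow up the reconstruction error
    j = np.arange(r)
    expo = np.clip(j[None, :] - j[:, None], 0, None).astype(float)
    if mu > 1.0:
        expo = np.minimum(expo, 250.0 / np.log10(mu))
    L = np.triu(np.power(float(mu), expo))
    R = np.linalg.cholesky(G).T  # G = R.T R
    b = scipy.linalg.solve_triangular(R, h, trans="T", lower=False)
    M = R @ L
    # column scaling keeps NNLS well conditioned when mu**r is huge
    scale = np.linalg.norm(M, axis=0)
    scale[scale == 0] = 1.0
    u, _ = scipy.optimize.nnls(M / scale, b)
    t = u / scale
    sigma = L @ t
    return np.maximum(sigma, 0.0)


def build_union_kernel(es: EigenSystem, delta_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reconstructed source kernel and the field-agnostic union kernel.

    ``K_s_tilde = phi_s_tilde diag(Delta*) phi_s_tilde.T`` and
    ``K_union = Phi diag(Delta*) Phi.T`` with ``Phi = [phi_s_tilde;
    phi_t]``; the source block of ``K_union`` equals ``K_s_tilde`` exactly
    and the whole matrix is PSD because ``Delta* >= 0``.
    """
    if es.phi_s_tilde is None:
        raise ValueError("run nystrom_extrapolate first")
    delta_star = np.asarray(delta_star, dtype=float)
    if delta_star.shape != (es.r,):
        raise ValueError(f"delta_star must have shape ({es.r},)")
    Phi = np.vstack([es.phi_s_tilde, es.phi_t])
    scaled = Phi * delta_star[None, :]
    K_union = scaled @ Phi.T
    K_union = (K_union + K_union.T) / 2.0
    n_s = es.phi_s_tilde.shape[0]
    K_s_tilde = K_union[:n_s, :n_s]
    return K_s_tilde, K_union


def kka_adapt(
    F_s: np.ndarray,
    F_t: np.ndarray,
    spec: KernelSpec | None = None,
    mu: float = 1.5,
    r_max: int | None = None,
    floor_ratio: float = 1e-8,
) -> KernelBundle:
    """Run the full adaptation chain on raw feature rows."""
    spec = spec or KernelSpec()
    F_s = np.atleast_2d(np.asarray(F_s, dtype=float))
    F_t = np.atleast_2d(np.asarray(F_t, dtype=float))
    if spec.gamma is None and spec.family != "linear":
        spec = KernelSpec(spec.family, default_gamma(np.vstack([F_s, F_t])))
    K_s = kernel_matrix(F_s, F_s, spec)
    K_t = kernel_matrix(F_t, F_t, spec)
    K_cross = kernel_matrix(F_s, F_t, spec)
    if r_max is None:
        r_max = min(F_s.shape[0], F_t.shape[0])
    es = target_eigensystem(K_t, r_max=r_max, floor_ratio=floor_ratio)
    es = nystrom_extrapolate(K_cross, es)
    delta_star = solve_spectrum_qp(es, K_s, mu=mu)
    K_s_tilde, K_union = build_union_kernel(es, delta_star)
    return KernelBundle(
        K_s=K_s,
        K_t=K_t,
        K_cross=K_cross,
        eigensystem=es,
        delta_star=delta_star,
        K_s_tilde=K_s_tilde,
        K_union=K_union,
        mu=mu,
        spec=spec,
    )
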