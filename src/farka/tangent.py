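"""Tangent-space mapping: SPD matrices to Euclidean feature vectors.

An aligned covariance matrix ``Q`` is mapped to
``upper(log(Q_ref Q Q_ref))`` with ``Q_ref`` the inverse square root of the
reference point. After per-subject alignment the natural common reference is
the identity, which makes features from different subjects directly
comparable — the property the kernel-adaptation stage relies on.

With the ``sqrt2_offdiag`` weighting the off-diagonal entries of the upper
triangle are scaled by sqrt(2), so the Euclidean norm of the feature vector
equals the Frobenius norm of the log-matrix, and hence (at the identity
reference) the Riemannian distance from the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import SPDSet
from .spd import MeanSpec, mean_spd, sym_log, sym_power

__all__ = ["TangentFeatures", "upper_vectorize", "tangent_map"]

_WEIGHTINGS = ("sqrt2_offdiag", "unweighted")


@dataclass
class TangentFeatures:
    """Per-epoch tangent-space vectors for one subject.

    ``vectors`` has shape ``(n, ch*(ch+1)/2)``; the vector of the reference
    point itself is zero.
    """

    subject_id: str
    vectors: np.ndarray
    labels: np.ndarray
    reference: np.ndarray
    weighting: str = "sqrt2_offdiag"

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def upper_vectorize(S: np.ndarray, weighting: str = "sqrt2_offdiag") -> np.ndarray:
    """Row-major upper triangle (with diagonal) of a symmetric matrix.

    ``sqrt2_offdiag`` multiplies off-diagonal entries by sqrt(2) so that
    ``norm(v) == norm(S, 'fro')``.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if np.max(np.abs(S - S.T)) > 1e-8:
        raise ValueError("S is not symmetric within 1e-8")
    if weighting not in _WEIGHTINGS:
        raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
    iu = np.triu_indices(S.shape[0])
    v = S[iu].copy()
    if weighting == "sqrt2_offdiag":
        v[iu[0] != iu[1]] *= np.sqrt(2.0)
    return v


def tangent_map(
    s: SPDSet,
    reference: np.ndarray | str = "identity",
    weighting: str = "sqrt2_offdiag",
) -> TangentFeatures:
    """Project a subject's SPD set onto the tangent space at ``reference``.

    ``reference`` may be an explicit SPD matrix, ``"identity"``, or
    ``"set_mean"`` (the Riemannian mean of the set). Warns if the set has
    not been aligned — the identity reference is only geometrically natural
    after alignment.
    """
    if not s.aligned:
        warnings.warn(
            f"tangent_map on unaligned set for subject {s.subject_id!r}; "
            "features of different subjects may not be comparable",
            UserWarning,
            stacklevel=2,
        )
    ch = s.ch
    if isinstance(reference, str):
        if reference == "identity":
            ref = np.eye(ch)
        elif reference == "set_mean":
            ref = mean_spd(s.matrices, MeanSpec(space="riemannian"))
        else:
            raise ValueError(f"unknown reference {reference!r}")
    else:
        ref = np.asarray(reference, dtype=float)

    identity_ref = np.allclose(ref, np.eye(ch), atol=1e-12)
    if identity_ref:
        logs = [sym_log(Q) for Q in s.matrices]
    else:
        W = sym_power(ref, -0.5)
        logs = [sym_log(W @ Q @ W) for Q in s.matrices]
    vectors = np.stack([upper_vectorize(L, weighting) for L in logs])
    return TangentFeatures(
        subject_id=s.subject_id,
        vectors=vectors,
        labels=s.labels.copy(),
        reference=ref,
        weighting=weighting,
    )
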