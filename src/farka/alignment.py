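"""Per-epoch covariance estimation and per-subject Riemannian alignment.

Each subject's epoched EEG is reduced to a set of channel covariance
matrices; the set is then whitened by the inverse square root of its own
centroid so that every subject's centroid lands at the identity. This
removes the subject-specific (invertible) spatial mixing that dominates
cross-subject distribution shift, and is done unsupervised — over all of a
subject's epochs regardless of class label, before any source/target split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spd import ConvergenceWarning, MeanSpec, mean_spd, sym_eig, sym_power

__all__ = ["EpochSet", "SPDSet", "estimate_covariances", "align_subject"]


@dataclass
class EpochSet:
    """Labelled epochs for one subject.

    ``epochs`` has shape ``(n_epochs, ch, T)``; ``labels`` holds the two
    integer class labels; ``sample_rate`` is in Hz.
    """

    subject_id: str
    epochs: np.ndarray
    labels: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must have shape (n_epochs, ch, T)")
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels and epochs length mismatch")
        if self.epochs.shape[2] < 1:
            raise ValueError("epochs must have at least one sample")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def ch(self) -> int:
        return self.epochs.shape[1]

    @property
    def T(self) -> int:
        return self.epochs.shape[2]


@dataclass
class SPDSet:
    """A subject's covariance matrices, pre- or post-alignment.

    ``matrices`` has shape ``(n, ch, ch)``. When ``aligned`` is true the
    centroid of the set in ``alignment_space`` is the identity (within
    numerical tolerance).
    """

    subject_id: str
    matrices: np.ndarray
    labels: np.ndarray
    aligned: bool = False
    alignment_space: MeanSpec | None = None
    warnings_: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (n, ch, ch)")
        if len(self.labels) != len(self.matrices):
            raise ValueError("labels and matrices length mismatch")

    @property
    def n(self) -> int:
        return self.matrices.shape[0]

    @property
    def ch(self) -> int:
        return self.matrices.shape[1]


def estimate_covariances(
    e: EpochSet, *, normalize: bool = True, shrinkage: float = 0.0
) -> SPDSet:
    """Sample covariance of each epoch, optionally shrunk toward a scaled identity.

    For epoch ``X`` (ch x T): ``M = X X.T / T`` when ``normalize``, else
    ``X X.T``; then ``M <- (1 - shrinkage) M + shrinkage (tr(M)/ch) I``.
    Epochs with fewer samples than channels are rank deficient and rejected
    unless ``shrinkage > 0``.
    """
    if not 0 <= shrinkage < 1:
        raise ValueError("shrinkage must be in [0, 1)")
    if e.T < e.ch and shrinkage == 0.0:
        raise ValueError(
            f"epochs are rank deficient (T={e.T} < ch={e.ch}); "
            "set shrinkage > 0 to regularize"
        )
    ch = e.ch
    mats = np.einsum("nct,ndt->ncd", e.epochs, e.epochs)
    if normalize:
        mats /= e.T
    if shrinkage > 0:
        traces = np.trace(mats, axis1=1, axis2=2)
        eye = np.eye(ch)
        mats = (1 - shrinkage) * mats + shrinkage * (traces / ch)[:, None, None] * eye
    for M in mats:  # reject non-SPD estimates up front
        sym_eig(M)
    return SPDSet(subject_id=e.subject_id, matrices=mats, labels=e.labels.copy())


def align_subject(s: SPDSet, spec: MeanSpec | None = None) -> SPDSet:
    """Whiten a subject's covariance set so its centroid becomes the identity.

    Computes the centroid ``N`` of all the subject's matrices in
    ``spec.space`` and returns ``Q_i = N^{-1/2} M_i N^{-1/2}``. Labels pass
    through untouched. Centroid non-convergence is recorded in the result's
    ``warnings_`` list rather than raised.
    """
    if s.aligned:
        raise ValueError(f"subject {s.subject_id!r} is already aligned")
    spec = spec or MeanSpec()
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        N = mean_spd(s.matrices, spec)
    notes.extend(str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning))
    W = sym_power(N, -0.5)
    aligned = np.einsum("ij,njk,kl->nil", W, s.matrices, W)
    aligned = (aligned + aligned.transpose(0, 2, 1)) / 2.0
    return SPDSet(
        subject_id=s.subject_id,
        matrices=aligned,
        labels=s.labels.copy(),
        aligned=True,
        alignment_space=spec,
        warnings_=notes,
    )
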