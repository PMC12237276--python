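"""The FARKA estimator: fit on a labelled source field, predict a target field.

Ties together kernel construction, knowledge kernel adaptation, and a
support vector machine operated on the precomputed (adapted) Gram matrix.
The SVM is trained on the reconstructed source block of the field-agnostic
kernel by default, and target predictions come from the target-by-source
cross block applied to the learned dual coefficients — no target labels are
ever consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .kka import KernelBundle, KernelSpec, kka_adapt
from .tangent import TangentFeatures

__all__ = ["FarkaParams", "FarkaModel", "fit", "predict", "fit_predict", "accuracy"]


@dataclass(frozen=True)
class FarkaParams:
    """Hyperparameters of the full estimator.

    mu:
        Damping factor of the spectrum QP (>= 1); larger values force a
        faster geometric decay of the learned eigenvalues.
    eta:
        SVM penalty (the usual C). The method is reported to be insensitive
        to it over 1..15; default 10.
    kernel:
        Kernel family/bandwidth used for all Gram matrices.
    r_max:
        Cap on the retained eigensystem rank (default min(n_s, n_t)).
    train_on:
        ``"reconstructed"`` trains the SVM on the adapted source block
        ``K_s_tilde``; ``"actual"`` uses the raw source kernel ``K_s``.
    """

    kernel: KernelSpec = field(default_factory=KernelSpec)
    mu: float = 1.5
    eta: float = 10.0
    r_max: int | None = None
    train_on: str = "reconstructed"

    def __post_init__(self) -> None:
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if self.train_on not in ("reconstructed", "actual"):
            raise ValueError("train_on must be 'reconstructed' or 'actual'")


@dataclass
class FarkaModel:
    """A fitted estimator: SVM dual solution plus the adapted kernels."""

    svm: SVC
    bundle: KernelBundle
    source_features: np.ndarray
    classes: tuple[int, int]  # (negative, positive) in input label space
    params: FarkaParams

    @property
    def n_dual(self) -> int:
        return len(self.svm.dual_coef_[0])


def _as_features(x) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(x, TangentFeatures):
        return x.vectors, x.labels
    return np.atleast_2d(np.asarray(x, dtype=float)), None


def _clip_psd(K: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues so the SVM sees a PSD Gram matrix."""
    w, U = np.linalg.eigh((K + K.T) / 2.0)
    if w[0] >= 0:
        return K
    return (U * np.maximum(w, 0.0)) @ U.T


def fit(source, target, params: FarkaParams | None = None,
        source_labels: np.ndarray | None = None) -> FarkaModel:
    """Fit the estimator on labelled source features and unlabelled target features.

    ``source`` and ``target`` are :class:`~farka.tangent.TangentFeatures`
    or plain feature arrays (then ``source_labels`` is required). The source
    must contain exactly two classes; the lexicographically smaller label is
    mapped to the negative class.
    """
    params = params or FarkaParams()
    F_s, labels = _as_features(source)
    if source_labels is not None:
        labels = np.asarray(source_labels, dtype=int)
    if labels is None:
        raise ValueError("source labels are required")
    F_t, _ = _as_features(target)
    if F_t.shape[0] == 0:
        raise ValueError("target field is empty")
    if F_s.shape[1] != F_t.shape[1]:
        raise ValueError("source/target feature dimension mismatch")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"source must contain exactly 2 classes, got {classes}")

    bundle = kka_adapt(F_s, F_t, spec=params.kernel, mu=params.mu, r_max=params.r_max)
    K_train = bundle.K_s_tilde if params.train_on == "reconstructed" else bundle.K_s
    y = np.where(labels == classes[0], -1, 1)
    svm = SVC(kernel="precomputed", C=params.eta)
    svm.fit(_clip_psd(K_train), y)
    return FarkaModel(
        svm=svm,
        bundle=bundle,
        source_features=F_s,
        classes=(int(classes[0]), int(classes[1])),
        params=params,
    )


def decision_function(model: FarkaModel) -> np.ndarray:
    """SVM decision values for every target epoch.

    Uses the target-rows-by-source-columns block of the field-agnostic
    kernel: ``K_ts = phi_t Delta* phi_s_tilde.T``.
    """
    n_s = model.bundle.n_s
    K_ts = model.bundle.K_union[n_s:, :n_s]
    return model.svm.decision_function(K_ts)


def predict(model: FarkaModel) -> np.ndarray:
    """Predicted class labels for the target field (ties go to the positive class)."""
    d = decision_function(model)
    neg, pos = model.classes
    return np.where(d >= 0, pos, neg)


def fit_predict(source, target, params: FarkaParams | None = None,
                source_labels: np.ndarray | None = None) -> np.ndarray:
    """Convenience: fit on the source field and predict the target field."""
    return predict(fit(source, target, params, source_labels))


def accuracy(predicted, truth) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch between predictions and truth")
    return float(np.mean(predicted == truth))
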