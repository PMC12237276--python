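"""Synthetic multi-subject motor-imagery EEG and degradation operators.

The generator emulates the statistical structure the pipeline consumes:
event-related desynchronization (ERD) appears as class-dependent variance
suppression in disjoint channel groups, and cross-subject variability as a
per-subject invertible spatial mixing ``A_c = I + eps * G`` applied by
congruence to the class covariances. Epochs are zero-mean Gaussian — the
pipeline only looks at second-order statistics, so no oscillatory content is
needed. Physiological realism (1/f spectra, artifacts, within-epoch
nonstationarity) is deliberately out of scope.

Degradation operators mirror common robustness probes: global amplitude
attenuation, additive white Gaussian noise at a target SNR, and the
zero-phase FIR band-pass used to isolate the mu/beta rhythms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .alignment import EpochSet

__all__ = ["PopulationSpec", "make_population", "attenuate", "add_awgn", "bandpass"]


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions for one synthetic population.

    Defaults define a regime where within-subject classification is easy
    (accuracy > 0.9) but cross-subject transfer degrades without alignment:
    8 channels, 512 samples/epoch, 40 epochs per class for each of 5
    subjects, ERD variance suppression 0.5 in two disjoint channel pairs,
    and mixing strength 0.3.
    """

    n_subjects: int = 5
    n_epochs_per_class: int = 40
    ch: int = 8
    T: int = 512
    erd_channels: tuple[tuple[int, ...], tuple[int, ...]] = ((0, 1), (2, 3))
    erd_depth: float = 0.5
    subject_mixing_strength: float = 0.3
    subject_noise: float = 0.0
    sample_rate: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = (set(self.erd_channels[0]), set(self.erd_channels[1]))
        if a & b:
            raise ValueError("erd channel sets must be disjoint")
        if max(a | b, default=-1) >= self.ch:
            raise ValueError("erd channel index out of range")
        if self.n_epochs_per_class < 1:
            raise ValueError("n_epochs_per_class must be >= 1")
        if self.ch < 2:
            raise ValueError("ch must be >= 2")
        if not 0 < self.erd_depth <= 1:
            raise ValueError("erd_depth must be in (0, 1]")
        if self.subject_mixing_strength < 0 or self.subject_noise < 0:
            raise ValueError("mixing strength and noise must be >= 0")


def _class_covariances(spec: PopulationSpec) -> list[np.ndarray]:
    covs = []
    for k in range(2):
        d = np.ones(spec.ch)
        d[list(spec.erd_channels[k])] *= spec.erd_depth
        covs.append(np.diag(d))
    return covs


def _subject_mixing(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """A_c = I + (eps/sqrt(ch)) G, resampled if badly conditioned."""
    eps = spec.subject_mixing_strength
    if eps == 0:
        return np.eye(spec.ch)
    for _ in range(100):
        G = rng.standard_normal((spec.ch, spec.ch))
        A = np.eye(spec.ch) + (eps / np.sqrt(spec.ch)) * G
        if np.linalg.cond(A) < 1e6:
            return A
    raise RuntimeError("could not draw a well-conditioned mixing matrix")


def make_population(spec: PopulationSpec) -> list[EpochSet]:
    """Draw one multi-subject population; deterministic given ``spec.seed``.

    Per subject ``c`` and class ``k`` the epoch covariance is
    ``A_c Sigma_k A_c.T + subject_noise * I`` with ``Sigma_k`` the shared
    ERD-structured class covariance; labels are balanced in {1, 2}.
    """
    rng = np.random.default_rng(spec.seed)
    base = _class_covariances(spec)
    subjects = []
    n_per = spec.n_epochs_per_class
    for c in range(spec.n_subjects):
        A = _subject_mixing(spec, rng)
        epochs = np.empty((2 * n_per, spec.ch, spec.T))
        labels = np.empty(2 * n_per, dtype=int)
        for k in range(2):
            cov = A @ base[k] @ A.T + spec.subject_noise * np.eye(spec.ch)
            C = np.linalg.cholesky(cov)
            z = rng.standard_normal((n_per, spec.ch, spec.T))
            epochs[k * n_per:(k + 1) * n_per] = np.einsum("ij,njt->nit", C, z)
            labels[k * n_per:(k + 1) * n_per] = k + 1
        # interleave classes so any contiguous split stays balanced
        order = np.argsort(np.tile(np.arange(n_per), 2), kind="stable")
        subjects.append(
            EpochSet(
                subject_id=f"S{c + 1:02d}",
                epochs=epochs[order],
                labels=labels[order],
                sample_rate=spec.sample_rate,
            )
        )
    return subjects


def attenuate(e: EpochSet, af: float) -> EpochSet:
    """Scale every epoch by a global attenuation factor in (0, 1]."""
    if not af > 0:
        raise ValueError("attenuation factor must be positive")
    return EpochSet(e.subject_id, e.epochs * af, e.labels.copy(), e.sample_rate)


def add_awgn(e: EpochSet, snr_db: float, seed: int | None = None) -> EpochSet:
    """Add white Gaussian noise at a target signal-to-noise ratio.

    ``SNR = 10 log10(P_signal / P_noise)`` with ``P_signal`` the mean
    squared amplitude over all of the subject's epochs/channels/samples;
    the noise variance is ``P_signal / 10**(snr_db / 10)``.
    """
    if e.n_epochs == 0:
        raise ValueError("empty epoch set")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    rng = np.random.default_rng(seed)
    p_signal = float(np.mean(e.epochs**2))
    noise_var = p_signal / 10 ** (snr_db / 10)
    noise = rng.standard_normal(e.epochs.shape) * np.sqrt(noise_var)
    return EpochSet(e.subject_id, e.epochs + noise, e.labels.copy(), e.sample_rate)


def bandpass(e: EpochSet, lo_hz: float, hi_hz: float, order: int = 50) -> EpochSet:
    """Zero-phase FIR band-pass (Hamming window) over every epoch.

    Applied forward-backward (``filtfilt``) so the pass band is attenuated
    twice in magnitude but the phase response is exactly zero.
    """
    nyq = e.sample_rate / 2.0
    if not 0 < lo_hz < hi_hz < nyq:
        raise ValueError(f"band edges must satisfy 0 < lo < hi < {nyq} Hz")
    taps = scipy.signal.firwin(
        order + 1, [lo_hz, hi_hz], pass_zero=False, fs=e.sample_rate, window="hamming"
    )
    padlen = min(3 * (len(taps) - 1), e.T - 1)  # default padding can exceed short epochs
    filtered = scipy.signal.filtfilt(taps, [1.0], e.epochs, axis=-1, padlen=padlen)
    return EpochSet(e.subject_id, filtered, e.labels.copy(), e.sample_rate)
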