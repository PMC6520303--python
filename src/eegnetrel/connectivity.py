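"""Phase-based functional connectivity: PLI and debiased weighted PLI.

Both indices quantify the asymmetry of the instantaneous phase-difference
distribution between two band-limited signals, obtained from the Hilbert
analytic signal. Volume conduction — one source seen by several sensors —
produces exactly zero phase difference and is therefore nulled by design.

PLI (Stam's phase lag index)::

    PLI = | < sign( sin(Δφ(t_k)) ) > |,   k = 1 … N per epoch

with <> the mean over time points; 0 for a symmetric phase-difference
distribution (including zero lag), 1 for a constant-sign lag.

dwPLI (Vinck's debiased weighted PLI-square) weights each time point by the
magnitude of the imaginary cross-spectrum, I_k = Im(a_k conj(b_k)), and
removes the finite-sample bias::

    dwPLI = ( (Σ I_k)² − Σ I_k² ) / ( (Σ |I_k|)² − Σ I_k² )

equivalently a ratio of sums over distinct pairs j ≠ k of I_j·I_k against
|I_j|·|I_k|. The debiasing can push the estimate below zero, so the range
is [−1, 1]; under independence its expectation is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import BandEpochSet

__all__ = [
    "ConnectivityMatrix",
    "instantaneous_phase",
    "analytic_signal",
    "pli_pair",
    "dwpli_pair",
    "connectivity_matrix",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel × channel connectivity for one subject-session-band."""

    subject_id: str
    session_id: int
    band_name: str
    method: str  # "pli" | "dwpli"
    values: np.ndarray
    channel_labels: list[str]
    n_epochs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if self.method == "pli" and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("PLI values must lie in [0, 1]")
        if self.method == "dwpli" and (v.min() < -1 - 1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("dwPLI values must lie in [-1, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]

    def edge_labels(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n_channels, k=1)
        return [(self.channel_labels[i], self.channel_labels[j])
                for i, j in zip(*iu)]


def analytic_signal(epoch: np.ndarray) -> np.ndarray:
    """Hilbert analytic signal of a channels × samples (band-limited) epoch."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if np.any(np.ptp(epoch, axis=-1) == 0):
        raise ValueError("phase undefined for a constant/all-zero channel")
    return signal.hilbert(epoch, axis=-1)


def instantaneous_phase(epoch: np.ndarray) -> np.ndarray:
    """Instantaneous phase in (−π, π] of each channel of an epoch."""
    return np.angle(analytic_signal(epoch))


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI of two equal-length phase sequences."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase sequences differ in length")
    if phase_a.size == 0:
        raise ValueError("need at least one sample")
    return float(np.abs(np.mean(np.sign(np.sin(phase_a - phase_b)))))


def _dwpli_from_sums(s: np.ndarray, s2: np.ndarray, sa: np.ndarray,
                     scale: np.ndarray, warn: bool = True):
    """Debiased ratio from pooled sums; ``scale`` = N · max|a| · max|b|.

    A pair whose imaginary cross terms vanish (zero lag) has a zero
    denominator only up to round-off, so "zero" is judged relative to the
    attainable magnitude of Σ|I|.
    """
    num = s ** 2 - s2
    den = sa ** 2 - s2
    scalar = np.isscalar(num) or getattr(num, "ndim", 0) == 0
    num = np.atleast_1d(np.asarray(num, dtype=float))
    den = np.atleast_1d(np.asarray(den, dtype=float))
    tiny = np.atleast_1d(np.asarray(sa <= 8 * np.finfo(float).eps * scale))
    zero = (den == 0) | tiny
    if warn and zero.any():
        warnings.warn(
            "dwPLI denominator is zero (all imaginary cross-spectral terms "
            "vanish, e.g. an exactly zero-lag pair); defining the value as 0",
            stacklevel=3)
    out = np.zeros_like(num)
    out[~zero] = num[~zero] / den[~zero]
    return float(out[0]) if scalar else out


def dwpli_pair(analytic_a: np.ndarray, analytic_b: np.ndarray) -> float:
    """Debiased weighted PLI-square of two equal-length analytic signals.

    The per-sample imaginary cross-spectral terms of all supplied samples
    are pooled before the ratio; to aggregate epochs, concatenate them (or
    use :func:`connectivity_matrix`, which sums the per-epoch terms).
    """
    analytic_a = np.asarray(analytic_a)
    analytic_b = np.asarray(analytic_b)
    if analytic_a.shape != analytic_b.shape:
        raise ValueError("analytic signals differ in length")
    if analytic_a.size == 0:
        raise ValueError("need at least one sample")
    imag = np.imag(analytic_a * np.conj(analytic_b))
    scale = imag.size * np.abs(analytic_a).max() * np.abs(analytic_b).max()
    return _dwpli_from_sums(imag.sum(), (imag ** 2).sum(),
                            np.abs(imag).sum(), scale)


def _epoch_pli(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLI of one epoch's channels × samples phase array."""
    d = phases[:, None, :] - phases[None, :, :]
    return np.abs(np.mean(np.sign(np.sin(d)), axis=-1))


def connectivity_matrix(epochs: BandEpochSet, method: str = "pli",
                        pool_samples: bool = False) -> ConnectivityMatrix:
    """Connectivity matrix over all unordered channel pairs of an epoch set.

    PLI: by default the index is computed within each epoch (mean over its
    N samples, absolute value) and then averaged across epochs;
    ``pool_samples=True`` instead pools all samples of all epochs into one
    mean before the absolute value.

    dwPLI: the per-sample imaginary cross-spectral terms of all epochs are
    summed before the debiased ratio — this pooling across epochs is where
    the sample-size debiasing acts.
    """
    if method not in ("pli", "dwpli"):
        raise ValueError(f"unknown method {method!r}")
    E, C, _N = epochs.epochs.shape
    if E < 1 or C < 2:
        raise ValueError("need at least one epoch and two channels")
    try:
        if method == "pli":
            if pool_samples:
                acc = np.zeros((C, C))
                for e in range(E):
                    ph = instantaneous_phase(epochs.epochs[e])
                    d = ph[:, None, :] - ph[None, :, :]
                    acc += np.sign(np.sin(d)).sum(axis=-1)
                values = np.abs(acc) / (E * epochs.epochs.shape[2])
            else:
                values = np.zeros((C, C))
                for e in range(E):
                    values += _epoch_pli(instantaneous_phase(epochs.epochs[e]))
                values /= E
        else:
            s = np.zeros((C, C))
            s2 = np.zeros((C, C))
            sa = np.zeros((C, C))
            amax = np.zeros(C)
            for e in range(E):
                a = analytic_signal(epochs.epochs[e])
                imag = np.imag(a[:, None, :] * np.conj(a[None, :, :]))
                s += imag.sum(axis=-1)
                s2 += (imag ** 2).sum(axis=-1)
                sa += np.abs(imag).sum(axis=-1)
                amax = np.maximum(amax, np.abs(a).max(axis=-1))
            n_total = E * epochs.epochs.shape[2]
            scale = n_total * amax[:, None] * amax[None, :]
            # the diagonal's cross terms vanish identically; only warn on
            # genuine off-diagonal zero-lag pairs
            values = _dwpli_from_sums(s, s2, sa, scale, warn=False)
            off = ~np.eye(C, dtype=bool)
            if np.any((sa <= 8 * np.finfo(float).eps * scale)[off]):
                warnings.warn(
                    "dwPLI denominator is zero for at least one channel "
                    "pair (exactly zero-lag signals); value defined as 0",
                    stacklevel=2)
    except ValueError as err:
        raise ValueError(
            f"{epochs.subject_id} session {epochs.session_id} "
            f"band {epochs.band_name!r}: {err}") from err
    values = np.asarray(values, dtype=float)
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # symmetrize away float round-off
    return ConnectivityMatrix(
        subject_id=epochs.subject_id, session_id=epochs.session_id,
        band_name=epochs.band_name, method=method, values=values,
        channel_labels=list(epochs.channel_labels), n_epochs=E)
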