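"""Preprocessing: resampling, zero-phase filtering, artifact handling, epoching.

The pipeline mirrors common sensor-space EEG practice: downsample the raw
acquisition-rate signal, band-pass 0.1–70 Hz with a two-way (zero-phase,
forward–backward) Butterworth filter, detect clearly non-neurological
stretches (step discontinuities, high-variance segments) without deep
cleaning, drop channels that are mostly artifact — from *both* sessions of
a subject, so the retained channel set matches across sessions — then
decompose into narrow frequency bands and cut into fixed-length epochs from
which a random subset is drawn for connectivity estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .cohort import Recording

__all__ = [
    "BandEpochSet",
    "resample",
    "broadband_filter",
    "band_filter",
    "band_decompose",
    "detect_artifacts",
    "detect_bad_channels",
    "harmonize_channels",
    "epoch_and_select",
]

_MAD_SCALE = 1.4826  # MAD -> sd for a normal distribution

# minimum variance ratio over the typical window before the variance rule
# may fire: windowed variance of narrowband signals fluctuates by up to
# ~3x through benign envelope modulation (chi-square with ~2*bandwidth*T
# degrees of freedom), while "clearly nonneurological" segments are tens
# to hundreds of times the typical variance
_MIN_VAR_FACTOR = 4.0


@dataclass
class BandEpochSet:
    """Fixed-length epochs of one subject-session in one frequency band.

    ``epochs`` is an n_epochs × channels × samples array; samples per
    epoch = epoch_length × sampling_rate (5 s × 512 Hz = 2,560 by default).
    """

    subject_id: str
    session_id: int
    band_name: str
    epochs: np.ndarray
    sampling_rate: float
    epoch_length: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x channels x samples")
        expected = int(round(self.epoch_length * self.sampling_rate))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch has {self.epochs.shape[2]} samples, expected {expected}")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def resample(rec: Recording, target_rate: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_rate``.

    Output length is ``floor(n_samples * target / original)``; upsampling
    is refused (the use case is decimating the acquisition rate, e.g.
    2048 Hz → 512 Hz).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise ValueError("target_rate exceeds the original sampling rate")
    if np.isclose(target_rate, rec.sampling_rate):
        return rec.copy()
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=-1)
    n_out = int(np.floor(rec.n_samples * target_rate / rec.sampling_rate))
    data = data[:, :n_out]
    return replace(rec, data=data, sampling_rate=float(target_rate),
                   channel_labels=list(rec.channel_labels))


def _bandpass_sos(low: float, high: float, fs: float, order: int) -> np.ndarray:
    nyq = fs / 2
    if not 0 < low < high < nyq:
        raise ValueError(
            f"need 0 < low < high < Nyquist ({nyq} Hz); got {low}-{high} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def broadband_filter(rec: Recording, low: float = 0.1, high: float = 70.0,
                     order: int = 4) -> Recording:
    """Zero-phase (forward–backward) Butterworth band-pass.

    ``order`` is per pass (default 4, the common EEG-toolbox choice); the
    two-way application doubles the effective order and cancels the group
    delay. Tones near a band edge are still attenuated by a few percent —
    the Butterworth −3 dB point sits *at* the edge.
    """
    sos = _bandpass_sos(low, high, rec.sampling_rate, order)
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=data, channel_labels=list(rec.channel_labels))


def band_filter(rec: Recording, low: float, high: float,
                order: int = 3) -> Recording:
    """Zero-phase band-pass to one analysis band (same filter family)."""
    return broadband_filter(rec, low, high, order=order)


def band_decompose(rec: Recording, bands, order: int = 3) -> list[Recording]:
    """One zero-phase band-passed copy of the recording per (name, lo, hi).

    Returned list is parallel to ``bands``; each copy keeps the full length
    (epoching happens afterwards, so filter transients are not cut into
    every epoch edge).
    """
    return [band_filter(rec, lo, hi, order=order) for _name, lo, hi in bands]


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        # majority of values identical: anything off the median is an
        # unambiguous outlier
        out = np.where(x == med, 0.0, np.inf)
        return out
    return (x - med) / (_MAD_SCALE * mad)


def detect_artifacts(rec: Recording, jump_z: float = 8.0, var_z: float = 4.0,
                     epoch_length: float = 5.0) -> np.ndarray:
    """Flag non-neurological stretches; returns a channels × samples mask.

    Two rules, per channel:

    * jump rule — samples whose first difference is more than ``jump_z``
      robust-z units (median/MAD) from the channel's typical difference;
      both samples straddling the offending difference are flagged;
    * variance rule — consecutive ``epoch_length`` windows whose
      log-variance is more than ``var_z`` robust-z units above the typical
      window. Each channel's window variances are first scaled by that
      channel's 10th-percentile window (a clean reference even when most
      of the channel is corrupted, which would poison its own median),
      log-transformed (variance estimates of narrowband signals are
      heavy-tailed on the raw scale) and pooled across channels, so
      channels with different intrinsic power do not shadow one another.

    A constant (zero-information) channel is flagged entirely.
    """
    if jump_z <= 0 or var_z <= 0:
        raise ValueError("thresholds must be positive")
    C, S = rec.data.shape
    mask = np.zeros((C, S), dtype=bool)
    n_ep = int(round(epoch_length * rec.sampling_rate))
    constant = np.ptp(rec.data, axis=1) == 0
    mask[constant] = True
    for c in range(C):
        if constant[c]:
            continue
        d = np.diff(rec.data[c])
        z = np.abs(_robust_z(d))
        hit = np.flatnonzero(z > jump_z)
        mask[c, hit] = True
        mask[c, hit + 1] = True
    if n_ep > 1 and S >= 2 * n_ep:
        n_full = S // n_ep
        live = np.flatnonzero(~constant)
        if live.size:
            v = rec.data[live, : n_full * n_ep].reshape(
                live.size, n_full, n_ep).var(axis=2)
            # 'lower' method: the reference is an actual (clean) window,
            # never an interpolation with a corrupted neighbour
            ref = np.quantile(v, 0.10, axis=1, keepdims=True, method="lower")
            ref[ref == 0] = 1.0
            logr = np.log(np.maximum(v / ref, 1e-300))
            vz = _robust_z(logr)
            big = logr > np.median(logr) + np.log(_MIN_VAR_FACTOR)
            for ci, ei in zip(*np.nonzero((vz > var_z) & big)):
                mask[live[ci], ei * n_ep:(ei + 1) * n_ep] = True
    return mask


def detect_bad_channels(rec: Recording, artifact_mask: np.ndarray) -> list[str]:
    """Channels whose artifact fraction strictly exceeds 50%."""
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != rec.data.shape:
        raise ValueError("artifact_mask shape does not match the recording")
    frac = artifact_mask.mean(axis=1)
    return [lbl for lbl, f in zip(rec.channel_labels, frac) if f > 0.5]


def harmonize_channels(session1: Recording, session2: Recording,
                       bad1, bad2) -> tuple[Recording, Recording]:
    """Drop the union of both sessions' bad channels from both sessions.

    Keeps the retained label order identical across sessions; errors if
    fewer than two channels remain.
    """
    if set(session1.channel_labels) != set(session2.channel_labels):
        raise ValueError("sessions carry different channel sets")
    bad = set(bad1) | set(bad2)
    keep = [lbl for lbl in session1.channel_labels if lbl not in bad]
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} channel(s) left after removing {sorted(bad)}")

    def _subset(rec: Recording) -> Recording:
        idx = [rec.channel_labels.index(lbl) for lbl in keep]
        return replace(rec, data=rec.data[idx], channel_labels=list(keep))

    return _subset(session1), _subset(session2)


def epoch_and_select(rec: Recording, epoch_length: float = 5.0,
                     n_select: int = 20, seed: int = 0,
                     artifact_mask: np.ndarray | None = None,
                     band_name: str = "") -> BandEpochSet:
    """Cut into consecutive non-overlapping epochs and draw a clean subset.

    Epochs start at sample 0; any epoch containing an artifact-flagged
    sample is removed from the candidate pool *before* the seeded uniform
    draw of ``n_select`` epochs without replacement. Selected epochs are
    returned in temporal order.
    """
    n_samp = int(round(epoch_length * rec.sampling_rate))
    if n_samp < 1:
        raise ValueError("epoch_length too short for the sampling rate")
    n_candidates = rec.n_samples // n_samp
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, dtype=bool)
        if artifact_mask.shape != rec.data.shape:
            raise ValueError("artifact_mask shape does not match the recording")
    clean = []
    for e in range(n_candidates):
        sl = slice(e * n_samp, (e + 1) * n_samp)
        if artifact_mask is None or not artifact_mask[:, sl].any():
            clean.append(e)
    if len(clean) < n_select:
        raise ValueError(
            f"only {len(clean)} clean epoch(s) available "
            f"({n_candidates} candidates), need {n_select}: "
            f"short by {n_select - len(clean)}")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(clean, size=n_select, replace=False))
    epochs = np.stack([
        rec.data[:, e * n_samp:(e + 1) * n_samp] for e in chosen])
    return BandEpochSet(subject_id=rec.subject_id, session_id=rec.session_id,
                        band_name=band_name, epochs=epochs,
                        sampling_rate=rec.sampling_rate,
                        epoch_length=epoch_length,
                        channel_labels=list(rec.channel_labels))
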