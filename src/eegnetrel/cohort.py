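"""Synthetic two-session EEG cohorts with known coupling structure.

The generator emulates a test-retest EEG study: a cohort of subjects is
recorded twice, roughly a week apart, with a multichannel sensor cap. Each
subject carries a connectivity "fingerprint" — per-band, per-edge phase
couplings drawn around a population mean — and the fingerprint of session 2
is correlated with that of session 1 by a tunable stability parameter. This
gives every downstream stage (filtering, phase connectivity, graph metrics,
ICC reliability) a ground truth to be validated against.

Signal model, per frequency band:

* each channel owns a latent band-limited oscillator (white noise band-pass
  filtered to the band, unit variance) — filtered noise, not a sinusoid, so
  the Hilbert phase is nondegenerate and the phase lag index does not
  saturate trivially;
* channel ``j`` receives the latent source of channel ``i`` (for ``i < j``)
  phase-shifted by ``phase_lag`` radians, with mixing weight equal to the
  edge coupling ``g[i, j]``; the channel's own source is down-weighted by
  the total incoming coupling so a strongly driven channel is dominated by
  its driver (coupling 1 ⇒ near-perfect phase locking);
* bands are summed and broadband white sensor noise of sd ``noise_sd`` is
  added.

Coupling is directed low-index → high-index so the phase lag has a
consistent sign; a symmetric convention would inject both +lag and −lag
copies whose sign contributions cancel in the PLI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "DEFAULT_BANDS",
    "CohortSpec",
    "Recording",
    "ArtifactTruth",
    "ring_coupling_base",
    "two_tier_coupling",
    "generate_cohort",
    "generate_recording",
    "subject_couplings",
    "inject_artifacts",
]

#: The six analysis bands (name, low Hz, high Hz) used throughout:
#: delta, theta, alpha1, alpha2, beta and low gamma.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 3.0),
    ("theta", 3.0, 6.0),
    ("alpha1", 6.0, 9.0),
    ("alpha2", 9.0, 12.0),
    ("beta", 12.0, 25.0),
    ("gamma", 25.0, 45.0),
)


@dataclass
class Recording:
    """One subject-session multichannel time series.

    ``data`` is a channels × samples real matrix in arbitrary (µV-scale)
    units. Invariant: no non-finite values.
    """

    subject_id: str
    session_id: int
    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       channel_labels=list(self.channel_labels))


def ring_coupling_base(n_channels: int, strength: float = 0.5,
                       decay: float = 1.5) -> np.ndarray:
    """Deterministic population-mean coupling with a ring topology.

    Channels sit on a ring; coupling decays exponentially with ring
    distance ``d``: ``strength * exp(-(d - 1) / decay)``. Nearest
    neighbours get ``strength``, long-range edges little — a lattice-like
    structure that yields clustered, small-world-flavoured networks.
    """
    idx = np.arange(n_channels)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, n_channels - d)
    with np.errstate(over="ignore"):
        base = strength * np.exp(-(d - 1) / decay)
    np.fill_diagonal(base, 0.0)
    return np.clip(base, 0.0, 1.0)


def two_tier_coupling(n_channels: int, strong: float = 0.5, weak: float = 0.15,
                      strong_fraction: float = 0.25, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Coupling base with a strong minority of edges and a weak majority.

    Returns ``(base, strong_mask)`` where ``strong_mask`` marks the strong
    edges (symmetric boolean matrix). Used to build cohorts in which edge
    strength and edge stability can be linked.
    """
    rng = np.random.default_rng(seed)
    n_edges = n_channels * (n_channels - 1) // 2
    n_strong = max(1, int(round(strong_fraction * n_edges)))
    chosen = rng.choice(n_edges, size=n_strong, replace=False)
    flat = np.full(n_edges, weak)
    flat[chosen] = strong
    base = np.zeros((n_channels, n_channels))
    iu = np.triu_indices(n_channels, k=1)
    base[iu] = flat
    base = base + base.T
    mask = np.zeros_like(base, dtype=bool)
    mask[iu] = flat > weak
    mask = mask | mask.T
    return base, mask


@dataclass
class CohortSpec:
    """Conditions of a synthetic two-session cohort.

    Defaults are desk-scale (20 subjects × 16 channels × 512 Hz × 120 s)
    so a full cohort generates in seconds; :meth:`study_scale` returns the
    emulated study's full size (60 subjects × 32 channels).

    Parameters
    ----------
    coupling_base
        Population-mean coupling per band: a single symmetric matrix in
        [0, 1] applied to every band, or a dict band-name → matrix.
        ``None`` selects :func:`ring_coupling_base`.
    subject_sd
        Between-subject sd of edge couplings. The deviation is split
        50/50 in variance between a gain shared by all edges of a subject
        and an edge-specific pattern, so between-subject spread survives
        averaging into global connectivity.
    session_stability
        Correlation ρ ∈ [0, 1] of a subject's coupling deviations across
        sessions; scalar, or a symmetric per-edge matrix.
    phase_lag
        Phase shift (radians) applied to each transmitted source. Must not
        be a multiple of π: a zero (or π) lag gives sign-symmetric phase
        differences and a PLI of 0 by construction.
    noise_sd
        Broadband white sensor noise sd, relative to the unit-variance
        band sources.
    """

    n_subjects: int = 20
    n_channels: int = 16
    sampling_rate: float = 512.0
    duration: float = 120.0
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    coupling_base: object = None
    subject_sd: float = 0.25
    session_stability: object = 0.8
    noise_sd: float = 0.5
    phase_lag: float = np.pi / 2
    seed: int = 0
    shared_gain_fraction: float = field(default=0.5, repr=False)

    @classmethod
    def study_scale(cls, **overrides) -> "CohortSpec":
        """Spec at the emulated study's size: 60 subjects, 32 channels."""
        kw = dict(n_subjects=60, n_channels=32)
        kw.update(overrides)
        return cls(**kw)

    # -- validation ---------------------------------------------------
    def coupling_for(self, band_name: str) -> np.ndarray:
        base = self.coupling_base
        if base is None:
            base = ring_coupling_base(self.n_channels)
        if isinstance(base, dict):
            base = base[band_name]
        return np.asarray(base, dtype=float)

    def stability_for(self, band_name: str) -> np.ndarray:
        rho = self.session_stability
        if isinstance(rho, dict):
            rho = rho[band_name]
        rho = np.asarray(rho, dtype=float)
        return rho

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 2:
            raise ValueError("need at least 1 subject and 2 channels")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("subject_sd and noise_sd must be nonnegative")
        if not np.isfinite(self.phase_lag) or np.isclose(
                np.sin(self.phase_lag), 0.0, atol=1e-12):
            raise ValueError(
                "phase_lag must be finite and not a multiple of pi "
                "(a zero/pi lag nulls the PLI by construction)")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        for name, lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"band {name}: need 0 < low < high")
            if hi >= self.sampling_rate / 2:
                raise ValueError(f"band {name}: high edge {hi} Hz at/above Nyquist")
            base = self.coupling_for(name)
            if base.shape != (self.n_channels, self.n_channels):
                raise ValueError(f"coupling_base for {name}: wrong shape")
            if not np.allclose(base, base.T):
                raise ValueError(f"coupling_base for {name} is not symmetric")
            if np.any(np.diag(base) != 0):
                raise ValueError(f"coupling_base for {name} has nonzero diagonal")
            if base.min() < 0 or base.max() > 1:
                raise ValueError(f"coupling_base for {name} outside [0, 1]")
            if not np.all(np.isfinite(base)):
                raise ValueError(f"coupling_base for {name} has non-finite entries")
            rho = self.stability_for(name)
            if np.any(rho < 0) or np.any(rho > 1) or not np.all(np.isfinite(rho)):
                raise ValueError("session_stability must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _band_sos(lo: float, hi: float, fs: float, order: int = 3) -> np.ndarray:
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _symmetric_normal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric zero-diagonal matrix of iid N(0,1) upper-triangle entries."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.standard_normal(len(iu[0]))
    return m + m.T


def subject_couplings(spec: CohortSpec, subject_index: int
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-band (session-1, session-2) coupling matrices for one subject.

    Deterministic given ``spec.seed`` and the subject index; independent of
    ``n_subjects`` (per-subject substreams), so growing the cohort leaves
    existing subjects untouched.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(subject_index)]))
    n = spec.n_channels
    a = np.sqrt(spec.shared_gain_fraction)
    b = np.sqrt(1.0 - spec.shared_gain_fraction)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mask_offdiag = ~np.eye(n, dtype=bool)
    for name, _, _ in spec.bands:
        base = spec.coupling_for(name)
        rho = spec.stability_for(name)
        # two independent deviations around the base, each a shared gain
        # plus an edge-specific pattern
        devs = []
        for _draw in range(2):
            gain = rng.standard_normal()
            edges = _symmetric_normal(rng, n)
            devs.append(spec.subject_sd * (a * gain * mask_offdiag + b * edges))
        d1, d2p = devs
        # correlate deviations (not raw couplings): keeps E[g2] = base
        d2 = rho * d1 + np.sqrt(1.0 - rho ** 2) * d2p
        g1 = np.clip(base + d1, 0.0, 1.0)
        g2 = np.clip(base + d2, 0.0, 1.0)
        np.fill_diagonal(g1, 0.0)
        np.fill_diagonal(g2, 0.0)
        out[name] = (g1, g2)
    return out


def _synthesize(spec: CohortSpec, couplings: dict[str, np.ndarray],
                rng: np.random.Generator) -> np.ndarray:
    """Render one session's channels × samples signal from its couplings."""
    n, n_samp = spec.n_channels, spec.n_samples
    # pad so filter/Hilbert edge transients never enter the kept span
    pad = int(round(2.0 * spec.sampling_rate))
    total = n_samp + 2 * pad
    shift = np.exp(-1j * spec.phase_lag)
    y = np.zeros((n, total))
    for name, lo, hi in spec.bands:
        g = couplings[name]
        sos = _band_sos(lo, hi, spec.sampling_rate)
        x = signal.sosfiltfilt(sos, rng.standard_normal((n, total)), axis=-1)
        x /= x.std(axis=-1, keepdims=True)
        analytic = signal.hilbert(x, axis=-1)
        lagged = (analytic * shift).real
        # directed mixing: channel j takes sources of channels i < j
        w = np.tril(g, k=-1)  # w[j, i] = g[i, j] for i < j
        own = np.maximum(1.0 - w.sum(axis=1), 0.1)
        y += own[:, None] * x + w @ lagged
    if spec.noise_sd > 0:
        y += spec.noise_sd * rng.standard_normal((n, total))
    return y[:, pad:pad + n_samp]


def generate_recording(spec: CohortSpec, subject_index: int, session_id: int
                       ) -> Recording:
    """Generate a single subject-session :class:`Recording`."""
    spec.validate()
    if session_id not in (1, 2):
        raise ValueError("session_id must be 1 or 2")
    pair = subject_couplings(spec, subject_index)
    couplings = {name: pair[name][session_id - 1] for name in pair}
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(spec.seed), int(subject_index), 1000 + session_id]))
    data = _synthesize(spec, couplings, rng)
    labels = [f"ch{c:02d}" for c in range(spec.n_channels)]
    return Recording(subject_id=f"sub{subject_index:03d}",
                     session_id=session_id, data=data,
                     sampling_rate=spec.sampling_rate, channel_labels=labels)


def generate_cohort(spec: CohortSpec, with_truth: bool = False):
    """Generate the full cohort: ``n_subjects`` × 2 sessions of recordings.

    Returns the list of :class:`Recording` (subject-major, session 1 then
    2). With ``with_truth=True`` also returns a tidy table of the
    ground-truth edge couplings (columns: subject, session, band, chan_i,
    chan_j, weight) as a pandas DataFrame.
    """
    spec.validate()
    recordings = []
    rows = []
    iu = np.triu_indices(spec.n_channels, k=1)
    for s in range(spec.n_subjects):
        pair = subject_couplings(spec, s)
        for session in (1, 2):
            recordings.append(generate_recording(spec, s, session))
            if with_truth:
                for name in pair:
                    g = pair[name][session - 1]
                    for i, j, wgt in zip(iu[0], iu[1], g[iu]):
                        rows.append((f"sub{s:03d}", session, name,
                                     int(i), int(j), float(wgt)))
    if with_truth:
        import pandas as pd

        truth = pd.DataFrame(
            rows, columns=["subject", "session", "band",
                           "chan_i", "chan_j", "weight"])
        return recordings, truth
    return recordings


@dataclass
class ArtifactTruth:
    """Ground truth of injected artifacts.

    ``mask`` flags corrupted samples (channels × samples); ``jumps`` lists
    (channel index, sample index, amplitude) of step discontinuities;
    ``bad_channels`` are labels corrupted over more than half their span.
    """

    mask: np.ndarray
    jumps: list[tuple[int, int, float]]
    bad_channels: list[str]


def inject_artifacts(rec: Recording, bad_channel_fraction: float = 0.0,
                     jump_rate: float = 0.0, seed: int = 0
                     ) -> tuple[Recording, ArtifactTruth]:
    """Corrupt a recording with step jumps and high-variance segments.

    ``bad_channel_fraction`` of channels become "bad": over 60% of their
    duration is replaced by high-variance noise, so the >50%-artifact
    channel-rejection rule must flag them. Each remaining channel gets a
    step discontinuity of 50 signal-sd with probability ``jump_rate``.
    With both parameters zero the recording is returned unchanged.
    """
    if not 0 <= bad_channel_fraction <= 1 or not 0 <= jump_rate <= 1:
        raise ValueError("fractions/rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = rec.copy()
    C, S = out.data.shape
    mask = np.zeros((C, S), dtype=bool)
    jumps: list[tuple[int, int, float]] = []

    n_bad = int(round(bad_channel_fraction * C))
    bad_idx = sorted(rng.choice(C, size=n_bad, replace=False)) if n_bad else []
    for c in bad_idx:
        sd = out.data[c].std()
        # one contiguous high-variance block over ~65% of the channel, so
        # whole-epoch artifact flagging still exceeds the 50% rule
        seg_len = int(0.65 * S)
        st = int(rng.integers(0, S - seg_len))
        sl = slice(st, st + seg_len)
        out.data[c, sl] += 10.0 * max(sd, 1.0) * rng.standard_normal(seg_len)
        mask[c, sl] = True

    for c in range(C):
        if c in bad_idx or rng.random() >= jump_rate:
            continue
        pos = int(rng.integers(S // 10, 9 * S // 10))
        amp = 50.0 * out.data[c].std() * (1 if rng.random() < 0.5 else -1)
        out.data[c, pos:] += amp
        mask[c, pos] = True
        jumps.append((c, pos, amp))

    if n_bad and not jumps and jump_rate > 0:
        warnings.warn("jump_rate > 0 but no jumps were drawn", stacklevel=2)
    truth = ArtifactTruth(mask=mask, jumps=jumps,
                          bad_channels=[rec.channel_labels[c] for c in bad_idx])
    return out, truth
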