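# Methods

This note documents the models, estimators and numerical choices behind
`eegnetrel`, in the order data flows through the pipeline.

## Synthetic two-session cohorts

The generator emulates a test–retest EEG study: `n_subjects` subjects
recorded in two sessions with `n_channels` sensors. Its defaults are
desk-scale (20 subjects × 16 channels × 512 Hz × 120 s, six bands:
delta 0.5–3, theta 3–6, alpha1 6–9, alpha2 9–12, beta 12–25, gamma
25–45 Hz) so a cohort builds in seconds; `CohortSpec.study_scale()`
switches to the emulated study's 60 subjects × 32 channels. Recordings
are synthesized directly at 512 Hz — the analysis rate — rather than at
an acquisition rate followed by decimation; the `resample` operation is
still provided and tested for real data entering at 2048 Hz.

**Coupling model.** Per band, a symmetric matrix `g ∈ [0,1]^{C×C}` of
edge couplings is drawn per subject around a population mean
(`coupling_base`, default: a ring topology with exponentially decaying
coupling over ring distance — strong neighbours, weak long-range edges).
The subject deviation is split 50/50 in variance between a *shared gain*
(one scalar added to every edge) and an *edge-specific pattern*; total
sd is `subject_sd` (default 0.25). The shared component is essential:
purely edge-independent fingerprints average out of global connectivity
as 1/√n_edges, which would leave between-subject spread of global PLI far
below what test–retest EEG studies actually observe (COV of a few to ~10%)
and would make global-connectivity ICC unrecoverable by construction.
With the default settings the generated between-subject COV of global PLI
is ≈ 0.07, inside the empirically reported range.

**Session stability.** Session 2's deviation is
`d₂ = ρ·d₁ + √(1−ρ²)·d₂′` with `d₂′` an independent draw, so
corr(d₁, d₂) = ρ = `session_stability` exactly in expectation. The mixture
is applied to the *deviations from the base*, not to the couplings
themselves — mixing the raw couplings would bias E[g₂] away from the base
for ρ ∉ {0, 1}. ρ may be a per-edge matrix, which allows cohorts in which
edge strength and edge stability are linked (used to reproduce the
"top-quartile edges are more reliable" effect by construction).

**Signal model.** Per band, each channel owns a latent oscillator:
white noise band-pass filtered to the band (order-3 zero-phase
Butterworth) and normalized to unit variance. Filtered noise, not a
sinusoid — a pure tone has a trivially linear Hilbert phase and saturates
any phase-locking index. Channel j receives the source of channel i
(for i < j) phase-shifted by `phase_lag` (default π/2) with weight
g[i,j]; its own source is down-weighted by the total incoming coupling
(floor 0.1), so a strongly driven channel is dominated by its driver and
coupling → 1 yields near-perfect phase locking. Coupling is directed
low→high index: a symmetric convention would inject +lag and −lag copies
whose sign contributions cancel in the PLI. `phase_lag` must not be a
multiple of π (zero-lag coupling is invisible to the PLI by design).
Bands are summed and white sensor noise (`noise_sd`, default 0.5 relative
to unit-variance sources) is added. Two seconds of padding are generated
at each end and discarded so filter/Hilbert transients never enter the
kept span.

**Reproducibility.** One global seed expands into per-subject
substreams (`SeedSequence([seed, subject])`), so cohorts are bit-identical
under the same spec and existing subjects are unchanged when `n_subjects`
grows.

**What the generator does not emulate:** volume conduction / field
spread (beyond the zero-lag null both estimators are built for), head
geometry and electrode positions, nonstationary task modulation (e.g.
stimulus-driven band-power changes — the process is stationary),
1/f background spectra, and realistic artifact morphology beyond step
jumps and variance bursts. Passing tests therefore demonstrate correct
*estimator and statistic* behaviour under a controlled phase-coupling
model, not realism of infant EEG.

## Preprocessing

* **Resampling** is polyphase and anti-aliased; output length
  `floor(n·target/original)`; upsampling is refused.
* **Broadband filtering** (default 0.1–70 Hz) is a zero-phase
  forward–backward Butterworth, order 4 per pass (the common EEG-toolbox
  default). Two-way application squares the magnitude response and cancels
  group delay. Note the −3 dB point sits at the band edge: a 50 Hz tone
  under a 70 Hz edge keeps ≈ 94% amplitude, a 100 Hz tone is attenuated
  ≈ 95%.
* **Artifact detection** is deliberately light ("not deep cleaned"),
  two rules per channel: samples whose first difference exceeds
  `jump_z` = 8 robust-z units (median/MAD), and `epoch_length` windows
  whose variance stands out. Window variances are scaled by the channel's
  10th-percentile window (an uncorrupted reference even when most of a
  channel is bad, which would poison its own median), log-transformed
  (raw windowed variances of narrowband signals are heavy-tailed through
  benign envelope modulation) and pooled across channels; a window is
  flagged when it exceeds `var_z` = 4 robust-z units *and* at least 4×
  the typical variance ratio. The multiplicative floor stops the z-rule
  from firing on the very tight variance distributions of clean broadband
  data, where even percent-level fluctuations are many MADs. Constant
  channels are flagged entirely.
* **Channel rejection**: channels with artifacts in strictly more than
  50% of their samples are removed — from *both* sessions of a subject,
  so the retained channel set (and hence the pair count) matches across
  sessions and varies per subject.
* **Band decomposition** applies order-3 zero-phase Butterworth
  band-passes to the *continuous* record before epoching, so filter
  transients do not contaminate every epoch edge.
* **Epoching**: consecutive non-overlapping epochs from sample 0
  (default 5 s → 2,560 samples at 512 Hz); epochs containing any flagged
  sample are removed from the candidate pool *before* the seeded uniform
  draw of `n_epochs` (default 20) without replacement. Whether exclusion
  precedes or follows the random draw is an open choice; excluding first
  guarantees the requested number of clean epochs or an explicit error
  naming the deficit.

## Connectivity

Phases/analytic signals come from the Hilbert transform per epoch, no
padding (epochs are cut after filtering). PLI is computed within each
epoch (mean over its N samples, absolute value) and averaged across
epochs — matching the per-epoch estimator definition; a pooled-samples
variant is available (`pool_samples=True`). The PLI has a positive
small-sample bias (≈ the expected |mean| of ±1 signs with the band's
autocorrelation time setting the effective sample count) that decreases
with epoch length, not with epoch count.

The dwPLI is the debiased weighted PLI-square over the per-sample
imaginary cross-spectral terms, with the sums pooled across *all* samples
of *all* epochs before the ratio — this pooling is where the
sample-size debiasing acts, and it makes the estimator exactly unbiased
at 0 under independence (it may go negative). A pair whose terms all
vanish (exactly zero lag — the volume-conduction case both indices
null) is defined as 0 with a warning; "vanish" is judged relative to
N·eps·max|a|·max|b|, since Im(z·conj(z)) is round-off, not exactly zero,
in floating point.

## Graph metrics

Computed on full weighted PLI matrices only — dwPLI matrices can carry
negative weights and are rejected with an instructive error. Weights are
scaled by the matrix maximum before Onnela clustering (the formula
presumes weights relative to the network maximum), and path length uses
edge length 1/w, the brain-connectivity-toolbox convention (the mapping
is otherwise undefined for weighted graphs). The random references
C_rand, L_rand are means over `n_surrogates` = 100 surrogates obtained by
uniformly permuting the upper-triangle weights (on complete weighted
graphs the degree sequence is trivial, so weight shuffling is the natural
null), seeded; one ensemble per matrix serves both normalizations and the
SWI. Both normalized metrics are invariant to uniform weight scaling.
Disconnected graphs (possible only with exact zero weights) raise.

## Reliability statistics

The ICC is the single-measure consistency form of the two-way mixed
model, ICC(3,1): MSr the between-subject mean square, MSe the residual
after removing subject and session main effects,
ICC = (MSr − MSe)/(MSr + (k−1)MSe). A one-way variant (MSe = within-
subject mean square) is available via `model="one_way"`. Negative ICCs
are reported as computed. Degenerate inputs: an all-identical table →
1 with a warning (the MSe → 0 limit); identical subjects with a session
effect → error (no between-subject variance to ratio). Unit-wise ICCs are
computed per edge over the channel set common to all subjects
(intersection); their summary is the median, as per-edge ICC
distributions are skewed. The top-percentile mask takes the
ceil(p/100 · n_edges) strongest edges of the grand-average matrix
(all subjects, both sessions), expanding to include cutoff ties with a
warning.

COV is sd/mean — the standard coefficient of variation — computed on
session-1 values by default (configurable). Bootstrap CIs resample
subjects with replacement keeping each subject's session pair intact,
`n_boot` = 10,000 by default, percentile 2.5/97.5 bounds (percentile
rather than BCa: the simplest defensible default, config-exposed).
Reliability labels: ICC < 0.4 low, 0.4–0.6 mediocre, 0.6–0.75 good,
> 0.75 excellent.

## Pipeline

`RunConfig` fully determines a run; exact stages (epoch draws, surrogate
permutations, bootstrap resamples) are bit-reproducible for a given seed,
float stages to numerical tolerance. Stage seeds are derived from the
global seed with a stable string hash (Python's builtin `hash` is
process-randomized). The manifest records config, seed, versions and
per-subject removed channels / epoch counts. dwPLI matrices stop at the
measure level; the graph section is PLI-only.

## Test and acceptance problem sizes

The unit suite runs on desk-scale cohorts (≤ 8 subjects, ≤ 8 channels,
≤ 40 s). The acceptance suite uses: 500 independent-noise pairs of
20 × 2,560 samples for the dwPLI null; 1,000 random tables against the
ANOVA oracle; 100 random graphs against brute-force oracles; 30-subject,
16-channel, single-band cohorts (20 × 5 s epochs) for ICC recovery over
the stability grid {0, 0.3, 0.6, 0.9, 1}; and 200 cohorts at
n_boot = 1,000 for bootstrap coverage. Recovery and top-quartile cohorts
use the beta band: its wide bandwidth (13 Hz) gives the shortest phase
autocorrelation time and hence the most effective samples per epoch,
i.e. the least estimator noise per unit compute. Coverage cohorts have
45 subjects (8 channels, 8 × 2 s epochs): percentile bootstrap intervals
for the ICC are anticonservative at small n — measured coverage was at
the low edge (≈ 0.90) with 30 subjects — and adequately calibrated by
n = 45; the reference "large-sample" ICC is estimated from a pooled
1,350-subject cohort of the same specification.

## Known limitations

* Sensor-space only; no leakage correction beyond the estimators' own
  zero-lag insensitivity.
* The variance-rule artifact detector assumes channels share a physical
  scale (true within an EEG montage); channels with wildly different
  gains should be normalized upstream.
* The EDF/BDF reader requires `mne`; EDF *export* is not provided —
  synthetic recordings persist as `.npy` + JSON sidecar.
* Unit-wise ICC uses the channel intersection across subjects; with very
  heterogeneous bad-channel patterns the common edge set can shrink
  substantially (the count is recorded in the report).
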