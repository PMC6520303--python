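"""Test-retest reliability statistics for two-session cohorts.

Three levels of analysis:

1. matrix level — Pearson correlation of each subject's vectorized
   session-1 vs session-2 connectivity matrix;
2. measure level — intraclass correlation of global connectivity (the mean
   over all retained electrode pairs) across sessions, plus "unit-wise"
   reliability: one ICC per edge over subjects, summarized by the median
   (the per-edge ICC distribution is not normal), optionally restricted to
   the top percentile of on-average strongest connections;
3. graph level — the same ICC applied to per-subject graph metrics.

The ICC is the single-measure consistency form of the two-way mixed model,
ICC(3,1)::

    ICC = (MSr − MSe) / (MSr + (k − 1) MSe)

with MSr the between-subject mean square, MSe the residual mean square
after removing subject and session effects, and k the number of sessions.
Consistency means an additive session-wide shift does not lower the ICC.
A one-way variant (MSe = within-subject mean square) is available via
``model="one_way"``. Negative ICCs are reported as computed, never clamped.

Between-subject variability is the coefficient of variation (sd/mean), and
confidence intervals come from resampling subjects with replacement
(keeping each subject's session pair intact) with percentile 2.5/97.5
bounds.

Reliability classification bins: ICC < 0.4 low, 0.4–0.6 mediocre,
0.6–0.75 good, > 0.75 excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "MeasurementTable",
    "ReliabilityReport",
    "matrix_correlation",
    "global_connectivity",
    "icc",
    "icc_table",
    "icc_bootstrap_ci",
    "icc_global",
    "icc_unitwise",
    "top_percentile_edges",
    "cov",
    "bootstrap_ci",
    "classify_icc",
    "pair_by_subject",
]

_EPS = 1e-12


@dataclass
class MeasurementTable:
    """Subjects × measurements table feeding the ICC (here k = 2 sessions)."""

    values: np.ndarray
    subject_ids: list[str]
    metric: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x measurements")
        if self.values.shape[1] < 2:
            raise ValueError("need at least two measurements per subject")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per row required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table contains missing/non-finite cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def matrix_correlation(m1: ConnectivityMatrix, m2: ConnectivityMatrix) -> float:
    """Pearson r between the two sessions' upper-triangle edge vectors."""
    if m1.channel_labels != m2.channel_labels:
        raise ValueError("matrices carry different channel sets")
    if m1.band_name != m2.band_name or m1.method != m2.method:
        raise ValueError("matrices must share band and method")
    a, b = m1.upper_triangle(), m2.upper_triangle()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def global_connectivity(m: ConnectivityMatrix) -> float:
    """Mean connectivity over all retained (upper-triangle) electrode pairs."""
    return float(m.upper_triangle().mean())


def _icc_from_tables(values: np.ndarray, model: str = "two_way_mixed"
                     ) -> np.ndarray:
    """Vectorized ICC over tables stacked in leading dimensions.

    ``values`` has shape (..., n, k); returns shape (...). Degenerate
    tables (zero denominator) yield nan — the scalar wrapper turns these
    into the documented special cases.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape[-2:]
    if n < 2:
        raise ValueError("need at least two subjects")
    grand = values.mean(axis=(-2, -1), keepdims=True)
    rows = values.mean(axis=-1, keepdims=True)
    ssr = k * ((rows - grand) ** 2).sum(axis=(-2, -1))
    msr = ssr / (n - 1)
    if model == "two_way_mixed":
        cols = values.mean(axis=-2, keepdims=True)
        resid = values - rows - cols + grand
        mse = (resid ** 2).sum(axis=(-2, -1)) / ((n - 1) * (k - 1))
    elif model == "one_way":
        mse = ((values - rows) ** 2).sum(axis=(-2, -1)) / (n * (k - 1))
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    den = msr + (k - 1) * mse
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > _EPS, (msr - mse) / np.where(den > _EPS, den, 1.0),
                       np.nan)
    return out


def icc(table: MeasurementTable, model: str = "two_way_mixed") -> float:
    """Single-measure ICC of a measurement table.

    Degenerate inputs: a table whose values are all identical has no
    between-subject variance to speak of but also zero error — it is
    reported as 1 with a warning (the MSe → 0 limit); a table whose rows
    are identical but whose sessions differ leaves the ICC undefined.
    """
    if table.n_subjects < 3:
        raise ValueError("need at least three subjects for a meaningful ICC")
    val = _icc_from_tables(table.values, model=model)
    if np.isnan(val):
        if np.ptp(table.values) == 0:
            warnings.warn(
                "all measurements identical: ICC taken as 1 (MSe -> 0 limit)",
                stacklevel=2)
            return 1.0
        raise ValueError(
            "ICC undefined: no between-subject variance in the table")
    return float(val)


def icc_table(values: np.ndarray, subject_ids: Sequence[str] | None = None,
              model: str = "two_way_mixed", **kw) -> float:
    """Convenience: ICC straight from a subjects × sessions array."""
    values = np.asarray(values, dtype=float)
    ids = list(subject_ids) if subject_ids is not None else [
        f"s{i}" for i in range(values.shape[0])]
    return icc(MeasurementTable(values, ids, **kw), model=model)


def cov(values: np.ndarray) -> float:
    """Coefficient of variation: sample sd over mean of per-subject values."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m == 0:
        raise ValueError("zero mean: coefficient of variation undefined")
    return float(values.std(ddof=1) / m)


def classify_icc(value: float) -> str:
    """Reliability label: <0.4 low, 0.4–0.6 mediocre, 0.6–0.75 good, >0.75 excellent."""
    if value < 0.4:
        return "low"
    if value < 0.6:
        return "mediocre"
    if value <= 0.75:
        return "good"
    return "excellent"


def bootstrap_ci(statistic: Callable, subjects: Sequence, n_boot: int = 10000,
                 seed: int = 0, ci: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI of a cohort statistic.

    ``subjects`` is a sequence of per-subject data (each element carries
    that subject's full session pair, so pairs stay intact under
    resampling); ``statistic`` maps such a sequence to a scalar. Resamples
    on which the statistic raises or returns non-finite count as
    undefined; more than 50% undefined is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = np.random.default_rng(seed)
    n = len(subjects)
    vals = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic([subjects[i] for i in idx])
        except (ValueError, ZeroDivisionError, FloatingPointError):
            continue
        if np.isfinite(v):
            vals[b] = v
    bad = np.isnan(vals)
    if bad.mean() > 0.5:
        raise ValueError(
            f"statistic undefined on {bad.mean():.0%} of bootstrap resamples")
    good = vals[~bad]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(good, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def icc_bootstrap_ci(values: np.ndarray, n_boot: int = 10000, seed: int = 0,
                     ci: float = 0.95, model: str = "two_way_mixed"
                     ) -> tuple[float, float]:
    """Vectorized percentile bootstrap CI for the ICC of a subjects × k table."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _icc_from_tables(values[idx], model=model)
    bad = np.isnan(boot)
    if bad.mean() > 0.5:
        raise ValueError("ICC undefined on most bootstrap resamples")
    good = boot[~bad]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(good, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# cohort-level helpers operating on lists of ConnectivityMatrix

def pair_by_subject(matrices: Sequence[ConnectivityMatrix]
                    ) -> dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]]:
    """Group matrices into (session 1, session 2) pairs per subject.

    Subjects missing a session are dropped with a warning (they cannot
    enter a test-retest comparison).
    """
    by_subj: dict[str, dict[int, ConnectivityMatrix]] = {}
    for m in matrices:
        by_subj.setdefault(m.subject_id, {})[m.session_id] = m
    pairs = {}
    dropped = []
    for sid in sorted(by_subj):
        sessions = by_subj[sid]
        if 1 in sessions and 2 in sessions:
            pairs[sid] = (sessions[1], sessions[2])
        else:
            dropped.append(sid)
    if dropped:
        warnings.warn(
            f"dropping subjects missing a session: {dropped}", stacklevel=2)
    return pairs


def _common_labels(matrices: Sequence[ConnectivityMatrix]) -> list[str]:
    common = None
    for m in matrices:
        s = set(m.channel_labels)
        common = s if common is None else common & s
    if not common:
        raise ValueError("no channels common to all subjects")
    # keep the order of the first matrix
    return [lbl for lbl in matrices[0].channel_labels if lbl in common]


def _restrict(m: ConnectivityMatrix, labels: list[str]) -> np.ndarray:
    idx = [m.channel_labels.index(lbl) for lbl in labels]
    return m.values[np.ix_(idx, idx)]


def _edge_table(matrices: Sequence[ConnectivityMatrix]
                ) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Stack cohort matrices into (n_subjects, 2, n_edges) over common edges."""
    pairs = pair_by_subject(matrices)
    if not pairs:
        raise ValueError("no subject has both sessions")
    labels = _common_labels([m for p in pairs.values() for m in p])
    iu = np.triu_indices(len(labels), k=1)
    rows = []
    for sid, (m1, m2) in pairs.items():
        rows.append(np.stack([_restrict(m1, labels)[iu],
                              _restrict(m2, labels)[iu]]))
    values = np.stack(rows)  # (n_subj, 2, n_edges)
    edge_labels = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return values, sorted(pairs), edge_labels


def icc_global(matrices: Sequence[ConnectivityMatrix],
               n_boot: int = 1000, seed: int = 0,
               model: str = "two_way_mixed"
               ) -> tuple[float, tuple[float, float]]:
    """ICC of global connectivity across sessions, with bootstrap CI."""
    values, subjects, _ = _edge_table(matrices)
    table = values.mean(axis=-1)  # (n_subj, 2) global connectivity
    point = icc_table(table, subjects, model=model)
    ci = icc_bootstrap_ci(table, n_boot=n_boot, seed=seed, model=model)
    return point, ci


def icc_unitwise(matrices: Sequence[ConnectivityMatrix],
                 model: str = "two_way_mixed"
                 ) -> tuple[np.ndarray, list[tuple[str, str]], float]:
    """One ICC per edge over subjects; summary is the median.

    Returns ``(per_edge_icc, edge_labels, median)``. Edges whose ICC is
    undefined (degenerate across the cohort) come back as nan and are
    excluded from the median.
    """
    values, _, edge_labels = _edge_table(matrices)
    if values.shape[0] < 3:
        raise ValueError("need at least three complete subjects")
    per_edge = _icc_from_tables(np.moveaxis(values, -1, 0), model=model)
    med = float(np.nanmedian(per_edge))
    return per_edge, edge_labels, med


def top_percentile_edges(matrices: Sequence[ConnectivityMatrix],
                         percentile: float = 25.0) -> np.ndarray:
    """Mask of the strongest ``percentile``% of edges of the grand average.

    The grand-average matrix pools all subjects and both sessions; the mask
    holds ceil(percentile/100 × n_edges) edges, expanded to include every
    edge tied with the cutoff strength (a warning notes the expansion).
    Order matches the common-edge upper triangle of :func:`icc_unitwise`.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    values, _, _ = _edge_table(matrices)
    grand = values.mean(axis=(0, 1))  # per-edge grand average
    n_edges = grand.size
    n_top = int(np.ceil(percentile / 100.0 * n_edges))
    cutoff = np.sort(grand)[::-1][n_top - 1]
    mask = grand >= cutoff
    if mask.sum() > n_top:
        warnings.warn(
            f"{mask.sum() - n_top} edge(s) tied at the strength cutoff "
            "included beyond the nominal count", stacklevel=2)
    return mask


@dataclass
class ReliabilityReport:
    """Per band and method: the full three-level reliability summary."""

    band: str
    method: str
    n_subjects: int
    n_boot: int
    seed: int
    matrix_correlations: dict[str, float]
    icc_global: float
    icc_global_ci: tuple[float, float]
    cov: float
    cov_ci: tuple[float, float]
    unitwise_icc: np.ndarray
    unitwise_edges: list[tuple[str, str]]
    unitwise_median: float
    top_percentile: float
    top_mask: np.ndarray
    unitwise_median_top: float
    graph_icc: dict[str, tuple[float, tuple[float, float]]] = field(
        default_factory=dict)


def reliability_report(matrices: Sequence[ConnectivityMatrix],
                       n_boot: int = 1000, seed: int = 0,
                       percentile: float = 25.0,
                       model: str = "two_way_mixed",
                       cov_session: int = 1) -> ReliabilityReport:
    """All three reliability levels for one band's cohort of matrices."""
    values, subjects, edge_labels = _edge_table(matrices)
    pairs = pair_by_subject(matrices)
    band = matrices[0].band_name
    method = matrices[0].method

    corr = {}
    labels = _common_labels([m for p in pairs.values() for m in p])
    for sid, (m1, m2) in pairs.items():
        iu = np.triu_indices(len(labels), k=1)
        a, b = _restrict(m1, labels)[iu], _restrict(m2, labels)[iu]
        corr[sid] = float(np.corrcoef(a, b)[0, 1])

    table = values.mean(axis=-1)
    g_icc = icc_table(table, subjects, model=model)
    g_ci = icc_bootstrap_ci(table, n_boot=n_boot, seed=seed, model=model)

    sess_vals = table[:, cov_session - 1]
    g_cov = cov(sess_vals)
    rng = np.random.default_rng(seed + 1)
    idx = rng.integers(0, len(sess_vals), size=(n_boot, len(sess_vals)))
    boot = sess_vals[idx]
    cov_boot = boot.std(axis=1, ddof=1) / boot.mean(axis=1)
    cov_ci_ = tuple(float(v) for v in np.percentile(cov_boot, [2.5, 97.5]))

    per_edge, edges, med = icc_unitwise(matrices, model=model)
    mask = top_percentile_edges(matrices, percentile=percentile)
    med_top = float(np.nanmedian(per_edge[mask]))

    return ReliabilityReport(
        band=band, method=method, n_subjects=len(subjects), n_boot=n_boot,
        seed=seed, matrix_correlations=corr, icc_global=g_icc,
        icc_global_ci=g_ci, cov=g_cov, cov_ci=cov_ci_,
        unitwise_icc=per_edge, unitwise_edges=edges, unitwise_median=med,
        top_percentile=percentile, top_mask=mask,
        unitwise_median_top=med_top)


__all__.append("reliability_report")
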