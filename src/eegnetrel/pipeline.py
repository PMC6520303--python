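"""End-to-end orchestration: simulate → preprocess → connect → graph → reliability.

A :class:`RunConfig` fully determines a run: with the same config and seed,
exact stages (epoch selection, surrogate draws, bootstrap resamples)
reproduce bit-for-bit and float stages reproduce to numerical tolerance.
Stage order follows the analysis ladder: raw multichannel recordings are
resampled and broadband filtered, artifacts and bad channels handled (bad
channels are dropped from *both* sessions of a subject), each band is
filtered out of the continuous record, epochs are cut and sampled,
connectivity matrices computed per method, graph metrics derived from the
PLI matrices only (dwPLI can be negative and is excluded from graph
analysis), and the three-level reliability report assembled per band.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import DEFAULT_BANDS, CohortSpec, Recording, generate_cohort
from .connectivity import ConnectivityMatrix, connectivity_matrix
from .graph import GraphMetricsRecord, graph_metrics
from .io import graph_metrics_frame, matrices_long_frame, save_matrix
from .preprocess import (band_filter, broadband_filter, detect_artifacts,
                         detect_bad_channels, epoch_and_select,
                         harmonize_channels, resample)
from .reliability import (ReliabilityReport, icc_bootstrap_ci, icc_table,
                          reliability_report)

__all__ = ["RunConfig", "PipelineResult", "validate_config", "run_pipeline"]

log = logging.getLogger("eegnetrel")


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    # input: either a synthetic cohort spec or a directory of recordings
    source: str = "synthetic"          # "synthetic" | "directory"
    data_dir: str | None = None
    n_subjects: int = 20
    n_channels: int = 16
    sampling_rate: float = 512.0
    duration: float = 120.0
    subject_sd: float = 0.25
    session_stability: float = 0.8
    noise_sd: float = 0.5
    phase_lag: float = float(np.pi / 2)

    # preprocessing
    resample_to: float = 512.0
    broadband: tuple[float, float] = (0.1, 70.0)
    filter_order: int = 3
    jump_z: float = 8.0
    var_z: float = 4.0
    bands: tuple = DEFAULT_BANDS
    epoch_length: float = 5.0
    n_epochs: int = 20

    # connectivity / graphs / reliability
    methods: tuple[str, ...] = ("pli", "dwpli")
    n_surrogates: int = 100
    n_boot: int = 10000
    percentile: float = 25.0
    icc_model: str = "two_way_mixed"
    cov_session: int = 1

    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        d["broadband"] = list(self.broadband)
        d["methods"] = list(self.methods)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(tuple(b) for b in d["bands"])
        if "broadband" in d:
            d["broadband"] = tuple(d["broadband"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=self.n_subjects, n_channels=self.n_channels,
            sampling_rate=self.sampling_rate, duration=self.duration,
            bands=tuple(tuple(b) for b in self.bands),
            subject_sd=self.subject_sd,
            session_stability=self.session_stability,
            noise_sd=self.noise_sd, phase_lag=self.phase_lag, seed=self.seed)


def validate_config(config: RunConfig) -> list[str]:
    """All problems that would make the run fail; empty list iff runnable."""
    problems: list[str] = []
    if config.source not in ("synthetic", "directory"):
        problems.append(f"source: unknown value {config.source!r}")
    if config.source == "directory":
        if not config.data_dir:
            problems.append("data_dir: required when source='directory'")
        elif not Path(config.data_dir).is_dir():
            problems.append(f"data_dir: {config.data_dir!r} is not a directory")
    nyq = config.resample_to / 2.0
    lo, hi = config.broadband
    if not 0 < lo < hi < nyq:
        problems.append(
            f"broadband: need 0 < {lo} < {hi} < Nyquist ({nyq} Hz)")
    for name, blo, bhi in config.bands:
        if not 0 < blo < bhi:
            problems.append(f"band {name}: need 0 < low < high")
        elif bhi >= nyq:
            problems.append(
                f"band {name}: high edge {bhi} Hz at/above Nyquist ({nyq} Hz)")
    need = config.n_epochs * config.epoch_length
    if config.source == "synthetic" and config.duration < need:
        problems.append(
            f"n_epochs: {config.n_epochs} epochs of {config.epoch_length} s "
            f"need at least {need} s per recording, duration is "
            f"{config.duration} s")
    for m in config.methods:
        if m not in ("pli", "dwpli"):
            problems.append(f"methods: unknown method {m!r}")
    if not config.methods:
        problems.append("methods: at least one connectivity method required")
    if config.n_boot < 1:
        problems.append("n_boot: must be at least 1")
    if not 0 < config.percentile < 100:
        problems.append("percentile: must lie in (0, 100)")
    if config.icc_model not in ("two_way_mixed", "one_way"):
        problems.append(f"icc_model: unknown model {config.icc_model!r}")
    if config.cov_session not in (1, 2):
        problems.append("cov_session: must be 1 or 2")
    if not (0 <= config.session_stability <= 1):
        problems.append("session_stability: must lie in [0, 1]")
    if config.seed < 0:
        problems.append("seed: must be nonnegative")
    return problems


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    config: RunConfig
    matrices: list[ConnectivityMatrix]
    graph_records: list[GraphMetricsRecord]
    reports: dict[tuple[str, str], ReliabilityReport]  # (band, method) ->
    graph_icc: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict


def _acquire(config: RunConfig) -> list[Recording]:
    if config.source == "synthetic":
        return generate_cohort(config.cohort_spec())
    from .io import iter_recordings

    recs = list(iter_recordings(config.data_dir))
    if not recs:
        raise ValueError(f"no recordings found in {config.data_dir!r}")
    return recs


def _preprocess_subject(config: RunConfig, s1: Recording, s2: Recording,
                        manifest_entry: dict) -> list:
    """One subject's sessions → list of per-band BandEpochSets per session."""
    out = []
    masks = {}
    sessions = {}
    for rec in (s1, s2):
        if rec.sampling_rate > config.resample_to:
            rec = resample(rec, config.resample_to)
        rec = broadband_filter(rec, *config.broadband,
                               order=config.filter_order)
        masks[rec.session_id] = detect_artifacts(
            rec, jump_z=config.jump_z, var_z=config.var_z,
            epoch_length=config.epoch_length)
        sessions[rec.session_id] = rec
    bad1 = detect_bad_channels(sessions[1], masks[1])
    bad2 = detect_bad_channels(sessions[2], masks[2])
    keep_idx = {
        sess: [i for i, lbl in enumerate(sessions[sess].channel_labels)
               if lbl not in set(bad1) | set(bad2)]
        for sess in (1, 2)}
    h1, h2 = harmonize_channels(sessions[1], sessions[2], bad1, bad2)
    manifest_entry["removed_channels"] = sorted(set(bad1) | set(bad2))
    manifest_entry["retained_channels"] = len(h1.channel_labels)
    for rec, mask_full, sess in ((h1, masks[1], 1), (h2, masks[2], 2)):
        mask = mask_full[keep_idx[sess]]
        per_band = []
        for bi, (name, blo, bhi) in enumerate(config.bands):
            banded = band_filter(rec, blo, bhi, order=config.filter_order)
            sel_seed = int(np.random.SeedSequence(
                [config.seed, 7, _stable_hash(rec.subject_id), sess]
            ).generate_state(1)[0])
            eps = epoch_and_select(
                banded, epoch_length=config.epoch_length,
                n_select=config.n_epochs, seed=sel_seed,
                artifact_mask=mask, band_name=name)
            per_band.append(eps)
        manifest_entry.setdefault("n_epochs", {})[str(sess)] = config.n_epochs
        out.append(per_band)
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; optionally write artifacts under ``config.out_dir``."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(level=config.log_level)

    recordings = _acquire(config)
    by_subject: dict[str, dict[int, Recording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, {})[rec.session_id] = rec

    manifest: dict = {
        "config": config.to_dict(), "seed": config.seed,
        "version": __version__,
        "numpy": np.__version__, "subjects": {},
    }
    matrices: list[ConnectivityMatrix] = []
    for sid in sorted(by_subject):
        sessions = by_subject[sid]
        if set(sessions) != {1, 2}:
            log.warning("subject %s misses a session; skipped", sid)
            continue
        entry: dict = {}
        try:
            per_session = _preprocess_subject(config, sessions[1], sessions[2],
                                              entry)
        except ValueError as err:
            raise ValueError(f"preprocess: subject {sid}: {err}") from err
        manifest["subjects"][sid] = entry
        for band_sets in per_session:
            for eps in band_sets:
                for method in config.methods:
                    try:
                        matrices.append(connectivity_matrix(eps, method=method))
                    except ValueError as err:
                        raise ValueError(
                            f"connectivity: subject {sid} session "
                            f"{eps.session_id} band {eps.band_name}: {err}"
                        ) from err
        log.info("subject %s: connectivity done", sid)

    # graph metrics from PLI matrices only
    graph_records: list[GraphMetricsRecord] = []
    if "pli" in config.methods:
        for m in matrices:
            if m.method != "pli":
                continue
            gseed = int(np.random.SeedSequence(
                [config.seed, 11, _stable_hash(m.subject_id),
                 m.session_id, _stable_hash(m.band_name)]
            ).generate_state(1)[0])
            try:
                graph_records.append(
                    graph_metrics(m, n_surrogates=config.n_surrogates,
                                  seed=gseed))
            except ValueError as err:
                raise ValueError(
                    f"graph: subject {m.subject_id} session {m.session_id} "
                    f"band {m.band_name}: {err}") from err

    reports: dict[tuple[str, str], ReliabilityReport] = {}
    for method in config.methods:
        for name, _, _ in config.bands:
            sel = [m for m in matrices
                   if m.method == method and m.band_name == name]
            reports[(name, method)] = reliability_report(
                sel, n_boot=config.n_boot, seed=config.seed,
                percentile=config.percentile, model=config.icc_model,
                cov_session=config.cov_session)

    graph_icc = _graph_icc_frame(config, graph_records)
    summary = _summary_frame(reports, graph_icc)

    if config.out_dir:
        _write_artifacts(config, matrices, graph_records, reports, graph_icc,
                         summary, manifest)
    return PipelineResult(config=config, matrices=matrices,
                          graph_records=graph_records, reports=reports,
                          graph_icc=graph_icc, summary=summary,
                          manifest=manifest)


def _graph_icc_frame(config: RunConfig,
                     records: list[GraphMetricsRecord]) -> pd.DataFrame:
    """ICC (with CI) of each graph metric per band, from PLI graphs."""
    rows = []
    if not records:
        return pd.DataFrame(
            columns=["band", "metric", "icc", "ci_lo", "ci_hi"])
    df = graph_metrics_frame(records)
    for band, per_band in df.groupby("band", sort=False):
        wide = per_band.pivot(index="subject", columns="session")
        for metric in ("Cw", "Lw", "Cw_nrm", "Lw_nrm", "SWI"):
            table = wide[metric][[1, 2]].dropna().to_numpy()
            point = icc_table(table, model=config.icc_model)
            lo, hi = icc_bootstrap_ci(table, n_boot=config.n_boot,
                                      seed=config.seed,
                                      model=config.icc_model)
            rows.append((band, metric, point, lo, hi))
    return pd.DataFrame(rows, columns=["band", "metric", "icc",
                                       "ci_lo", "ci_hi"])


def _summary_frame(reports: dict, graph_icc: pd.DataFrame) -> pd.DataFrame:
    """Tidy run summary: one row per band × method × quantity."""
    rows = []
    for (band, method), rep in reports.items():
        rows += [
            (band, method, "icc_global", rep.icc_global,
             rep.icc_global_ci[0], rep.icc_global_ci[1]),
            (band, method, "cov_global", rep.cov, rep.cov_ci[0], rep.cov_ci[1]),
            (band, method, "icc_unitwise_median", rep.unitwise_median,
             np.nan, np.nan),
            (band, method, "icc_unitwise_median_top", rep.unitwise_median_top,
             np.nan, np.nan),
            (band, method, "matrix_correlation_median",
             float(np.median(list(rep.matrix_correlations.values()))),
             np.nan, np.nan),
        ]
    for _, r in graph_icc.iterrows():
        rows.append((r["band"], "pli", f"icc_{r['metric']}", r["icc"],
                     r["ci_lo"], r["ci_hi"]))
    return pd.DataFrame(rows, columns=["band", "method", "quantity", "value",
                                       "ci_lo", "ci_hi"])


def _write_artifacts(config, matrices, graph_records, reports, graph_icc,
                     summary, manifest) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices_long_frame(matrices).to_csv(out / "connectivity_long.csv",
                                         index=False)
    mat_dir = out / "matrices"
    for m in matrices:
        save_matrix(m, mat_dir)
    if graph_records:
        graph_metrics_frame(graph_records).to_csv(out / "graph_metrics.csv",
                                                  index=False)
        graph_icc.to_csv(out / "graph_icc.csv", index=False)
    summary.to_csv(out / "reliability_summary.csv", index=False)
    # per-edge ICC, long format
    edge_rows = []
    for (band, method), rep in reports.items():
        for (ci, cj), v, in_top in zip(rep.unitwise_edges, rep.unitwise_icc,
                                       rep.top_mask):
            edge_rows.append((band, method, ci, cj, float(v), bool(in_top)))
    pd.DataFrame(edge_rows, columns=[
        "band", "method", "chan_i", "chan_j", "icc", "top_percentile"
    ]).to_csv(out / "unitwise_icc.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _stable_hash(s: str) -> int:
    return sum(ord(c) * 31 ** i for i, c in enumerate(s)) % (2 ** 31)
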