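"""Reading and writing recordings, connectivity matrices and reports.

Recordings travel either as EDF/BDF (read through :mod:`mne`, optional
dependency) or as the package's own flat layout: a ``.npy`` matrix
(channels × samples) next to a JSON sidecar carrying subject, session,
sampling rate and channel labels. Connectivity matrices are written both as
square TSV files (one per subject-session-band-method) and as one tidy
long-format CSV per run.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Recording
from .connectivity import ConnectivityMatrix
from .graph import GraphMetricsRecord

__all__ = [
    "save_recording", "load_recording", "iter_recordings",
    "read_recording_edf",
    "save_matrix", "load_matrix", "iter_matrices",
    "matrices_long_frame", "graph_metrics_frame",
    "save_truth_csv",
]

_REC_RE = re.compile(r"^(?P<subject>.+)_s(?P<session>\d+)\.npy$")
_MAT_RE = re.compile(
    r"^(?P<subject>.+)_s(?P<session>\d+)_(?P<band>[^_]+)_(?P<method>pli|dwpli)\.tsv$")


def save_recording(rec: Recording, directory) -> Path:
    """Write ``<subject>_s<session>.npy`` plus a JSON sidecar; returns the npy path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_s{rec.session_id}"
    npy = directory / f"{stem}.npy"
    np.save(npy, rec.data)
    sidecar = {
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "sampling_rate": rec.sampling_rate,
        "channel_labels": rec.channel_labels,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return npy


def load_recording(npy_path) -> Recording:
    npy_path = Path(npy_path)
    sidecar = json.loads(npy_path.with_suffix(".json").read_text())
    return Recording(subject_id=sidecar["subject_id"],
                     session_id=int(sidecar["session_id"]),
                     data=np.load(npy_path),
                     sampling_rate=float(sidecar["sampling_rate"]),
                     channel_labels=list(sidecar["channel_labels"]))


def iter_recordings(directory) -> Iterable[Recording]:
    """All recordings in a directory: flat .npy+sidecar and EDF/BDF files."""
    directory = Path(directory)
    for path in sorted(directory.iterdir()):
        if _REC_RE.match(path.name):
            yield load_recording(path)
        elif path.suffix.lower() in (".edf", ".bdf"):
            yield read_recording_edf(path)


def _parse_subject_session(name: str) -> tuple[str, int]:
    m = re.match(r"^(?P<subject>.+?)[_-]s(?:es)?(?P<session>\d+)$", name)
    if not m:
        raise ValueError(
            f"cannot parse subject/session from {name!r}; expected "
            "'<subject>_s<session>' (e.g. sub001_s1.edf)")
    return m.group("subject"), int(m.group("session"))


def read_recording_edf(path, subject_id: str | None = None,
                       session_id: int | None = None) -> Recording:
    """Read an EDF/BDF file into a :class:`Recording` (requires mne)."""
    import mne  # optional dependency, imported lazily

    path = Path(path)
    reader = (mne.io.read_raw_bdf if path.suffix.lower() == ".bdf"
              else mne.io.read_raw_edf)
    raw = reader(path, preload=True, verbose="error")
    if subject_id is None or session_id is None:
        subject_id, session_id = _parse_subject_session(path.stem)
    return Recording(subject_id=subject_id, session_id=session_id,
                     data=raw.get_data(), sampling_rate=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


def save_matrix(m: ConnectivityMatrix, directory) -> Path:
    """Square TSV with channel labels as header/index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / (f"{m.subject_id}_s{m.session_id}_{m.band_name}"
                        f"_{m.method}.tsv")
    pd.DataFrame(m.values, index=m.channel_labels,
                 columns=m.channel_labels).to_csv(path, sep="\t")
    return path


def load_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    m = _MAT_RE.match(path.name)
    if not m:
        raise ValueError(f"unrecognized matrix filename {path.name!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        subject_id=m.group("subject"), session_id=int(m.group("session")),
        band_name=m.group("band"), method=m.group("method"),
        values=df.to_numpy(), channel_labels=list(df.columns), n_epochs=0)


def iter_matrices(directory) -> Iterable[ConnectivityMatrix]:
    directory = Path(directory)
    for path in sorted(directory.glob("*.tsv")):
        if _MAT_RE.match(path.name):
            yield load_matrix(path)


def matrices_long_frame(matrices: Sequence[ConnectivityMatrix]) -> pd.DataFrame:
    """Tidy long format: subject, session, band, method, chan_i, chan_j, value."""
    rows = []
    for m in matrices:
        iu = np.triu_indices(m.n_channels, k=1)
        for i, j in zip(*iu):
            rows.append((m.subject_id, m.session_id, m.band_name, m.method,
                         m.channel_labels[i], m.channel_labels[j],
                         float(m.values[i, j])))
    return pd.DataFrame(rows, columns=[
        "subject", "session", "band", "method", "chan_i", "chan_j", "value"])


def graph_metrics_frame(records: Sequence[GraphMetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject": r.subject_id, "session": r.session_id, "band": r.band_name,
        "Cw": r.Cw, "Lw": r.Lw, "Cw_nrm": r.Cw_nrm, "Lw_nrm": r.Lw_nrm,
        "SWI": r.SWI, "n_surrogates": r.n_surrogates, "seed": r.surrogate_seed,
    } for r in records])


def save_truth_csv(truth: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False)
    return path
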