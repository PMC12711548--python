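"""Readers and writers for recordings and result tables.

The canonical on-disk recording format is a delimited sample matrix
(``<stem>.tsv``, samples as rows, one column per channel) with a JSON
sidecar (``<stem>.json``) carrying the sampling rate, channel names and
block annotations in seconds.  EDF files can be read when ``mne`` is
installed (``pip install respconn[edf]``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import Annotation, Recording

SIDECAR_FIELDS = ("sampling_rate", "channel_names", "annotations")


def write_recording(recording: Recording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` (samples x channels) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    data_path = stem.with_suffix(".tsv")
    sidecar_path = stem.with_suffix(".json")
    df = pd.DataFrame(recording.data.T, columns=list(recording.channel_names))
    df.to_csv(data_path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "sampling_rate": recording.fs,
        "channel_names": list(recording.channel_names),
        "annotations": [
            {
                "condition": a.condition,
                "start_s": a.start / recording.fs,
                "end_s": a.stop / recording.fs,
            }
            for a in recording.annotations
        ],
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return data_path, sidecar_path


def _read_sidecar(path: Path) -> dict:
    try:
        sidecar = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"sidecar {path} is not valid JSON: {exc}") from exc
    for fld in SIDECAR_FIELDS:
        if fld not in sidecar:
            raise ValueError(f"sidecar {path} is missing required field {fld!r}")
    return sidecar


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording from delimited+sidecar (default) or EDF.

    ``fmt`` may be ``"delimited"`` or ``"edf"``; when omitted it is inferred
    from the suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return _read_edf(path)
    if fmt != "delimited":
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = _read_sidecar(path.with_suffix(".json"))
    df = pd.read_csv(path.with_suffix(".tsv"), sep="\t")
    names = sidecar["channel_names"]
    if list(df.columns) != list(names):
        raise ValueError(
            f"channel mismatch: sidecar lists {names}, data columns are {list(df.columns)}"
        )
    fs = float(sidecar["sampling_rate"])
    anns = [
        Annotation(a["condition"], int(round(a["start_s"] * fs)), int(round(a["end_s"] * fs)))
        for a in sidecar["annotations"]
    ]
    return Recording(df.to_numpy().T, fs, tuple(names), anns)


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the 'edf' extra (pip install respconn[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    anns = [
        Annotation(d, int(round(o * fs)), int(round((o + du) * fs)))
        for d, o, du in zip(
            raw.annotations.description, raw.annotations.onset, raw.annotations.duration
        )
    ]
    if not anns:
        raise ValueError(f"EDF file {path} carries no block annotations")
    return Recording(data, fs, tuple(raw.ch_names), anns)


def write_matrix(values: np.ndarray, channel_names, path: str | Path) -> Path:
    """Square connectivity matrix as a labelled TSV."""
    path = Path(path)
    pd.DataFrame(values, index=list(channel_names), columns=list(channel_names)).to_csv(
        path, sep="\t", float_format="%.6f"
    )
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.columns)


def write_cohort_manifest(subjects, seeds, path: str | Path) -> Path:
    """Cohort manifest (subject_id, fvc, seed)."""
    path = Path(path)
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "fvc": [s.fvc if s.fvc is not None else np.nan for s in subjects],
            "seed": seeds,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
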