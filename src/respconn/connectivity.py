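"""Phase-locking value (PLV) functional connectivity.

The PLV between two channels is the modulus of the time-averaged unit
phasor of their instantaneous phase difference, with phases taken from the
analytic signal (Hilbert transform) of band-limited data: 0 means no phase
coupling, 1 perfect locking.  Matrices are computed per segment and
averaged across a condition's segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .preprocessing import ConditionBlocks


@dataclass
class ConnectivityMatrix:
    """Symmetric PLV matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    band: str
    condition: str
    subject_id: str = ""
    n_samples: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PLV matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("PLV values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("PLV diagonal must be 1")
        self.values = v


def instantaneous_phase(segment: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) per channel via the analytic signal."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if np.any(segment.std(axis=-1) == 0):
        raise ValueError("constant (zero-variance) channel has no defined phase")
    return np.angle(hilbert(segment, axis=-1))


def plv_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLV = | mean_t exp(i (phi_a(t) - phi_b(t))) |."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    if phase_a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.exp(1j * (phase_a - phase_b)).mean()))


def _plv_from_phases(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLV from a channels x samples phase matrix."""
    z = np.exp(1j * phases)
    m = np.abs(z @ z.conj().T) / phases.shape[-1]
    return np.clip(m, 0.0, 1.0)


def plv_matrix(
    blocks: ConditionBlocks,
    condition: str,
    band: str,
    subject_id: str = "",
    edge_trim: float = 0.05,
) -> ConnectivityMatrix:
    """Segment-averaged PLV matrix for one (condition, band).

    ``edge_trim`` discards that fraction of samples at each end of every
    segment's phase series before averaging, suppressing Hilbert transform
    edge effects.
    """
    try:
        segs = blocks.segments[condition][band]
    except KeyError:
        raise ValueError(f"no segments for condition {condition!r}, band {band!r}") from None
    if not segs:
        raise ValueError(f"no segments for condition {condition!r}, band {band!r}")
    mats, n_used = [], 0
    for seg in segs:
        phases = instantaneous_phase(seg)
        trim = int(round(edge_trim * phases.shape[-1]))
        if trim:
            phases = phases[:, trim:-trim]
        n_used += phases.shape[-1]
        mats.append(_plv_from_phases(phases))
    values = np.mean(mats, axis=0)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values, band, condition, subject_id, n_used)


def plv_matrices(blocks: ConditionBlocks, subject_id: str = "", edge_trim: float = 0.05):
    """All (condition, band) PLV matrices for one subject."""
    out: dict[tuple[str, str], ConnectivityMatrix] = {}
    for cond, per_band in blocks.segments.items():
        for band in per_band:
            out[(cond, band)] = plv_matrix(blocks, cond, band, subject_id, edge_trim)
    return out


def vectorize_matrix(values: np.ndarray, mode: str = "unique") -> np.ndarray:
    """Flatten a square connectivity matrix into a feature vector.

    ``"unique"`` takes the strictly-upper-triangle entries (120 for 16
    channels); ``"full"`` flattens the whole matrix (256 entries for 16
    channels, diagonal included) — statistically redundant but provided to
    reproduce full-matrix test-family arithmetic.
    """
    values = np.asarray(values, dtype=float)
    if mode == "unique":
        return values[np.triu_indices(values.shape[0], k=1)]
    if mode == "full":
        return values.ravel()
    raise ValueError(f"unknown vectorization mode {mode!r}")


def edge_labels(channel_names, mode: str = "unique") -> list[str]:
    """Edge names matching :func:`vectorize_matrix` ordering."""
    names = list(channel_names)
    if mode == "unique":
        iu = np.triu_indices(len(names), k=1)
        return [f"{names[i]}-{names[j]}" for i, j in zip(*iu)]
    if mode == "full":
        return [f"{a}-{b}" for a in names for b in names]
    raise ValueError(f"unknown vectorization mode {mode!r}")


def edge_table(conn: ConnectivityMatrix, channel_names) -> pd.DataFrame:
    """Long-format edge listing (subject, condition, band, ch_i, ch_j, plv)."""
    names = list(channel_names)
    iu = np.triu_indices(len(names), k=1)
    return pd.DataFrame(
        {
            "subject": conn.subject_id,
            "condition": conn.condition,
            "band": conn.band,
            "ch_i": [names[i] for i in iu[0]],
            "ch_j": [names[j] for j in iu[1]],
            "plv": conn.values[iu],
        }
    )
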