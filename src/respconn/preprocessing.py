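"""Deterministic cleaning and band decomposition of annotated EEG recordings.

The pipeline assumes ocular/muscle artifacts have already been removed from
real recordings; what remains here is broadband band-pass filtering,
amplitude-based channel rejection, baseline correction anchored at block
onsets, and the split of a continuous run into per-condition, per-band
segment sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

CONDITIONS = ("SB", "BH", "PB")

#: Fixed 16-channel montage used throughout.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "T7", "T8",
    "C3", "C4", "P3", "P4", "P7", "P8", "O1", "O2",
)


@dataclass(frozen=True)
class BandDefinition:
    """Canonical frequency band, lower edge inclusive, upper edge exclusive.

    The half-open convention makes the delta/theta/alpha/beta table a
    partition of 1-30 Hz despite the shared printed endpoints (4, 8, 13 Hz).
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, freq: float) -> bool:
        return self.lo <= freq < self.hi


#: Delta/theta/alpha/beta; gamma (31-45 Hz) deliberately excluded.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass(frozen=True)
class Annotation:
    """Half-open, 0-based sample interval labelled with a condition."""

    condition: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"annotation {self.condition!r}: empty interval [{self.start}, {self.stop})")


@dataclass
class Recording:
    """Multichannel EEG: channels x samples, microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
        One unique label per row of ``data``.
    annotations : list of Annotation
        Sorted, non-overlapping block labels covering the conditions.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        prev_stop = 0
        for ann in self.annotations:
            if ann.start < prev_stop:
                raise ValueError("annotations must be sorted and non-overlapping")
            if ann.stop > self.n_samples:
                raise ValueError(f"annotation [{ann.start}, {ann.stop}) exceeds recording length")
            prev_stop = ann.stop

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, names: Sequence[str]) -> "Recording":
        idx = [self.channel_names.index(n) for n in names]
        return Recording(self.data[idx], self.fs, tuple(names), list(self.annotations))


@dataclass
class ConditionBlocks:
    """Per-condition segment sets, broadband and band-filtered.

    ``broadband[cond]`` holds the baseline-corrected 1-45 Hz segments (one
    per annotated block, original block length); ``segments[cond][band]``
    holds the same segments narrow-band filtered.  ``provenance`` records
    filter settings and rejected channels for the manifest.
    """

    broadband: dict[str, list[np.ndarray]]
    segments: dict[str, dict[str, list[np.ndarray]]]
    channel_names: tuple[str, ...]
    fs: float
    provenance: dict = field(default_factory=dict)

    def conditions(self) -> tuple[str, ...]:
        return tuple(self.broadband)


def _butter_sos(fs: float, lo: float, hi: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got [{lo}, {hi}]")
    if hi > nyq:
        raise ValueError(f"upper edge {hi} Hz exceeds Nyquist {nyq} Hz")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_array(data: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    sos = _butter_sos(fs, lo, hi, order)
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def bandpass(recording: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Band-pass every channel of a recording, preserving length and annotations."""
    out = bandpass_array(recording.data, recording.fs, lo, hi, order)
    return Recording(out, recording.fs, recording.channel_names, list(recording.annotations))


def reject_channels(
    recording: Recording,
    epoch_len: float = 2.0,
    amplitude: float = 100.0,
    fraction: float = 0.20,
) -> tuple[Recording, list[str]]:
    """Drop channels exceeding ``+-amplitude`` microvolts in more than ``fraction`` of epochs.

    The recording is tiled into non-overlapping epochs of ``epoch_len``
    seconds (a trailing partial epoch is ignored); an epoch counts against a
    channel when any sample magnitude exceeds ``amplitude``.  The share must
    strictly exceed ``fraction`` for rejection; no interpolation is applied.
    """
    if epoch_len <= 0:
        raise ValueError("epoch_len must be positive")
    n_epoch = int(round(epoch_len * recording.fs))
    n_full = recording.n_samples // n_epoch
    if n_full == 0:
        raise ValueError("recording shorter than one rejection epoch")
    tiled = recording.data[:, : n_full * n_epoch].reshape(recording.n_channels, n_full, n_epoch)
    bad_epochs = (np.abs(tiled) > amplitude).any(axis=2)  # channels x epochs
    share = bad_epochs.mean(axis=1)
    rejected = [name for name, s in zip(recording.channel_names, share) if s > fraction]
    keep = [name for name in recording.channel_names if name not in rejected]
    if not keep:
        raise ValueError("all channels rejected")
    return recording.pick(keep), rejected


def baseline_correct(
    segment: np.ndarray,
    fs: float,
    window: tuple[float, float] = (-200.0, 0.0),
    onset: int = 0,
) -> np.ndarray:
    """Subtract the per-channel mean of a pre-onset window from a whole segment.

    ``window`` is in milliseconds relative to the sample index ``onset``
    within ``segment`` (rows are channels).  With the default (-200, 0) ms
    the 200 ms immediately preceding the onset define the baseline.  When
    the window would start before the segment it is clamped; if that leaves
    it empty the first ``|window|`` samples after the onset are used instead
    (the only case is a block at the very start of a run).
    """
    segment = np.asarray(segment, dtype=float)
    lo = onset + int(round(window[0] * fs / 1000.0))
    hi = onset + int(round(window[1] * fs / 1000.0))
    if hi <= lo:
        raise ValueError("baseline window contains zero samples")
    width = hi - lo
    if lo < 0:
        lo, hi = 0, min(width, segment.shape[-1])
    if hi > segment.shape[-1] or hi <= lo:
        raise ValueError("baseline window outside segment")
    base = segment[..., lo:hi].mean(axis=-1, keepdims=True)
    return segment - base


def split_conditions_and_bands(
    recording: Recording,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    required_conditions: Sequence[str] = CONDITIONS,
    filter_order: int = 4,
    rejected_channels: Sequence[str] = (),
) -> ConditionBlocks:
    """Extract annotated blocks, baseline-correct at block onset, filter per band.

    Baseline means are taken from the continuous recording over the window
    preceding each block onset (see :func:`baseline_correct` for the run
    start).  Band filtering is applied per extracted block after baseline
    correction, so each band segment keeps the source block length.
    """
    if not recording.annotations:
        raise ValueError("recording has no block annotations")
    present = {a.condition for a in recording.annotations}
    missing = [c for c in required_conditions if c not in present]
    if missing:
        raise ValueError(f"no blocks annotated for condition(s): {', '.join(missing)}")

    width = int(round((baseline_window[1] - baseline_window[0]) * recording.fs / 1000.0))
    broadband: dict[str, list[np.ndarray]] = {}
    segments: dict[str, dict[str, list[np.ndarray]]] = {}
    for ann in recording.annotations:
        block = recording.data[:, ann.start : ann.stop]
        base_lo = ann.start + int(round(baseline_window[0] * recording.fs / 1000.0))
        base_hi = ann.start + int(round(baseline_window[1] * recording.fs / 1000.0))
        if base_lo < 0:  # run start: no pre-onset context
            base_lo, base_hi = ann.start, ann.start + width
        base = recording.data[:, base_lo:base_hi].mean(axis=1, keepdims=True)
        corrected = block - base
        broadband.setdefault(ann.condition, []).append(corrected)
        per_band = segments.setdefault(ann.condition, {b.name: [] for b in bands})
        for b in bands:
            per_band[b.name].append(bandpass_array(corrected, recording.fs, b.lo, b.hi, filter_order))

    provenance = {
        "filter": {"family": "butterworth", "order": filter_order, "zero_phase": True},
        "bands": {b.name: (b.lo, b.hi) for b in bands},
        "baseline_window_ms": tuple(baseline_window),
        "rejected_channels": list(rejected_channels),
    }
    return ConditionBlocks(broadband, segments, recording.channel_names, recording.fs, provenance)
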