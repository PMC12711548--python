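"""Welch power spectral density and band-averaged log power.

Spectra are estimated with Welch's averaged modified periodogram using a
128-sample Hamming window, 50% overlap and zero-padding to 256 points.
Note that at 500 Hz this grid has a step of 500/256 ~= 1.95 Hz (recorded in
``PsdEstimate.params``); band power is the mean over in-band bins followed
by a log transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocessing import BandDefinition, ConditionBlocks, DEFAULT_BANDS


@dataclass
class PsdEstimate:
    """One-sided PSD per channel: ``power`` is channels x frequencies (uV^2/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


def welch_psd(
    segment: np.ndarray,
    fs: float,
    window_len: int = 128,
    overlap: float = 0.5,
    nfft: int = 256,
) -> PsdEstimate:
    """Welch PSD of a channels x samples segment (one-sided density scaling)."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[-1] < window_len:
        raise ValueError(
            f"segment of {segment.shape[-1]} samples shorter than window ({window_len})"
        )
    noverlap = int(round(window_len * overlap))
    freqs, power = signal.welch(
        segment,
        fs=fs,
        window="hamming",
        nperseg=window_len,
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    params = {
        "window": "hamming",
        "window_len": window_len,
        "overlap": overlap,
        "nfft": nfft,
        "resolution_hz": fs / nfft,
    }
    return PsdEstimate(freqs, power, params)


def band_log_power(psd: PsdEstimate, band: BandDefinition, log_base: float = 10.0) -> np.ndarray:
    """Mean in-band power per channel, log-transformed (base 10 by default)."""
    mask = (psd.frequencies >= band.lo) & (psd.frequencies < band.hi)
    if not mask.any():
        raise ValueError(f"no frequency bins fall inside band {band.name!r}")
    mean_power = psd.power[..., mask].mean(axis=-1)
    if log_base == 10.0:
        return np.log10(mean_power)
    return np.log(mean_power) / np.log(log_base)


def band_power_table(
    blocks: ConditionBlocks,
    bands=DEFAULT_BANDS,
    subject_id: str = "",
    window_len: int = 128,
    overlap: float = 0.5,
    nfft: int = 256,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Long-format log band power per (subject, condition, band, channel).

    Per-segment band power is averaged across a condition's segments
    (epochs) first, then log-transformed.
    """
    rows = []
    for cond, segs in blocks.broadband.items():
        per_seg = []
        for seg in segs:
            psd = welch_psd(seg, blocks.fs, window_len, overlap, nfft)
            per_seg.append(
                {b.name: psd.power[..., (psd.frequencies >= b.lo) & (psd.frequencies < b.hi)].mean(axis=-1) for b in bands}
            )
        for b in bands:
            mean_power = np.mean([p[b.name] for p in per_seg], axis=0)
            logp = np.log10(mean_power) if log_base == 10.0 else np.log(mean_power) / np.log(log_base)
            for ch, v in zip(blocks.channel_names, logp):
                rows.append(
                    {
                        "subject": subject_id,
                        "condition": cond,
                        "band": b.name,
                        "channel": ch,
                        "log_power": float(v),
                    }
                )
    return pd.DataFrame(rows)
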