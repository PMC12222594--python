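"""Minimal EEG conditioning on already-clean data.

Filtering follows one convention throughout: 3rd-order Butterworth designed
for 3 dB attenuation at the cutoff, applied zero-phase via forward and
backward passes (net 6 dB at cutoff). The artifact-decomposition stage that
a real-recording pipeline would run here (ICA, bad-channel interpolation)
is represented by an explicit pass-through so the stage order stays visible.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ContinuousRecording

__all__ = [
    "bandpass",
    "lowpass",
    "lowpass30",
    "decimate_recording",
    "rereference",
    "artifact_stage_passthrough",
    "normalize_eeg",
]

logger = logging.getLogger(__name__)


def _filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(rec: ContinuousRecording, lo: float = 1.0, hi: float = 45.0) -> ContinuousRecording:
    """Zero-phase 3rd-order Butterworth band-pass per channel."""
    if hi >= rec.fs / 2:
        raise ValueError(f"hi={hi} must be below Nyquist ({rec.fs / 2})")
    if lo <= 0 or lo >= hi:
        raise ValueError("need 0 < lo < hi")
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(data=_filtfilt(sos, rec.data))


def lowpass(rec: ContinuousRecording, cutoff: float) -> ContinuousRecording:
    """Zero-phase 3rd-order Butterworth low-pass per channel."""
    if cutoff >= rec.fs / 2:
        raise ValueError(f"cutoff={cutoff} must be below Nyquist ({rec.fs / 2})")
    sos = signal.butter(3, cutoff, btype="low", fs=rec.fs, output="sos")
    return rec.copy_with(data=_filtfilt(sos, rec.data))


def lowpass30(rec: ContinuousRecording) -> ContinuousRecording:
    """The 30 Hz low-pass applied before ERP segmentation."""
    return lowpass(rec, 30.0)


def decimate_recording(rec: ContinuousRecording, fs_out: float = 256.0) -> ContinuousRecording:
    """Anti-aliased rational resampling (e.g. 512 -> 256 Hz)."""
    if fs_out > rec.fs:
        raise ValueError("decimation cannot increase the sampling rate")
    if fs_out == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    frac = Fraction(fs_out / rec.fs).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=data, fs=fs_out)


def rereference(rec: ContinuousRecording, reference_channels: list[str]) -> ContinuousRecording:
    """Subtract the mean of the reference channels from every channel."""
    if not reference_channels:
        raise ValueError("need at least one reference channel")
    idx = [rec.channel_index(name) for name in reference_channels]
    ref = rec.data[idx].mean(axis=0)
    return rec.copy_with(
        data=rec.data - ref[None, :],
        reference="average:" + "+".join(reference_channels),
    )


def artifact_stage_passthrough(rec: ContinuousRecording) -> ContinuousRecording:
    """No-op stand-in for decomposition-based artifact removal.

    Synthetic and pre-cleaned recordings need no component rejection; the
    stage exists so pipelines on real data can swap in a real cleaner
    without reordering the chain.
    """
    logger.info("artifact decomposition stage skipped (input treated as clean)")
    return rec


def normalize_eeg(recordings: list[ContinuousRecording]) -> list[ContinuousRecording]:
    """Center each channel and divide by one pooled standard deviation.

    Each channel of each trial is centered to 0 uV, then all amplitude
    values across all channels and trials are divided by their single
    pooled (population) standard deviation, so the pooled std of the output
    is exactly 1.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    centered = [r.data - r.data.mean(axis=1, keepdims=True) for r in recordings]
    pool = np.concatenate([c.ravel() for c in centered])
    sigma = float(pool.std())
    if sigma == 0:
        raise ValueError("degenerate pool: zero variance")
    return [
        rec.copy_with(data=c / sigma) for rec, c in zip(recordings, centered)
    ]
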