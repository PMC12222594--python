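"""Acoustic envelope extraction: gammatone subbands to onset envelopes.

The chain converts a speech waveform into a broadband envelope
(128 gammatone subbands between 100 and 8000 Hz, Hilbert magnitude per
band, power-law compression x**0.3, mean across bands) and then into an
onset envelope (25 Hz zero-phase lowpass, first difference, half-wave
rectification), finally decimated to the 256 Hz analysis rate.

Gammatone realisation: scipy's 4th-order IIR gammatone (Slaney/Patterson
lineage) with ERB-rate spaced center frequencies. Filters are designed per
center frequency and applied as plain forward IIR passes; the subsequent
Hilbert-magnitude step discards their phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import OnsetEnvelope

__all__ = [
    "SubbandSet",
    "erb_space",
    "gammatone_filterbank",
    "broadband_envelope",
    "onset_envelope",
    "decimate_envelope",
    "normalize_envelope",
    "audio_to_onset_envelope",
]

# Glasberg & Moore ERB-rate constants (Slaney's implementation)
_EAR_Q = 9.26449
_MIN_BW = 24.7


@dataclass
class SubbandSet:
    """Bandpassed subband signals (bands x samples) with their centers."""

    data: np.ndarray
    center_frequencies: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.center_frequencies = np.asarray(self.center_frequencies, dtype=float)
        if self.data.shape[0] != self.center_frequencies.size:
            raise ValueError("one center frequency per band required")
        if np.any(np.diff(self.center_frequencies) <= 0):
            raise ValueError("center frequencies must strictly increase")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]


def erb_space(f_lo: float, f_hi: float, n_bands: int) -> np.ndarray:
    """ERB-rate spaced center frequencies, ascending from ``f_lo``.

    Slaney's ERBSpace convention: ``f_lo`` is the lowest center frequency
    and ``f_hi`` the upper band edge, so the topmost center sits one
    ERB-rate step below ``f_hi``.
    """
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("need 0 < f_lo < f_hi")
    ear_q, min_bw = _EAR_Q, _MIN_BW
    idx = np.arange(n_bands, 0, -1)  # ascending centers
    cf = -(ear_q * min_bw) + np.exp(
        idx * (-np.log(f_hi + ear_q * min_bw) + np.log(f_lo + ear_q * min_bw))
        / n_bands
    ) * (f_hi + ear_q * min_bw)
    return cf


def gammatone_filterbank(
    audio: np.ndarray,
    fs: float,
    n_bands: int = 128,
    f_lo: float = 100.0,
    f_hi: float = 8000.0,
) -> SubbandSet:
    """Decompose audio into gammatone subbands.

    Requires ``fs >= 2 * f_hi`` so the highest band is representable.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if fs < 2 * f_hi:
        raise ValueError(f"fs={fs} too low for f_hi={f_hi} (need fs >= 2*f_hi)")
    centers = erb_space(f_lo, f_hi, n_bands)
    out = np.empty((n_bands, audio.size))
    for i, cf in enumerate(centers):
        b, a = signal.gammatone(cf, "iir", fs=fs)
        out[i] = signal.lfilter(b, a, audio)
    return SubbandSet(out, centers, fs)


def broadband_envelope(subbands: SubbandSet, exponent: float = 0.3) -> np.ndarray:
    """Mean across bands of the power-law-compressed Hilbert magnitudes.

    The analytic signal is computed per band over the whole series
    (frequency-domain Hilbert transform); edges are trimmed downstream.
    """
    analytic = signal.hilbert(subbands.data, axis=1)
    return np.mean(np.abs(analytic) ** exponent, axis=0)


def onset_envelope(broadband: np.ndarray, fs: float) -> np.ndarray:
    """Half-wave-rectified first difference of the 25 Hz lowpassed envelope.

    The Butterworth lowpass (3rd order, 3 dB at cutoff) is applied zero-phase
    via forward and backward passes. The first difference is taken without
    rate scaling: the downstream threshold is in pooled-sigma units and is
    invariant to a global scale factor. Output length equals input length
    (the leading difference sample is 0).
    """
    x = np.asarray(broadband, dtype=float).ravel()
    if fs <= 50:
        raise ValueError("fs must exceed 50 Hz for a 25 Hz lowpass")
    sos = signal.butter(3, 25.0, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * 3 + 1)
    if x.size <= padlen:
        raise ValueError("series shorter than filter warm-up")
    smooth = signal.sosfiltfilt(sos, x)
    diff = np.diff(smooth, prepend=smooth[0])
    return np.clip(diff, 0.0, None)


def decimate_envelope(series: np.ndarray, fs_in: float, fs_out: float = 256.0) -> np.ndarray:
    """Anti-aliased rational resampling from ``fs_in`` to ``fs_out``.

    Upsampling is rejected; ``fs_in == fs_out`` is the identity.
    """
    x = np.asarray(series, dtype=float).ravel()
    if fs_out > fs_in:
        raise ValueError("decimation cannot increase the sampling rate")
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def normalize_envelope(envelopes: list[np.ndarray]) -> list[np.ndarray]:
    """Divide every envelope by the pooled standard deviation.

    One population standard deviation is computed over the concatenation of
    all samples of all provided envelopes (all conditions and trials of a
    subject), and every sample is divided by it. The pooled std of the
    output is exactly 1.
    """
    if not envelopes:
        raise ValueError("need at least one envelope")
    pool = np.concatenate([np.asarray(e, dtype=float).ravel() for e in envelopes])
    sigma = float(pool.std())
    if sigma == 0:
        raise ValueError("degenerate pool: zero variance")
    return [np.asarray(e, dtype=float) / sigma for e in envelopes]


def audio_to_onset_envelope(
    audio: np.ndarray,
    fs: float,
    n_bands: int = 128,
    f_lo: float = 100.0,
    f_hi: float = 8000.0,
    exponent: float = 0.3,
    fs_out: float = 256.0,
    source_id: str = "",
) -> OnsetEnvelope:
    """Full chain: audio -> subbands -> broadband -> onset envelope @ fs_out."""
    subbands = gammatone_filterbank(audio, fs, n_bands, f_lo, f_hi)
    broad = broadband_envelope(subbands, exponent)
    onset = onset_envelope(broad, fs)
    dec = decimate_envelope(onset, fs, fs_out)
    return OnsetEnvelope(np.clip(dec, 0.0, None), fs_out, source_id=source_id)
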