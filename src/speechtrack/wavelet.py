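"""Analytic generalized Morse wavelets, instantaneous phase and WPSS.

The Morse family psi_{gamma, beta} is constructed directly in the frequency
domain as omega**beta * exp(-omega**gamma) on the positive frequencies only,
which makes the kernels exactly analytic (zero response at all negative
DFT bins). The default family (gamma=3, beta=3.29) maximises time-frequency
symmetry with a nearly minimal Heisenberg area and carries one full
oscillation cycle of the peak frequency within its central energy window
(sqrt(beta*gamma)/pi ~= 1.00 cycles).

The wavelet phase synchronization stability (WPSS; also known as the
phase-locking factor or inter-trial phase coherence) at a time-frequency
cell is the mean resultant vector length of the unit vectors given by the
instantaneous phases across sweeps: 1 for perfect phase locking, 0 for full
desynchronization. It is invariant to per-sweep amplitude scaling and to a
common phase rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

__all__ = [
    "MorseFamily",
    "morse_wavelet",
    "cwt",
    "cwt_sweeps",
    "instantaneous_phase",
    "wpss",
    "wpss_from_sweeps",
    "WpssMap",
    "band_window_mean",
]

logger = logging.getLogger(__name__)


def _geometric_frequencies(f_lo: float, f_hi: float, voices_per_octave: int) -> np.ndarray:
    n_octaves = np.log2(f_hi / f_lo)
    n = int(round(n_octaves * voices_per_octave)) + 1  # inclusive endpoints
    return f_lo * 2.0 ** (np.arange(n) / voices_per_octave)


@dataclass(frozen=True)
class MorseFamily:
    """A scale grid of generalized Morse wavelets.

    Default grid: 17 voices per octave spanning 2-32 Hz inclusive
    (4 octaves -> 69 center frequencies). "Center frequency" means the
    wavelet peak frequency omega_p = (beta/gamma)**(1/gamma) mapped to Hz.
    """

    gamma: float = 3.0
    beta: float = 3.29
    fs: float = 256.0
    f_lo: float = 2.0
    f_hi: float = 32.0
    voices_per_octave: int = 17

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if not 0 < self.f_lo <= self.f_hi:
            raise ValueError("need 0 < f_lo <= f_hi")

    @property
    def frequencies(self) -> np.ndarray:
        return _geometric_frequencies(self.f_lo, self.f_hi, self.voices_per_octave)

    @property
    def peak_frequency_radians(self) -> float:
        """Dimensionless peak frequency omega_p of the frequency response."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    @property
    def cycles_in_energy_window(self) -> float:
        """Oscillation cycles of the peak frequency inside the central
        energy window (duration 2*sqrt(beta*gamma) radians at omega_p)."""
        return float(np.sqrt(self.beta * self.gamma) / np.pi)

    def subset(self, f_lo: float, f_hi: float) -> "MorseFamily":
        """Family restricted to grid frequencies inside [f_lo, f_hi].

        The restricted grid keeps the parent's voice positions, so scale
        selections of the parent and subset coincide where they overlap.
        """
        freqs = self.frequencies
        inside = freqs[(freqs >= f_lo - 1e-9) & (freqs <= f_hi + 1e-9)]
        if inside.size == 0:
            raise ValueError("no grid frequencies inside the requested band")
        return MorseFamily(
            self.gamma, self.beta, self.fs,
            float(inside[0]), float(inside[-1]), self.voices_per_octave,
        )


def morse_wavelet(
    gamma: float,
    beta: float,
    center_frequency: float,
    fs: float,
    length: int,
) -> np.ndarray:
    """Unit-energy analytic Morse kernel with its peak at the center index.

    Constructed in the frequency domain on a grid of ``length`` samples
    (made odd if necessary so that centering is exact): positive DFT bins
    carry (omega/omega_c * omega_p)**beta * exp(-(...)**gamma), all other
    bins are exactly zero, and the inverse transform is circularly rolled
    so t=0 sits at the middle. The circular roll only multiplies the
    spectrum by a phase, so analyticity is exact for the returned kernel.
    """
    if gamma <= 0 or beta <= 0 or center_frequency <= 0:
        raise ValueError("parameters must be positive")
    if center_frequency >= fs / 2:
        raise ValueError("center frequency must be below Nyquist")
    n = int(length)
    if n < 3:
        raise ValueError("kernel length too short")
    if n % 2 == 0:
        n -= 1
    omega_p = (beta / gamma) ** (1.0 / gamma)
    k = np.arange(n)
    f = k * fs / n
    pos = (k >= 1) & (k <= (n - 1) // 2)
    x = np.zeros(n)
    x[pos] = f[pos] / center_frequency * omega_p
    response = np.zeros(n)
    with np.errstate(divide="ignore"):
        response[pos] = np.exp(beta * np.log(x[pos]) - x[pos] ** gamma)
    kernel = np.fft.ifft(response)
    kernel = np.roll(kernel, (n - 1) // 2)
    energy = np.sum(np.abs(kernel) ** 2)
    return kernel / np.sqrt(energy)


def cwt_sweeps(sweeps: np.ndarray, family: MorseFamily) -> np.ndarray:
    """Analytic CWT of a batch of sweeps.

    Parameters
    ----------
    sweeps : ndarray, shape (n_sweeps, n_times)
    family : MorseFamily

    Returns
    -------
    coefficients : complex ndarray, shape (n_sweeps, n_freqs, n_times)
        Per scale, the complex convolution of each sweep with the analytic
        kernel, same-length alignment centered on the kernel peak.
    """
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    n_sweeps, n_times = sweeps.shape
    freqs = family.frequencies
    min_support = int(family.fs / freqs.min())
    if n_times < min_support:
        raise ValueError(
            f"sweep of {n_times} samples shorter than the longest kernel's "
            f"effective support (~{min_support} samples)"
        )
    out = np.empty((n_sweeps, freqs.size, n_times), dtype=complex)
    for j, fc in enumerate(freqs):
        kernel = morse_wavelet(family.gamma, family.beta, fc, family.fs, n_times)
        out[:, j, :] = sp_signal.fftconvolve(
            sweeps, kernel[None, :], mode="same", axes=1
        )
    return out


def cwt(sweep: np.ndarray, family: MorseFamily) -> np.ndarray:
    """Analytic CWT of a single sweep -> complex (n_freqs x n_times)."""
    sweep = np.asarray(sweep, dtype=float)
    if sweep.ndim != 1:
        raise ValueError("cwt expects a 1-D sweep; use cwt_sweeps for batches")
    return cwt_sweeps(sweep[None, :], family)[0]


def instantaneous_phase(coefficients: np.ndarray) -> np.ndarray:
    """Elementwise argument in (-pi, pi]; zero-magnitude cells get phase 0."""
    coefficients = np.asarray(coefficients)
    zero = coefficients == 0
    n_zero = int(zero.sum())
    if n_zero:
        logger.info("%d zero-magnitude cells; their phase is set to 0", n_zero)
    return np.angle(coefficients)


@dataclass
class WpssMap:
    """Phase-consistency map (frequencies x time), values in [0, 1]."""

    values: np.ndarray
    frequencies: np.ndarray
    times_ms: np.ndarray
    n_sweeps: int
    channel: int | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.frequencies), len(self.times_ms)):
            raise ValueError("map shape must be (n_freqs, n_times)")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("WPSS values must lie in [0, 1]")

    def trimmed(self, lo_ms: float, hi_ms: float) -> "WpssMap":
        sel = (self.times_ms >= lo_ms - 1e-9) & (self.times_ms <= hi_ms + 1e-9)
        return WpssMap(
            self.values[:, sel], self.frequencies, self.times_ms[sel],
            self.n_sweeps, self.channel, self.condition,
        )


def wpss(
    phases: np.ndarray,
    frequencies: np.ndarray | None = None,
    times_ms: np.ndarray | None = None,
    channel: int | None = None,
    condition: str = "",
) -> WpssMap | np.ndarray:
    """Mean resultant vector length across sweeps per time-frequency cell.

    ``phases`` has shape (n_sweeps, n_freqs, n_times) and must contain at
    least two sweeps. Returns a bare array when no axes are supplied.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 3:
        raise ValueError("phases must be (n_sweeps, n_freqs, n_times)")
    k = phases.shape[0]
    if k < 2:
        raise ValueError("WPSS is undefined for fewer than 2 sweeps")
    resultant = np.abs(np.mean(np.exp(1j * phases), axis=0))
    resultant = np.clip(resultant, 0.0, 1.0)
    if frequencies is None or times_ms is None:
        return resultant
    return WpssMap(resultant, np.asarray(frequencies), np.asarray(times_ms), k,
                   channel, condition)


def wpss_from_sweeps(
    sweeps: np.ndarray,
    family: MorseFamily,
    times_ms: np.ndarray,
    channel: int | None = None,
    condition: str = "",
) -> WpssMap:
    """WPSS map computed scale-by-scale without storing all coefficients.

    Mathematically identical to ``wpss(instantaneous_phase(cwt_sweeps(...)))``
    but holds only one scale's coefficients at a time, which keeps memory
    flat for thousands of sweeps. Zero-magnitude coefficients contribute a
    unit vector at phase 0, matching the phase convention of
    :func:`instantaneous_phase`.
    """
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    k, n_times = sweeps.shape
    if k < 2:
        raise ValueError("WPSS is undefined for fewer than 2 sweeps")
    freqs = family.frequencies
    n_kernel = n_times if n_times % 2 else n_times - 1
    nfft = sp_fft.next_fast_len(n_times + n_kernel - 1, real=False)
    spectra = np.fft.fft(sweeps, nfft, axis=1)
    start = (n_kernel - 1) // 2  # 'same' alignment on the kernel peak
    out = np.empty((freqs.size, n_times))
    for j, fc in enumerate(freqs):
        kernel = morse_wavelet(family.gamma, family.beta, fc, family.fs, n_kernel)
        kfft = np.fft.fft(kernel, nfft)
        seg = np.fft.ifft(spectra * kfft[None, :], axis=1)[:, start : start + n_times]
        mag = np.abs(seg)
        unit = np.where(mag == 0, 1.0 + 0j, seg / np.where(mag == 0, 1.0, mag))
        out[j] = np.abs(unit.mean(axis=0))
    return WpssMap(np.clip(out, 0.0, 1.0), freqs, np.asarray(times_ms), k,
                   channel, condition)


def band_window_mean(
    wpss_map: WpssMap,
    band_hz: tuple[float, float] = (4.0, 8.0),
    window_ms: tuple[float, float] = (116.7, 246.6),
) -> float:
    """Mean over cells with center frequency in ``band_hz`` and time in
    ``window_ms`` (both inclusive). The default window is the N1-P2 complex
    of the attended-condition average with a 20 ms buffer on each side."""
    fsel = (wpss_map.frequencies >= band_hz[0] - 1e-9) & (
        wpss_map.frequencies <= band_hz[1] + 1e-9
    )
    tsel = (wpss_map.times_ms >= window_ms[0] - 1e-9) & (
        wpss_map.times_ms <= window_ms[1] + 1e-9
    )
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band/window selection")
    return float(wpss_map.values[np.ix_(fsel, tsel)].mean())
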