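"""Epoching, artifact rejection, sweep matching, averaging and component
measures for speech-evoked ERPs.

Sweeps are extracted over -500..2000 ms around each trigger, baseline
corrected to the -50..0 ms mean, and rejected when any channel exceeds
+-100 uV. Sweep counts are matched across conditions by uniform random
subsampling before averaging so condition contrasts compare equal amounts
of data. Component amplitudes are windowed means (+-20 ms) around the peak
latencies found in the attended-condition average at the peak channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ContinuousRecording
from .events import TriggerSequence

__all__ = [
    "EpochSet",
    "epoch",
    "baseline_correct",
    "reject_artifacts",
    "match_sweep_counts",
    "average_erp",
    "peak_latency",
    "component_amplitude",
    "DEFAULT_EPOCH_WINDOW_MS",
    "DEFAULT_BASELINE_MS",
    "N1_SEARCH_MS",
    "P2_SEARCH_MS",
    "COMPARISON_SPAN_MS",
]

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_WINDOW_MS = (-500.0, 2000.0)
DEFAULT_BASELINE_MS = (-50.0, 0.0)
# default component search windows on the attended-condition average
N1_SEARCH_MS = (80.0, 180.0)
P2_SEARCH_MS = (180.0, 280.0)
# span over which ERP and TRF waveforms are compared / reported
COMPARISON_SPAN_MS = (-50.0, 500.0)


@dataclass
class EpochSet:
    """Sweeps x channels x time array with provenance and rejection mask."""

    data: np.ndarray
    times_ms: np.ndarray
    fs: float
    trigger_indices: np.ndarray = field(default=None)
    mask: np.ndarray = field(default=None)  # True = accepted
    baseline_applied: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (sweeps x channels x time)")
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.size != self.data.shape[2]:
            raise ValueError("time axis length mismatch")
        if self.trigger_indices is None:
            self.trigger_indices = np.arange(self.n_sweeps)
        self.trigger_indices = np.asarray(self.trigger_indices, dtype=int)
        if self.mask is None:
            self.mask = np.ones(self.n_sweeps, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.size != self.n_sweeps:
            raise ValueError("mask length mismatch")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_accepted(self) -> int:
        return int(self.mask.sum())

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def accepted(self) -> np.ndarray:
        """View of the accepted sweeps only."""
        return self.data[self.mask]

    def time_slice(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Boolean selector over the time axis, inclusive at both ends."""
        return (self.times_ms >= lo_ms - 1e-9) & (self.times_ms <= hi_ms + 1e-9)


def epoch(
    rec: ContinuousRecording,
    triggers: TriggerSequence | np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_EPOCH_WINDOW_MS,
    channels: list[int] | None = None,
) -> EpochSet:
    """Cut sweeps around trigger onsets.

    Sweep k, channel n, sample j equals ``rec.data[n, trigger_k + offset_j]``
    with offsets spanning the window. Triggers whose window would leave the
    recording are dropped (their count is logged); an empty trigger set
    yields an empty EpochSet.
    """
    idx = triggers.sample_indices if isinstance(triggers, TriggerSequence) else np.asarray(triggers, dtype=int)
    fs = rec.fs
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    if hi < lo:
        raise ValueError("window upper bound below lower bound")
    offsets = np.arange(lo, hi + 1)
    times_ms = offsets / fs * 1000.0

    in_bounds = (idx + lo >= 0) & (idx + hi < rec.n_samples)
    dropped = int((~in_bounds).sum())
    if dropped:
        logger.info("dropped %d out-of-bounds triggers", dropped)
    idx = idx[in_bounds]
    data = rec.data if channels is None else rec.data[channels]
    if channels is not None:
        data = np.atleast_2d(data)
    if idx.size == 0:
        empty = np.empty((0, data.shape[0], offsets.size))
        return EpochSet(empty, times_ms, fs, np.empty(0, dtype=int))
    # gather: (sweeps, channels, time)
    sweeps = data[:, idx[:, None] + offsets[None, :]]  # (channels, sweeps, time)
    sweeps = np.transpose(sweeps, (1, 0, 2)).copy()
    return EpochSet(sweeps, times_ms, fs, idx)


def baseline_correct(
    epochs: EpochSet, window_ms: tuple[float, float] = DEFAULT_BASELINE_MS
) -> EpochSet:
    """Subtract the per-sweep, per-channel mean over the baseline window."""
    if epochs.baseline_applied:
        raise RuntimeError("baseline correction already applied")
    sel = epochs.time_slice(*window_ms)
    if not sel.any():
        raise ValueError("baseline window outside the epoch window")
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return EpochSet(
        epochs.data - base,
        epochs.times_ms,
        epochs.fs,
        epochs.trigger_indices,
        epochs.mask.copy(),
        baseline_applied=True,
    )


def reject_artifacts(epochs: EpochSet, abs_threshold: float = 100.0) -> EpochSet:
    """Reject sweeps in which any channel exceeds ``abs_threshold`` (uV)."""
    if abs_threshold <= 0:
        raise ValueError("threshold must be positive")
    if not epochs.baseline_applied:
        raise RuntimeError("artifact rejection expects baseline-corrected epochs")
    if epochs.n_sweeps:
        peak = np.abs(epochs.data).max(axis=(1, 2))
        mask = epochs.mask & (peak <= abs_threshold)
    else:
        mask = epochs.mask
    return EpochSet(
        epochs.data, epochs.times_ms, epochs.fs, epochs.trigger_indices,
        mask, epochs.baseline_applied,
    )


def match_sweep_counts(
    epochs_by_condition: dict[str, EpochSet],
    n: int | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, EpochSet]:
    """Uniform random selection of exactly ``n`` accepted sweeps per condition.

    ``n`` defaults to the minimum accepted count across conditions; a larger
    ``n`` than available raises, naming the deficit. Reproducible from seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = {c: e.n_accepted for c, e in epochs_by_condition.items()}
    if n is None:
        n = min(counts.values())
    out: dict[str, EpochSet] = {}
    for cond, eps in epochs_by_condition.items():
        have = counts[cond]
        if have < n:
            raise ValueError(
                f"condition {cond!r} has {have} accepted sweeps, {n - have} short of {n}"
            )
        accepted_pos = np.flatnonzero(eps.mask)
        chosen = rng.choice(accepted_pos, size=n, replace=False)
        chosen.sort()
        out[cond] = EpochSet(
            eps.data[chosen],
            eps.times_ms,
            eps.fs,
            eps.trigger_indices[chosen],
            np.ones(n, dtype=bool),
            eps.baseline_applied,
        )
    return out


def average_erp(epochs: EpochSet) -> np.ndarray:
    """Arithmetic mean across accepted sweeps (channels x time)."""
    if epochs.n_accepted == 0:
        raise ValueError("no accepted sweeps to average")
    return epochs.accepted().mean(axis=0)


def peak_latency(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    channel: int,
    polarity: int,
    search_window_ms: tuple[float, float],
) -> float:
    """Latency (ms) of the extremum of the given polarity in the window.

    Ties break toward the earliest sample; a flat window returns its first
    sample and logs a degeneracy warning.
    """
    waveform = np.atleast_2d(waveform)
    times_ms = np.asarray(times_ms, dtype=float)
    sel = (times_ms >= search_window_ms[0] - 1e-9) & (times_ms <= search_window_ms[1] + 1e-9)
    if not sel.any():
        raise ValueError("empty search window")
    seg = waveform[channel, sel]
    t = times_ms[sel]
    if np.allclose(seg, seg[0]):
        logger.warning("flat waveform in search window; returning earliest sample")
        return float(t[0])
    i = int(np.argmin(seg)) if polarity < 0 else int(np.argmax(seg))
    return float(t[i])


def component_amplitude(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    channel: int,
    center_ms: float,
    half_width_ms: float = 20.0,
) -> float:
    """Mean voltage in ``center +- half_width`` ms at one channel."""
    waveform = np.atleast_2d(waveform)
    times_ms = np.asarray(times_ms, dtype=float)
    sel = (times_ms >= center_ms - half_width_ms - 1e-9) & (
        times_ms <= center_ms + half_width_ms + 1e-9
    )
    if not sel.any():
        raise ValueError("component window outside the waveform span")
    return float(waveform[channel, sel].mean())
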