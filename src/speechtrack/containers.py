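"""Core in-memory containers shared across the pipeline.

A :class:`ContinuousRecording` holds multichannel EEG (or any multichannel
time series) in microvolts; an :class:`OnsetEnvelope` holds a single
nonnegative acoustic-edge series. Both carry their sampling rate so every
downstream operation can convert between samples and milliseconds without
extra bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ContinuousRecording", "OnsetEnvelope"]


@dataclass
class ContinuousRecording:
    """Multichannel time series (channels x samples) with sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (for EEG) or arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        One label per channel; generated as ``CH01..`` when omitted.
    reference : str
        Free-form note on the referencing state (e.g. ``"average-mastoid"``).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] | None = None
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channel_names is None:
            self.channel_names = [f"CH{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("one channel name required per channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def copy_with(self, **changes) -> "ContinuousRecording":
        return replace(self, **changes)


@dataclass
class OnsetEnvelope:
    """Single-channel nonnegative onset-envelope series.

    ``pooled_sigma`` is filled in after the per-subject pooling step and is
    the scale against which the 2-sigma trigger threshold is expressed.
    """

    values: np.ndarray
    fs: float
    source_id: str = ""
    pooled_sigma: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("envelope contains non-finite samples")
        if self.values.size and self.values.min() < 0:
            raise ValueError("onset envelope must be nonnegative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "OnsetEnvelope":
        return replace(self, **changes)
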