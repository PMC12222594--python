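"""Segmentation triggers from onset envelopes (pooled 2-sigma rule).

The trigger threshold is expressed in units of the pooled envelope standard
deviation: all onset envelopes of one subject (two streams x all trials)
are concatenated, the population standard deviation sigma_env is taken over
every sample, and a trigger is inserted wherever an envelope changes from
sub- to suprathreshold amplitude at threshold 2 * sigma_env.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, OnsetEnvelope

__all__ = [
    "TriggerSequence",
    "pooled_sigma",
    "extract_triggers",
    "trim_edges",
    "write_events_tsv",
    "read_events_tsv",
]


@dataclass
class TriggerSequence:
    """Strictly increasing trigger sample indices with their provenance."""

    sample_indices: np.ndarray
    fs: float
    threshold: float
    stream: str = ""

    def __post_init__(self) -> None:
        self.sample_indices = np.asarray(self.sample_indices, dtype=int).ravel()
        if np.any(np.diff(self.sample_indices) <= 0):
            raise ValueError("trigger indices must strictly increase")

    def __len__(self) -> int:
        return self.sample_indices.size

    @property
    def rate(self) -> float:
        """Triggers per second over the span they were extracted from."""
        if len(self) < 2:
            return 0.0
        return len(self) / ((self.sample_indices[-1] - self.sample_indices[0]) / self.fs)


def pooled_sigma(envelopes: list[np.ndarray | OnsetEnvelope]) -> float:
    """Population standard deviation over all samples of all envelopes.

    The population convention (divide by N) is used: pools are on the order
    of 1e6 samples, where the N vs N-1 distinction is negligible.
    """
    if not envelopes:
        raise ValueError("empty envelope pool")
    arrays = [
        e.values if isinstance(e, OnsetEnvelope) else np.asarray(e, dtype=float).ravel()
        for e in envelopes
    ]
    pool = np.concatenate(arrays)
    if pool.size == 0:
        raise ValueError("empty envelope pool")
    return float(pool.std())


def extract_triggers(
    env: OnsetEnvelope | np.ndarray,
    threshold: float | None = None,
    fs: float | None = None,
    stream: str = "",
) -> TriggerSequence:
    """Sub-to-suprathreshold crossings of an onset envelope.

    Index ``i`` is a trigger iff ``env[i-1] <= threshold < env[i]``; the very
    first sample can never be a trigger (it has no defined predecessor). When
    ``threshold`` is omitted, it defaults to ``2 * env.pooled_sigma``.
    """
    if isinstance(env, OnsetEnvelope):
        values, fs = env.values, env.fs
        if threshold is None:
            if env.pooled_sigma is None:
                raise ValueError("threshold omitted and pooled_sigma not set")
            threshold = 2.0 * env.pooled_sigma
    else:
        values = np.asarray(env, dtype=float).ravel()
        if threshold is None:
            raise ValueError("threshold required for bare arrays")
        if fs is None:
            raise ValueError("fs required for bare arrays")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = values > threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return TriggerSequence(crossings, fs, threshold, stream)


def trim_edges(obj, seconds: float = 1.0, triggers: TriggerSequence | None = None):
    """Discard the first and last ``seconds`` of a recording or envelope.

    Removes ``round(fs * seconds)`` samples from each end; with ``triggers``
    given, returns a second object with trigger indices re-expressed in
    trimmed coordinates (triggers falling in the trimmed margins are dropped).
    ``seconds=0`` is the identity.
    """
    if seconds < 0:
        raise ValueError("seconds must be nonnegative")
    if isinstance(obj, ContinuousRecording):
        fs, n = obj.fs, obj.n_samples
    elif isinstance(obj, OnsetEnvelope):
        fs, n = obj.fs, obj.n_samples
    else:
        raise TypeError("trim_edges expects a ContinuousRecording or OnsetEnvelope")
    cut = int(round(fs * seconds))
    if n <= 2 * cut:
        raise ValueError("input too short to trim")
    if isinstance(obj, ContinuousRecording):
        trimmed = obj.copy_with(data=obj.data[:, cut : n - cut].copy())
    else:
        trimmed = obj.copy_with(values=obj.values[cut : n - cut].copy())
    if triggers is None:
        return trimmed
    idx = triggers.sample_indices
    keep = (idx >= cut) & (idx < n - cut)
    shifted = TriggerSequence(idx[keep] - cut, triggers.fs, triggers.threshold, triggers.stream)
    return trimmed, shifted


def write_events_tsv(path, triggers_by_trial: list[dict[str, TriggerSequence]]) -> None:
    """Write triggers as TSV with columns onset_sample, stream, trial."""
    rows = []
    for trial, streams in enumerate(triggers_by_trial):
        for stream, seq in streams.items():
            for s in seq.sample_indices:
                rows.append({"onset_sample": int(s), "stream": stream, "trial": trial})
    pd.DataFrame(rows, columns=["onset_sample", "stream", "trial"]).to_csv(
        path, sep="\t", index=False
    )


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    required = {"onset_sample", "stream", "trial"}
    if not required.issubset(df.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    return df
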