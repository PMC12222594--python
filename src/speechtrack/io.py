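"""Reading and writing the pipeline's on-disk formats.

EEG travels as flat little-endian float32 binary (channels x samples,
C order) with a structured JSON sidecar carrying the sampling rate and
channel names; EDF files are read through :mod:`mne` when it is installed.
Envelopes are single-column TSV files with a small JSON sidecar. Events are
tab-separated tables (onset_sample, stream, trial) handled in
:mod:`speechtrack.events`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, OnsetEnvelope

__all__ = [
    "write_recording",
    "read_recording",
    "write_envelope_tsv",
    "read_envelope_tsv",
    "write_epochs",
    "read_epochs",
    "write_wpss_map",
    "read_wpss_map",
    "write_linear_model",
    "read_linear_model",
    "read_wav",
    "read_edf",
]


def write_recording(path, rec: ContinuousRecording) -> None:
    """Write EEG as flat float32 binary plus a JSON sidecar."""
    path = Path(path)
    data = rec.data.astype("<f4")
    data.tofile(path.with_suffix(".dat"))
    sidecar = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_names": rec.channel_names,
        "reference": rec.reference,
        "dtype": "<f4",
        "order": "C (channels x samples)",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path) -> ContinuousRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".dat"), dtype=sidecar.get("dtype", "<f4"))
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"]).astype(float)
    return ContinuousRecording(
        data,
        sidecar["fs"],
        channel_names=sidecar.get("channel_names"),
        reference=sidecar.get("reference", "as-recorded"),
    )


def write_envelope_tsv(path, env: OnsetEnvelope, chain_note: str = "") -> None:
    """Single-column TSV plus a sidecar noting fs and the processing chain."""
    path = Path(path)
    pd.DataFrame({"envelope": env.values}).to_csv(path, sep="\t", index=False)
    sidecar = {"fs": env.fs, "source_id": env.source_id, "chain": chain_note}
    if env.pooled_sigma is not None:
        sidecar["pooled_sigma"] = env.pooled_sigma
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_envelope_tsv(path) -> OnsetEnvelope:
    path = Path(path)
    values = pd.read_csv(path, sep="\t")["envelope"].to_numpy(dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    fs, source_id, pooled = 256.0, "", None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        fs = sidecar.get("fs", fs)
        source_id = sidecar.get("source_id", "")
        pooled = sidecar.get("pooled_sigma")
    return OnsetEnvelope(values, fs, source_id=source_id, pooled_sigma=pooled)


def write_epochs(path, epochs) -> None:
    """Epoch sweeps as flat float32 binary with dims, time axis and mask."""
    path = Path(path)
    epochs.data.astype("<f4").tofile(path.with_suffix(".dat"))
    sidecar = {
        "shape": list(epochs.data.shape),
        "times_ms": epochs.times_ms.tolist(),
        "fs": epochs.fs,
        "trigger_indices": epochs.trigger_indices.tolist(),
        "mask": epochs.mask.astype(int).tolist(),
        "baseline_applied": epochs.baseline_applied,
        "dtype": "<f4",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_epochs(path):
    from .erp import EpochSet

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".dat"), dtype=sidecar.get("dtype", "<f4"))
    data = data.reshape(sidecar["shape"]).astype(float)
    return EpochSet(
        data,
        np.asarray(sidecar["times_ms"]),
        sidecar["fs"],
        np.asarray(sidecar["trigger_indices"], dtype=int),
        np.asarray(sidecar["mask"], dtype=bool),
        sidecar["baseline_applied"],
    )


def write_wpss_map(path, wpss_map) -> None:
    """Phase-consistency map as flat binary with both axes in the sidecar."""
    path = Path(path)
    wpss_map.values.astype("<f4").tofile(path.with_suffix(".dat"))
    sidecar = {
        "shape": list(wpss_map.values.shape),
        "frequencies": wpss_map.frequencies.tolist(),
        "times_ms": wpss_map.times_ms.tolist(),
        "n_sweeps": wpss_map.n_sweeps,
        "channel": wpss_map.channel,
        "condition": wpss_map.condition,
        "dtype": "<f4",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_wpss_map(path):
    from .wavelet import WpssMap

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    values = np.fromfile(path.with_suffix(".dat"), dtype=sidecar.get("dtype", "<f4"))
    values = np.clip(values.reshape(sidecar["shape"]).astype(float), 0.0, 1.0)
    return WpssMap(
        values,
        np.asarray(sidecar["frequencies"]),
        np.asarray(sidecar["times_ms"]),
        sidecar["n_sweeps"],
        sidecar["channel"],
        sidecar["condition"],
    )


def write_linear_model(path, results, trial_ids=None) -> None:
    """Fitted TRF or decoder weights plus fitting metadata.

    ``results`` is a TRFResults or DecoderResults object; weights go to flat
    float64 binary and the sidecar records direction, lag grid (ms and
    samples), the lambda list verbatim and optional training trial ids.
    """
    path = Path(path)
    weights = np.asarray(results.weights, dtype="<f8")
    weights.tofile(path.with_suffix(".dat"))
    grid = results.lag_grid
    sidecar = {
        "direction": results.direction,
        "weights_shape": list(weights.shape),
        "lag_span_ms": [grid.tau_min_ms, grid.tau_max_ms],
        "lag_samples": grid.lags.tolist(),
        "fs": grid.fs,
        "lambdas": results.lambdas.tolist(),
        "n_trials": results.n_trials,
        "trial_ids": list(trial_ids) if trial_ids is not None else None,
        "dtype": "<f8",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_linear_model(path) -> tuple[np.ndarray, dict]:
    """Weights and metadata of a serialized model (no refitting implied)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    weights = np.fromfile(path.with_suffix(".dat"), dtype=sidecar.get("dtype", "<f8"))
    return weights.reshape(sidecar["weights_shape"]), sidecar


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file to float64 in [-1, 1] (mono: channels averaged)."""
    from scipy.io import wavfile

    fs, data = wavfile.read(Path(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(fs)


def read_edf(path) -> ContinuousRecording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return ContinuousRecording(
        raw.get_data() * 1e6,  # volts -> microvolts
        raw.info["sfreq"],
        channel_names=list(raw.ch_names),
    )
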