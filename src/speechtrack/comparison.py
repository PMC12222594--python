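"""ERP-TRF similarity: best-fit lag, topographic and waveform correlations.

The spatial correlation r2D is the Pearson correlation computed across
channels between two scalp topographies: -1 for perfectly inverted maps,
+1 for identical maps, and invariant to any common positive affine
transform of one map.
"""

from __future__ import annotations

import numpy as np

from .models import pearson_r

__all__ = [
    "best_lag",
    "spatial_correlation",
    "topographic_similarity_course",
    "waveform_correlation_per_channel",
    "shift_waveform",
]

MIN_SPATIAL_CHANNELS = 3


def _normalized_xcorr_at_lag(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson correlation of a[t] with b[t - lag] over the overlap."""
    if lag >= 0:
        seg_a, seg_b = a[lag:], b[: b.size - lag]
    else:
        seg_a, seg_b = a[: a.size + lag], b[-lag:]
    if seg_a.size < 3:
        raise ValueError("overlap too short at this lag")
    return pearson_r(seg_a, seg_b)


def best_lag(
    erp_waveforms: np.ndarray,
    trf_waveforms: np.ndarray,
    max_lag: int = 32,
) -> int:
    """Lag (samples) maximizing the mean normalized cross-correlation.

    ``erp_waveforms``/``trf_waveforms`` are (n_participants x n_times) or
    1-D single waveforms. A positive lag means the ERP lags the TRF by that
    many samples (the TRF must be delayed to match). The correlation is
    averaged across participants per candidate lag and maximized; ties break
    toward the smaller absolute lag.
    """
    erp = np.atleast_2d(np.asarray(erp_waveforms, dtype=float))
    trf = np.atleast_2d(np.asarray(trf_waveforms, dtype=float))
    if erp.shape != trf.shape:
        raise ValueError("waveform sets must have matching shapes")
    if max_lag >= erp.shape[1]:
        raise ValueError("max_lag must be below the waveform span")
    lags = np.arange(-max_lag, max_lag + 1)
    mean_r = np.array(
        [
            np.mean([_normalized_xcorr_at_lag(e, t, lag) for e, t in zip(erp, trf)])
            for lag in lags
        ]
    )
    best = mean_r.max()
    candidates = lags[np.isclose(mean_r, best)]
    return int(candidates[np.argmin(np.abs(candidates))])


def shift_waveform(waveform: np.ndarray, lag: int) -> np.ndarray:
    """Delay a (channels x time) waveform by ``lag`` samples, edge-padded."""
    wave = np.atleast_2d(np.asarray(waveform, dtype=float))
    if lag == 0:
        return wave.copy()
    out = np.empty_like(wave)
    if lag > 0:
        out[:, lag:] = wave[:, :-lag]
        out[:, :lag] = wave[:, :1]
    else:
        out[:, :lag] = wave[:, -lag:]
        out[:, lag:] = wave[:, -1:]
    return out


def spatial_correlation(frame_a: np.ndarray, frame_b: np.ndarray) -> float:
    """r2D: Pearson correlation across channels of two topography frames."""
    a = np.asarray(frame_a, dtype=float).ravel()
    b = np.asarray(frame_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("frames must share the channel set")
    if a.size < MIN_SPATIAL_CHANNELS:
        raise ValueError(
            f"spatial correlation needs >= {MIN_SPATIAL_CHANNELS} channels"
        )
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("zero-variance topography frame")
    return pearson_r(a, b)


def topographic_similarity_course(
    erp: np.ndarray,
    lag_corrected_trf: np.ndarray,
    times_ms: np.ndarray,
    span_ms: tuple[float, float] = (-50.0, 500.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise r2D between ERP and TRF topographies over a span.

    Both inputs are (channels x time) on the same time axis; returns
    ``(times_in_span, r2d_series)``.
    """
    erp = np.atleast_2d(erp)
    trf = np.atleast_2d(lag_corrected_trf)
    times_ms = np.asarray(times_ms, dtype=float)
    if erp.shape != trf.shape or erp.shape[1] != times_ms.size:
        raise ValueError("waveforms and time axis must align")
    sel = (times_ms >= span_ms[0] - 1e-9) & (times_ms <= span_ms[1] + 1e-9)
    if not sel.any():
        raise ValueError("span outside the waveforms")
    idx = np.flatnonzero(sel)
    series = np.array(
        [spatial_correlation(erp[:, i], trf[:, i]) for i in idx]
    )
    return times_ms[idx], series


def waveform_correlation_per_channel(
    erp: np.ndarray,
    lag_corrected_trf: np.ndarray,
    times_ms: np.ndarray,
    span_ms: tuple[float, float] = (-50.0, 500.0),
) -> np.ndarray:
    """Pearson r between ERP and TRF along time, one value per channel."""
    erp = np.atleast_2d(erp)
    trf = np.atleast_2d(lag_corrected_trf)
    times_ms = np.asarray(times_ms, dtype=float)
    if erp.shape != trf.shape or erp.shape[1] != times_ms.size:
        raise ValueError("waveforms and time axis must align")
    sel = (times_ms >= span_ms[0] - 1e-9) & (times_ms <= span_ms[1] + 1e-9)
    if not sel.any():
        raise ValueError("span outside the waveforms")
    return np.array(
        [pearson_r(erp[n, sel], trf[n, sel]) for n in range(erp.shape[0])]
    )
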