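"""Forward (TRF) and backward (stimulus-reconstruction) linear models.

Both directions are ridge regressions on lagged designs:

* forward:  r(t, n) = sum_l s(t - tau_l) h(tau_l, n) + eps(t, n),
  solved per subject with all trials concatenated,
  h = (S'S + lambda I)^-1 S'r;
* backward: s_hat(t) = sum_n sum_l r(t + tau_l, n) g(tau_l, n),
  g = (R'R + lambda I)^-1 R's.

Regularization deliberately skips per-lambda cross-validation: models are
fitted separately on 20 logarithmically spaced lambdas spanning 1e-6..1e6
and the resulting weights are averaged, which stabilises the smoothing
level across subjects and conditions. lambda is applied to the raw,
unnormalized normal equations (no eigenvalue-mean scaling); data are
centered beforehand, so no intercept column is used.

Usage follows the model/results pattern::

    model = TemporalResponseFunction(stim_trials, eeg_trials, fs=256)
    res = model.fit()
    waveform = res.postprocess()      # 30 Hz lowpass, baseline, trim
    print(res.summary())

    accs = loo_reconstruction(eeg_trials, stim_trials, fs=256)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import signal as sp_signal

from .containers import ContinuousRecording, OnsetEnvelope

__all__ = [
    "LagGrid",
    "default_lambda_grid",
    "build_lagged_design",
    "ridge_solve",
    "TemporalResponseFunction",
    "TRFResults",
    "TRFWaveform",
    "StimulusDecoder",
    "DecoderResults",
    "loo_reconstruction",
    "pearson_r",
]

FORWARD_LAG_SPAN_MS = (-250.0, 700.0)
BACKWARD_LAG_SPAN_MS = (0.0, 500.0)
TRF_TRIM_SPAN_MS = (-50.0, 500.0)  # forward span minus the 200 ms buffers


def default_lambda_grid(n: int = 20, lo: float = 1e-6, hi: float = 1e6) -> np.ndarray:
    """20 logarithmically spaced regularization parameters in [1e-6, 1e6]."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass(frozen=True)
class LagGrid:
    """Consecutive integer sample lags spanning a millisecond range."""

    tau_min_ms: float
    tau_max_ms: float
    fs: float

    def __post_init__(self) -> None:
        if self.tau_max_ms < self.tau_min_ms:
            raise ValueError("tau_max must be >= tau_min")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def lags(self) -> np.ndarray:
        lo = int(round(self.tau_min_ms / 1000.0 * self.fs))
        hi = int(round(self.tau_max_ms / 1000.0 * self.fs))
        return np.arange(lo, hi + 1)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags / self.fs * 1000.0

    @property
    def n_lags(self) -> int:
        return self.lags.size


def _as_series(x) -> np.ndarray:
    if isinstance(x, OnsetEnvelope):
        return x.values
    return np.asarray(x, dtype=float).ravel()


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, ContinuousRecording):
        return x.data
    return np.atleast_2d(np.asarray(x, dtype=float))


def build_lagged_design(source, lag_grid: LagGrid, direction: str) -> np.ndarray:
    """Shift-and-zero-pad design matrix.

    forward  : 1-D source s -> T x L with column j holding s(t - tau_j);
    backward : multichannel source r (N x T) -> T x (N*L), channel-major,
               with the column for (n, j) holding r(t + tau_j, n).
    Out-of-range entries are zero.
    """
    lags = lag_grid.lags
    if direction == "forward":
        s = _as_series(source)
        t_len = s.size
        if t_len < lag_grid.n_lags:
            raise ValueError("source shorter than the lag window")
        design = np.zeros((t_len, lags.size))
        for j, tau in enumerate(lags):
            if tau >= 0:
                design[tau:, j] = s[: t_len - tau] if tau else s
            else:
                design[:tau, j] = s[-tau:]
        return design
    if direction == "backward":
        r = _as_matrix(source)
        n_chan, t_len = r.shape
        if t_len < lag_grid.n_lags:
            raise ValueError("source shorter than the lag window")
        design = np.zeros((t_len, n_chan * lags.size))
        for n in range(n_chan):
            for j, tau in enumerate(lags):
                col = n * lags.size + j
                if tau >= 0:
                    if tau:
                        design[: t_len - tau, col] = r[n, tau:]
                    else:
                        design[:, col] = r[n]
                else:
                    design[-tau:, col] = r[n, :tau]
        return design
    raise ValueError("direction must be 'forward' or 'backward'")


def ridge_solve(design: np.ndarray, target: np.ndarray, lam: float) -> np.ndarray:
    """Solve (X'X + lambda I) w = X'y without forming the inverse."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float)
    gram = design.T @ design
    xty = design.T @ target
    return _solve_normal_equations(gram, xty, lam)


def _solve_normal_equations(gram: np.ndarray, xty: np.ndarray, lam: float) -> np.ndarray:
    n = gram.shape[0]
    if lam == 0:
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "singular normal equations at lambda=0; regularize or reduce lags"
            )
        return scipy.linalg.solve(gram, xty, assume_a="sym")
    return scipy.linalg.solve(gram + lam * np.eye(n), xty, assume_a="pos")


class _EigenRidge:
    """Eigendecomposition of a Gram matrix, reused across many lambdas."""

    def __init__(self, gram: np.ndarray, xty: np.ndarray):
        self.evals, self.evecs = scipy.linalg.eigh(gram)
        self.proj = self.evecs.T @ xty

    def solve(self, lam: float) -> np.ndarray:
        if lam == 0 and self.evals.min() <= 1e-12 * max(self.evals.max(), 1.0):
            raise np.linalg.LinAlgError("singular normal equations at lambda=0")
        denom = self.evals + lam
        if self.proj.ndim == 1:
            return self.evecs @ (self.proj / denom)
        return self.evecs @ (self.proj / denom[:, None])


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance input to correlation")
    return float((a @ b) / denom)


# ---------------------------------------------------------------------------
# forward model


class TemporalResponseFunction:
    """Forward encoding model: stimulus feature -> multichannel response.

    Parameters
    ----------
    stimulus_trials : list of 1-D arrays or OnsetEnvelope
        The (normalized) single-channel stimulus feature, one per trial.
    response_trials : list of (n_channels x n_samples) arrays or
        ContinuousRecording, aligned sample-for-sample with the stimulus.
    fs : float
        Common sampling rate in Hz.
    lag_span_ms : (float, float)
        Lag range; default -250..700 ms.
    lambdas : array-like
        Regularization values; weights are averaged across them.

    All trials enter one set of normal equations (designs are built per
    trial and summed, so lag windows zero-pad at trial boundaries rather
    than leaking across them), and all channels share the single stimulus
    design and are solved in one factorization.
    """

    def __init__(
        self,
        stimulus_trials,
        response_trials,
        fs: float,
        lag_span_ms: tuple[float, float] = FORWARD_LAG_SPAN_MS,
        lambdas: np.ndarray | None = None,
    ):
        self.stimulus_trials = [_as_series(s) for s in stimulus_trials]
        self.response_trials = [_as_matrix(r) for r in response_trials]
        if not self.stimulus_trials:
            raise ValueError("need at least one trial")
        if len(self.stimulus_trials) != len(self.response_trials):
            raise ValueError("stimulus/response trial count mismatch")
        for k, (s, r) in enumerate(zip(self.stimulus_trials, self.response_trials)):
            if s.size != r.shape[1]:
                raise ValueError(
                    f"trial {k}: stimulus has {s.size} samples, response {r.shape[1]}"
                )
        n_chan = {r.shape[0] for r in self.response_trials}
        if len(n_chan) != 1:
            raise ValueError("all trials must share the channel count")
        self.n_channels = n_chan.pop()
        self.fs = float(fs)
        self.lag_grid = LagGrid(lag_span_ms[0], lag_span_ms[1], self.fs)
        self.lambdas = (
            default_lambda_grid() if lambdas is None else np.asarray(lambdas, dtype=float)
        )

    def fit(self) -> "TRFResults":
        grid = self.lag_grid
        n_lags = grid.n_lags
        gram = np.zeros((n_lags, n_lags))
        xty = np.zeros((n_lags, self.n_channels))
        t_total = 0
        for s, r in zip(self.stimulus_trials, self.response_trials):
            design = build_lagged_design(s, grid, "forward")
            gram += design.T @ design
            xty += design.T @ r.T
            t_total += s.size
        solver = _EigenRidge(gram, xty)
        per_lambda = np.stack([solver.solve(lam) for lam in self.lambdas])
        weights = per_lambda.mean(axis=0)
        return TRFResults(
            model=self,
            weights=weights,
            weights_per_lambda=per_lambda,
            lag_grid=grid,
            lambdas=self.lambdas.copy(),
            n_trials=len(self.stimulus_trials),
            n_samples_total=t_total,
        )


@dataclass
class TRFWaveform:
    """Postprocessed TRF as a channels x lag-time waveform."""

    data: np.ndarray  # channels x time
    times_ms: np.ndarray
    fs: float


@dataclass
class TRFResults:
    """Fitted forward model: lambda-averaged TRF weights plus metadata."""

    model: TemporalResponseFunction
    weights: np.ndarray  # L x N
    weights_per_lambda: np.ndarray  # n_lambda x L x N
    lag_grid: LagGrid
    lambdas: np.ndarray
    n_trials: int
    n_samples_total: int
    _postprocessed: bool = field(default=False, repr=False)

    @property
    def direction(self) -> str:
        return "forward"

    def predict(self, stimulus) -> np.ndarray:
        """Predicted response (n_channels x n_samples) for one trial."""
        design = build_lagged_design(_as_series(stimulus), self.lag_grid, "forward")
        return (design @ self.weights).T

    def postprocess(
        self,
        lowpass_hz: float = 30.0,
        baseline_ms: tuple[float, float] = (-50.0, 0.0),
        trim_ms: tuple[float, float] = TRF_TRIM_SPAN_MS,
    ) -> TRFWaveform:
        """30 Hz zero-phase lowpass along lags, baseline-correct, trim.

        Mirrors the ERP treatment: the lowpass removes regularization
        ringing, the -50..0 ms mean is subtracted per channel, and the
        200 ms buffers at both lag edges are discarded (-250..700 ms grid
        -> -50..500 ms waveform). Raises on a second invocation.
        """
        if self._postprocessed:
            raise RuntimeError("postprocess() already applied to these results")
        self._postprocessed = True
        wave = self.weights.T.astype(float)  # channels x lags
        sos = sp_signal.butter(3, lowpass_hz, btype="low", fs=self.lag_grid.fs, output="sos")
        wave = sp_signal.sosfiltfilt(sos, wave, axis=1)
        times = self.lag_grid.lag_times_ms
        base = (times >= baseline_ms[0] - 1e-9) & (times <= baseline_ms[1] + 1e-9)
        if not base.any():
            raise ValueError("baseline window outside the lag span")
        wave = wave - wave[:, base].mean(axis=1, keepdims=True)
        keep = (times >= trim_ms[0] - 1e-9) & (times <= trim_ms[1] + 1e-9)
        return TRFWaveform(wave[:, keep].copy(), times[keep].copy(), self.lag_grid.fs)

    def summary(self) -> str:
        lines = [
            "Temporal Response Function (forward ridge model)",
            "=" * 48,
            f"channels:            {self.model.n_channels}",
            f"trials:              {self.n_trials}",
            f"samples (total):     {self.n_samples_total}",
            f"lag span:            {self.lag_grid.tau_min_ms:.0f}..{self.lag_grid.tau_max_ms:.0f} ms"
            f" ({self.lag_grid.n_lags} lags @ {self.lag_grid.fs:.0f} Hz)",
            f"lambdas averaged:    {self.lambdas.size}"
            f" (log-spaced {self.lambdas.min():.0e}..{self.lambdas.max():.0e})",
            f"|h| max (uV):        {np.abs(self.weights).max():.4g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# backward model


class StimulusDecoder:
    """Backward model: multichannel response -> stimulus feature.

    ``channels`` selects a subset of response channels (indices); single-
    channel decoding is the degenerate subset of length one. ``scheme``
    selects how multiple training trials combine: ``"per-trial"`` fits one
    decoder per trial and averages the weights (the default), while
    ``"concatenated"`` pools all trials into one set of normal equations.
    """

    def __init__(
        self,
        response_trials,
        stimulus_trials,
        fs: float,
        lag_span_ms: tuple[float, float] = BACKWARD_LAG_SPAN_MS,
        lambdas: np.ndarray | None = None,
        channels: list[int] | None = None,
        scheme: str = "per-trial",
    ):
        if scheme not in ("per-trial", "concatenated"):
            raise ValueError("scheme must be 'per-trial' or 'concatenated'")
        self.response_trials = [_as_matrix(r) for r in response_trials]
        self.stimulus_trials = [_as_series(s) for s in stimulus_trials]
        if not self.response_trials:
            raise ValueError("need at least one training trial")
        if len(self.response_trials) != len(self.stimulus_trials):
            raise ValueError("stimulus/response trial count mismatch")
        for k, (r, s) in enumerate(zip(self.response_trials, self.stimulus_trials)):
            if r.shape[1] != s.size:
                raise ValueError(f"trial {k}: response/stimulus length mismatch")
        if channels is not None:
            self.response_trials = [r[np.asarray(channels)] for r in self.response_trials]
        self.channels = channels
        self.n_channels = self.response_trials[0].shape[0]
        self.fs = float(fs)
        self.lag_grid = LagGrid(lag_span_ms[0], lag_span_ms[1], self.fs)
        self.lambdas = (
            default_lambda_grid() if lambdas is None else np.asarray(lambdas, dtype=float)
        )
        self.scheme = scheme

    def _fit_single_trial(self, response: np.ndarray, stimulus: np.ndarray) -> np.ndarray:
        design = build_lagged_design(response, self.lag_grid, "backward")
        solver = _EigenRidge(design.T @ design, design.T @ stimulus)
        return np.mean([solver.solve(lam) for lam in self.lambdas], axis=0)

    def fit(self) -> "DecoderResults":
        if self.scheme == "per-trial":
            per_trial = np.stack(
                [
                    self._fit_single_trial(r, s)
                    for r, s in zip(self.response_trials, self.stimulus_trials)
                ]
            )
            weights = per_trial.mean(axis=0)
        else:
            n_cols = self.n_channels * self.lag_grid.n_lags
            gram = np.zeros((n_cols, n_cols))
            xty = np.zeros(n_cols)
            for r, s in zip(self.response_trials, self.stimulus_trials):
                design = build_lagged_design(r, self.lag_grid, "backward")
                gram += design.T @ design
                xty += design.T @ s
            solver = _EigenRidge(gram, xty)
            weights = np.mean([solver.solve(lam) for lam in self.lambdas], axis=0)
            per_trial = weights[None, :]
        return DecoderResults(
            model=self,
            weights=weights,
            per_trial_weights=per_trial,
            lag_grid=self.lag_grid,
            lambdas=self.lambdas.copy(),
            n_trials=len(self.response_trials),
        )


@dataclass
class DecoderResults:
    """Fitted backward model: averaged spatiotemporal decoding filter."""

    model: StimulusDecoder
    weights: np.ndarray  # (N*L,)
    per_trial_weights: np.ndarray  # n_trials x (N*L)
    lag_grid: LagGrid
    lambdas: np.ndarray
    n_trials: int

    @property
    def direction(self) -> str:
        return "backward"

    def reconstruct(self, response, weights: np.ndarray | None = None) -> np.ndarray:
        """Estimated stimulus series for one response trial."""
        r = _as_matrix(response)
        if self.model.channels is not None and r.shape[0] != self.model.n_channels:
            r = r[np.asarray(self.model.channels)]
        design = build_lagged_design(r, self.lag_grid, "backward")
        w = self.weights if weights is None else weights
        return design @ w

    def accuracy(self, response, stimulus, weights: np.ndarray | None = None) -> float:
        """Pearson correlation between the true and reconstructed stimulus."""
        return pearson_r(self.reconstruct(response, weights), _as_series(stimulus))

    def summary(self) -> str:
        lines = [
            "Stimulus-Reconstruction Decoder (backward ridge model)",
            "=" * 54,
            f"channels used:       {self.model.n_channels}",
            f"training trials:     {self.n_trials} ({self.model.scheme})",
            f"lag span:            {self.lag_grid.tau_min_ms:.0f}..{self.lag_grid.tau_max_ms:.0f} ms"
            f" ({self.lag_grid.n_lags} lags @ {self.lag_grid.fs:.0f} Hz)",
            f"lambdas averaged:    {self.lambdas.size}"
            f" (log-spaced {self.lambdas.min():.0e}..{self.lambdas.max():.0e})",
            f"|g| max:             {np.abs(self.weights).max():.4g}",
        ]
        return "\n".join(lines)


def loo_reconstruction(
    response_trials,
    stimulus_trials,
    fs: float,
    lag_span_ms: tuple[float, float] = BACKWARD_LAG_SPAN_MS,
    lambdas: np.ndarray | None = None,
    channels: list[int] | None = None,
    scheme: str = "per-trial",
) -> tuple[np.ndarray, float]:
    """Leave-one-trial-out stimulus-reconstruction accuracy.

    For each held-out trial, one decoder per remaining training trial is
    fitted, the decoders are averaged with equal weights, the average is
    applied to the held-out response, and the accuracy is the Pearson
    correlation with the true stimulus. Each trial is held out exactly
    once; returns the per-fold correlations and their mean.
    """
    n = len(response_trials)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 trials")
    model = StimulusDecoder(
        response_trials, stimulus_trials, fs, lag_span_ms, lambdas, channels, scheme
    )
    r_per_fold = np.empty(n)
    if scheme == "per-trial":
        fitted = model.fit()
        per_trial = fitted.per_trial_weights
        for fold in range(n):
            train = np.delete(np.arange(n), fold)
            if train.size < 2:
                raise ValueError("fewer than 2 training trials")
            avg = per_trial[train].mean(axis=0)
            r_per_fold[fold] = fitted.accuracy(
                response_trials[fold], stimulus_trials[fold], weights=avg
            )
    else:
        for fold in range(n):
            train = [k for k in range(n) if k != fold]
            sub = StimulusDecoder(
                [response_trials[k] for k in train],
                [stimulus_trials[k] for k in train],
                fs, lag_span_ms, lambdas, channels, scheme,
            ).fit()
            r_per_fold[fold] = sub.accuracy(response_trials[fold], stimulus_trials[fold])
    return r_per_fold, float(r_per_fold.mean())
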