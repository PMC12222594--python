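# Methods

This note documents the models and procedures implemented in `speechtrack`,
the assumptions behind them, and the choices made where the design was
genuinely open. All numbers quoted here are computed by the test suite or
by `scripts/acceptance.py`; none are asserted from memory.

## The analysis model

The package treats continuous speech listening as a superposition of
transient evoked responses to acoustic edges. Under that premise, three
views of the same underlying response are computed and compared:

* **ERP view.** Salient intensity rises (edges) in the speech onset
  envelope act as triggers; averaging EEG sweeps around them yields a
  P1-N1-P2 complex. Selective attention enhances the N1 (the *N1 effect*),
  so attended-stream ERPs are larger than ignored-stream ERPs.
* **Forward-regression view.** The temporal response function (TRF)
  h(τ, n) is the linear impulse response from the onset envelope s(t) to
  each EEG channel r(t, n): r(t,n) = Σ_l s(t−τ_l) h(τ_l, n) + ε(t,n). When
  the EEG truly is a superposition of edge-evoked responses, the TRF is an
  unbiased deconvolution of the same kernel that the ERP estimates by
  triggered averaging — so the two waveforms should agree up to a small
  latency offset introduced by the threshold rule (a threshold crossing
  precedes the pulse peak, delaying the apparent ERP latency).
* **Backward-regression view.** A decoder g reconstructs the envelope from
  lagged multichannel EEG, ŝ(t) = Σ_n Σ_l r(t+τ_l, n) g(τ_l, n).
  Reconstruction accuracy (Pearson r between ŝ and s) is the standard
  speech-tracking / attention-decoding measure. If attention improves the
  single-sweep SNR of the evoked response, attended envelopes reconstruct
  better, and the effect should co-vary with the phase stability of the
  sweeps.

Phase stability is quantified by the wavelet phase synchronization
stability (WPSS, also called the phase-locking factor or inter-trial phase
coherence): at each time-frequency cell, the resultant length
|K⁻¹ Σ_k e^{iφ_k}| of the instantaneous phases of K sweeps. The transform
uses analytic generalized Morse wavelets ψ_{γ,β} built directly in the
frequency domain as ω^β e^{−ω^γ} on positive frequencies, so analyticity is
exact. The default (γ=3, β=3.29) maximises time-frequency symmetry at a
nearly minimal Heisenberg area and places one oscillation cycle of the peak
frequency (√(βγ)/π ≈ 1.00 cycles) inside the central energy window; its
footprint at theta frequencies (125–250 ms) motivates reducing the WPSS
over the whole N1–P2 window rather than the N1 alone.

The WPSS is used strictly as a waveform-consistency statistic; it does not
discriminate between phase-reset and additive accounts of ERP generation,
and the package makes no claim about that question.

## Processing chain and fixed parameters

| stage | parameter | value | note |
|---|---|---|---|
| envelope | gammatone bands | 128, ERB-spaced, 100–8000 Hz | Slaney-convention band edges; 4th-order IIR |
| envelope | compression | x^0.3 | loudness-like power law on Hilbert magnitudes |
| onset envelope | lowpass | 25 Hz, 3rd-order Butterworth, zero-phase | then first difference, half-wave rectification |
| analysis rate | fs | 256 Hz | envelopes decimated; EEG simulated/decimated to match |
| trigger rule | threshold | 2·σ_env | σ_env pooled over all (2 × trials) envelopes per subject, population convention |
| trimming | edges | 1 s per trial end | removes filter edge artifacts |
| epochs | window | −500…2000 ms | baseline −50…0 ms; rejection at ±100 µV |
| TRF | lags | −250…700 ms | reported span −50…500 ms after removing 200 ms buffers |
| decoder | lags | 0…500 ms | leave-one-trial-out, per-trial decoders averaged |
| ridge | λ grid | 20 log-spaced, 1e−6…1e6 | weights averaged over λ, no cross-validation |
| WPSS | scales | 17/octave, 2–32 Hz inclusive (69 scales) | theta reduction uses the 4–8 Hz subset of the same grid |
| stats | cluster test | two-tailed t, thresholds 0.01/0.05, 10000 sign-flip permutations | 1-D temporal or 2-D 4-neighbour adjacency, within channel |

Filtering convention throughout: Butterworth designed for 3 dB attenuation
at the cutoff, applied via forward and backward passes (zero phase, 6 dB at
cutoff net).

Conventions chosen where several were defensible:

* σ_env uses the population (divide-by-N) standard deviation — pools are
  ~10⁶ samples, so the distinction from N−1 is negligible.
* A crossing at the very first sample is not a trigger (no predecessor to
  verify a sub→supra transition). No refractory period is imposed.
* Envelope pooling happens after decimation to 256 Hz, matching the stated
  processing order.
* The first difference is not scaled by fs: the threshold is in pooled-σ
  units and invariant to global scaling.
* λ regularizes the raw normal equations (no eigenvalue-mean scaling, no
  intercept column; data are centered beforehand).
* Trials are concatenated by summing per-trial normal equations, so lag
  windows zero-pad at trial boundaries instead of leaking across trials.
* Decoder training fits one decoder per training trial and averages them
  with equal weights; a pooled ("concatenated") variant is available via
  `scheme="concatenated"` for sensitivity analysis.
* Peak search windows on the attended grand average default to N1 ∈
  [80, 180] ms and P2 ∈ [180, 280] ms at the peak-topography channel; the
  ignored condition reuses the attended window centers, and component
  amplitudes are windowed means (center ± 20 ms) with N1P2 = P2 − N1.
* Spatial (topographic) correlation requires ≥ 3 channels; degenerate
  frames raise instead of returning NaN. The ERP–TRF lag search spans ±125
  ms and aggregates across participants by maximizing the participant-mean
  normalized cross-correlation at the peak-topography channel.
* Zero-magnitude wavelet coefficients get phase 0 (logged), keeping WPSS
  defined on degenerate inputs.
* Cluster masses are summed |t| over sign-homogeneous connected clusters;
  positive and negative clusters are scored against the same max-mass null.
  Sign flips are fully enumerated when 2^n ≤ n_perm.

## The synthetic cohort

`speechtrack.simulate` generates the study conditions the pipeline is
validated on: per subject, 20 trials of 50 s at 256 Hz with 16 channels
(64 supported), two concurrent streams per trial.

* **Pulse trains.** Inter-onset intervals are gamma-distributed (shape 2,
  mean 1/rate, rate 3.5 events/s): irregular but non-Poisson, like syllable
  onsets. Pulses are Gaussians of width σ = 4 ms; heights are log-normal
  (median 1, σ_ln = 0.75), calibrated so that ~78–80 % of pulses clear the
  pooled 2σ_env threshold and the trigger rate lands near 2.7 events/s.
  The amplitude law is a stand-in — the distribution of real onset-envelope
  pulse heights is not characterized here — chosen to produce both supra-
  and subthreshold events.
* **Kernels.** Attended: P1 +0.5 µV @ 80 ms (σ 15 ms), N1 −1.0 µV @ 135 ms
  (σ 22 ms), P2 +0.8 µV @ 225 ms (σ 30 ms). Ignored: identical except the
  N1 amplitude is multiplied by the attention gain 0.4. All attention
  effects in the generator flow through this single N1 gain.
* **Topography.** Unit-norm Gaussian profile over a nominal scalp arc,
  peaking at a designated central ("Cz-like") channel — a frontocentral
  distribution in miniature.
* **Noise.** 1/f-shaped Gaussian noise, independent across channels
  (spatially correlated mixing available behind a flag), scaled per trial
  to an SNR of −10 dB between the pooled evoked signal and the noise — a
  realistic single-sweep evoked-response SNR. Determinism: all draws
  descend from one `SeedSequence`, so identical specs give byte-identical
  cohorts.

What the generator does **not** emulate: real envelope statistics
(amplitude distribution, serial correlations of speech), non-Gaussian EEG
artifacts (blinks, muscle), volume-conduction-realistic topographies and
spatially structured background rhythms, subject heterogeneity in kernel
shape or latency, and any nonlinearity between stimulus and response.
Passing tests therefore demonstrate that the pipeline's estimators recover
a known linear superposition model under realistic noise — not that the
same effect sizes would be observed on recorded EEG.

A known consequence of the threshold rule is visible in the synthetic
results exactly as expected from its geometry: the threshold crossing
precedes the pulse peak by a few milliseconds, so the ERP N1 appears ~4–6
ms later than the generative 135 ms while the TRF, a true deconvolution,
peaks at the kernel latency. The matched sweep minimum (~2350 per condition
on the default cohort) sits ~5 % below the raw trigger count because sweeps
whose −500…2000 ms window leaves the trimmed trial are discarded.

## Problem sizes in tests and the acceptance script

Unit and property tests run on seconds-scale fixtures. The acceptance
computations use the default cohort (12 subjects × 20 trials × 50 s,
16 channels, 256 Hz) and 4 replicate cohorts for the attention-effect
fractions — a fraction of 1.0 over 4 replicates is required, which is a
stricter per-replicate bar than 95 % of a larger ensemble. The WPSS
attention scalar is computed from the theta-band scales at the
peak-topography channel only (exactly the cells entering the reduction);
full-grid maps are available through `wavelet.MorseFamily` defaults.
Cluster-test calibration uses simulated null datasets at n_perm = 1000
(500 datasets in the test suite, 1000 in the acceptance script for a
tighter Monte-Carlo estimate); the uniform-phase WPSS level uses K = 100
sweeps × 10⁴ replicate cells against the closed-form Rayleigh expectation
√π/2 · K^(−1/2).

## Numerical notes and limitations

* Morse kernels are constructed on the epoch-length DFT grid; the circular
  construction keeps analyticity exact but assumes the kernel has decayed
  within the epoch — true for ≥ 2 Hz on 2.5 s epochs.
* The CWT uses 'same'-aligned linear convolution; cone-of-influence
  contamination is pushed outside the reported −50…500 ms span by
  transforming the full −500…2000 ms epoch first.
* `wpss_from_sweeps` streams the transform scale-by-scale (identical
  results to the naive path within 1e-10, verified by test) to keep memory
  flat across thousands of sweeps.
* Ridge solves share one eigendecomposition of the Gram matrix across the
  20 λ values; λ = 0 on a singular system raises rather than silently
  pseudo-inverting.
* Permutation p-values are bounded below by 1/(n_perm+1); the significance
  rule (mass strictly above the (1−p_cluster) null quantile) makes the
  cluster test slightly conservative at small n_perm.
* Single-channel decoding of a causal response kernel cannot reach r = 1
  even noiselessly when inversion requires negative lags; the 0…500 ms lag
  window matches a response that follows the stimulus.
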