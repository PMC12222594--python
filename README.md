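# speechtrack

Linear-modeling and ERP analysis of selective attention to continuous
speech, for auditory-neuroscience researchers working with cocktail-party
EEG. The package links the classical event-related-potential (ERP) view of
auditory attention to the regression-based speech-tracking view by running
both on the same stimulus representation — the speech **onset envelope** —
and quantifying how the attention-enhanced N1 component drives forward and
backward model performance.

## What it computes

Given two-speaker EEG (one attended, one ignored stream per trial) and the
speech onset envelopes of both streams:

1. **Speech-evoked ERPs.** The onset envelope (half-wave-rectified
   derivative of the 25 Hz-lowpassed broadband envelope from a 128-band
   gammatone filter bank, power-law compressed with x^0.3) is thresholded
   at twice its pooled standard deviation, 2·σ_env. Each sub- to
   suprathreshold crossing triggers an EEG sweep (−500…2000 ms), which is
   baseline-corrected (−50…0 ms), artifact-screened (±100 µV) and averaged
   after matching sweep counts across conditions.
2. **Forward TRFs.** The temporal response function h solves
   r(t,n) = Σ_l s(t−τ_l) h(τ_l,n) + ε by ridge regression,
   h = (SᵀS + λI)⁻¹Sᵀr, over lags −250…700 ms. Instead of cross-validating
   λ, models are fitted on 20 log-spaced λ ∈ [1e−6, 1e6] and the weights
   averaged, then lowpassed at 30 Hz, baseline-corrected and trimmed to
   −50…500 ms for comparison with the ERPs.
3. **Backward stimulus reconstruction.** A spatiotemporal decoder
   g = (RᵀR + λI)⁻¹Rᵀs (lags 0…500 ms) is fitted per training trial; the
   held-out trial is decoded by the average of the remaining trials'
   decoders (leave-one-out), and accuracy is Pearson's r between the true
   and reconstructed envelope. Decoding runs on any channel subset,
   including single channels.
4. **Phase consistency (WPSS).** Sweeps are transformed with analytic
   generalized Morse wavelets ψ_{γ=3, β=3.29} (17 scales/octave, 2–32 Hz);
   the wavelet phase synchronization stability at each time–frequency cell
   is the resultant length |K⁻¹ Σ_k e^{iφ_k}| across sweeps — 1 for perfect
   phase locking, 0 for desynchronization. The attention measure averages
   the theta band (4–8 Hz) over the N1–P2 window.
5. **Group statistics.** One-tailed paired t-tests (attended > ignored) for
   scalar measures, and sign-flip cluster-mass permutation tests
   (two-tailed t, 10000 permutations, thresholds 0.01/0.05) for waveforms
   and time–frequency maps.

A synthetic cocktail-party generator (`speechtrack.simulate`) produces
cohorts with known ground truth — P1-N1-P2 kernels whose N1 is enhanced for
the attended stream, a frontocentral topography, gamma-spaced log-normal
pulse trains and 1/f noise — so every stage of the pipeline is testable
against the parameters that generated the data.

## Worked example

```python
import numpy as np
from speechtrack import CohortSpec
from speechtrack.attention import analyze_subject
from speechtrack.simulate import simulate_subject

cohort = CohortSpec(seed=1)                    # 20 trials x 50 s, 16 channels
recordings, envelopes, truth = simulate_subject(cohort, 0)
ana = analyze_subject(recordings, envelopes, truth.peak_channel, seed=3)

print(f"matched sweeps per condition: {ana.n_matched}")
print(f"trigger rate: {ana.trigger_rate:.2f} /s")
print(f"SR accuracy  attended {ana.sr_accuracy['attended']:.3f}"
      f"  ignored {ana.sr_accuracy['ignored']:.3f}")
for cond in ("attended", "ignored"):
    theta = ana.wpss_maps[cond].values.mean()
    print(f"WPSS theta mean ({cond}): {theta:.3f}")
```

Output for this seed:

```
matched sweeps per condition: 2475
trigger rate: 2.75 /s
SR accuracy  attended 0.316  ignored 0.218
WPSS theta mean (attended): 0.542
WPSS theta mean (ignored): 0.386
```

The acoustic edges of the attended stream trigger ~2.7 sweeps per second.
The attended envelope is reconstructed better than the ignored one
(r 0.32 vs 0.22) and the evoked responses to attended edges are more
phase-stable in the theta band (0.54 vs 0.39) — the qualitative signature
of the attention-driven N1 enhancement that the generator embeds.

The fitted models follow the model/results pattern:

```python
from speechtrack import TemporalResponseFunction
model = TemporalResponseFunction(stim_trials, eeg_trials, fs=256)
res = model.fit()           # lambda-averaged TRF weights
wave = res.postprocess()    # 30 Hz lowpass, baseline, -50..500 ms
print(res.summary())
```

A thin CLI wraps the same functions:
`speechtrack simulate|envelope|trf|decode --help`.

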