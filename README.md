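# timepop

Population analysis of time-interval reproduction.

In an interval-reproduction task a subject measures the duration of a
sensory stimulus (3–7.5 s, drawn from a seven-value grid) and then
reproduces it with its own behavior while neurons are recorded. Behavior in
such tasks shows the *regression effect* (central tendency, Vierordt's law):
short intervals are overestimated and long ones underestimated, so the slope
of reproductions `r` on stimuli `s` is below 1, and response variability is
*scalar* (SD ∝ s, constant CV). `timepop` is for researchers who want to ask
how a recorded neural population measures, stores and reproduces such
intervals — and which single-cell response types (constant-slope ramps,
ramp-to-threshold cells, phasic cells, stimulus-tuned cells) can or cannot
account for the behavioral regression effect under a linear readout.

The package implements, as a tested reusable pipeline:

* **Synthetic sessions** — a shrinkage observer
  (`r = λ·m + (1−λ)·μ + production noise`, with `m = s(1 + w_m z)`), the
  adaptive ±3% reward tolerance, and inhomogeneous-Poisson spike trains from
  stereotype rate profiles, so every analysis stage is verifiable at desk
  scale without recordings.
* **Behavioral statistics** — regression slope,
  `CV(r) = E_s[STD_s(r)/E[r|s]]`, `BIAS(r) = E_s[E[r|s] − s]`.
* **Spike density functions** — causal 100 ms binning, per-stimulus warping
  of reproduction trials, time normalization, per-unit z-scoring, shuffle
  and noise surrogates.
* **Correlation battery** — pairwise, population-vector, cross-phase and
  cross-stimulus Pearson correlations with significance fractions.
* **Temporal scaling** — centers of mass, scaling indices
  (`COM(s)/COM(5.25 s)`, analytically 0.57–1.43 for a perfectly scaling
  unit), shuffled-identity controls, subsampled two-sample KS tests.
* **Demixed and conventional PCA** — exact marginalization-based demixing of
  time-course vs stimulus components, stratified 10% bootstraps, trajectory
  length/speed per stimulus.
* **Response-type categorization** — reconstruction explained variance,
  strongest-component + 22.5° angle rule, surrogate chance counts,
  measurement→reproduction transition tables.
* **Linear time decoding** — Wiener filter `R·β = t` on z-scored SDFs with
  σ=0.5 fit noise and 20-cell bootstraps; final-value regression slopes for
  stereotype populations and mixtures (slope ≈ 1 for constant-slope ramps,
  ≈ 0 for ramp-to-threshold cells, monotone in between).
* **Speed modulation** — speed response functions in 5 cm/s bins,
  max-of-10-shuffles Levene significance, index `(r90−r10)/(r90+r10)`.

## Worked example

```python
import numpy as np
from timepop import generate_session, SessionConfig
from timepop.behavior import summarize
from timepop import sdf as S
from timepop.decode import bootstrap_decode

cfg = SessionConfig(n_trials=120, n_units=24, rate_noise_sd=0.3, seed=7)
trials, spikes = generate_session(cfg)
summary = summarize(trials)
print(f"slope = {summary.slope:.3f}  CV = {summary.cv:.3f}  "
      f"bias = {summary.bias:+.3f} s  reward rate = {summary.reward_rate:.2f}")

warped = S.warp_reproduction_trials(spikes)
repro = S.normalize_and_zscore(S.compute_sdf(warped, "reproduction"), n_bins=40)
boot = bootstrap_decode(repro, subset_size=20, runs=200, seed=1)
print(f"decoded final values (s): {np.round(boot.decoded_mean[:, -1], 2)}")
print(f"median final-value slope = {boot.median_slope:.2f} "
      f"(IQR {boot.iqr[0]:.2f}-{boot.iqr[1]:.2f})")
```

Output:

```
slope = 0.730  CV = 0.109  bias = -0.000 s  reward rate = 0.51
decoded final values (s): [4.19 3.77 4.31 4.77 4.68 4.41 4.91]
median final-value slope = 0.26 (IQR 0.23-0.29)
```

The behavioral slope of 0.73 reproduces the observer's shrinkage weight
(λ = 0.7): the session shows a clear regression effect with ~11% scalar
variability and no overall bias. Decoding elapsed time from the default
mixed population (ramps, ramp-to-threshold, phasic, tuned and noise cells)
yields final decoded values compressed toward the mean duration — a
final-value slope of 0.26, i.e. a *stronger* regression effect than the
behavior, because only part of the population carries veridical duration
information. Pure constant-slope ramp populations decode with slope ≈ 1 and
pure ramp-to-threshold populations with slope ≈ 0; mixing the two response
types sweeps the decoded regression effect between these extremes.

A command-line interface runs the same stages end to end:

```bash
timepop all --seed 7 --out runs/demo        # simulate + every analysis
timepop decode --seed 7 --out runs/decode   # one stage (plus dependencies)
```

Each run writes CSV/JSON/HDF5 outputs and a manifest with per-stage
sub-seeds and content hashes; identical config and seed give byte-identical
results.

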