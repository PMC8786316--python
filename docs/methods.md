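# Methods

`timepop` analyzes time-interval reproduction experiments in which a subject
measures the duration of a sensory stimulus (the *measurement* phase) and then
reproduces it with its own behavior (the *reproduction* phase), while a
population of neurons is recorded. The package implements the full analysis
chain — spike density functions, correlation batteries, temporal scaling,
demixed and conventional PCA, response-type categorization, linear time
decoding, and running-speed modulation — together with a synthetic-data
generator that makes every stage testable without recordings.

## The task and the synthetic generator

Stimulus durations are drawn from a discrete uniform grid of seven values,
3–7.5 s in 0.75 s steps (mean 5.25 s). A trial is rewarded when the
reproduction `r` falls within `(1±k)·s` of the stimulus `s`; the tolerance
`k` narrows by 3 percentage points after a reward and widens by 3 otherwise,
floored at 0 (no floor is physically required, but tolerances near zero are
where adaptive staircases operate; the floor only prevents a negative width).

**Observer model.** Reproductions come from a shrinkage observer:
`m = s·(1 + w_m·z₁)` is a noisy internal measurement,
`center = λ·m + (1−λ)·μ` shrinks it toward a prior mean `μ` (defaults to the
grid mean), and `r = center·(1 + w_p·z₂)` adds multiplicative production
noise. This is the minimal generative model with the two signatures of
interval reproduction: a regression slope of `E[r|s]` on `s` equal to `λ < 1`
(central tendency) and `SD(r|s) ∝ s` (scalar variability, constant CV). The
error-minimizing shrinkage for a given sensory noise is
`λ* = 1/(1 + w_m²·mean(grid)²/var(grid))`, which couples response
variability to regression strength — the mechanism behind the negative
slope–CV correlation across sessions. Defaults: `λ=0.7`, `w_m=w_p=0.1`,
values typical of rodent timing performance in this duration range.

**Stereotype neurons.** Firing-rate profiles cover the response types that
matter for time decoding:

| kind | rate on [0, s] | role |
|---|---|---|
| `linear_increasing` | `b + a·t`, same slope for all `s` | end rate encodes duration → veridical decoding |
| `ramp_to_threshold_up/down` | `b ± A·t/s` | same end level for all `s` → encodes only the mean duration |
| `phasic_absolute` | Gaussian bump at a fixed clock time | absolute-time tiling |
| `phasic_relative` | bump at `phase·s`, width `∝ s` | scales with the interval |
| `stimulus_constant` | time-constant, linear in `s` | pure stimulus tuning |
| `unrelated_noise` | baseline | null cells |

All rates are rectified at 0 Hz; optional additive rate noise is piecewise
constant on a 100 ms grid, and optional speed modulation adds
`gain·speed(t)`. Spike trains are inhomogeneous Poisson, generated by
thinning against a per-profile rate bound; validity is checked by the
time-rescaling theorem (transformed ISIs are Exp(1)). Sessions place a
stimulus-independent reaction-time gap of 1–3 s (uniform) between phases.
Running speed is smoothed Gaussian noise restandardized to a configurable
mean/SD (defaults 40/15 cm/s) and clipped at 0; this reproduces broad,
autocorrelated speed coverage but none of the kinematics of real locomotion
(no acceleration limits, no stimulus-locked starts/stops), so speed analyses
on synthetic data validate calibration and power, not behavioral realism.

What the generator does *not* emulate: learning across sessions, premature
movements during measurement, spike-sorting artifacts, non-Poisson
variability, and correlated noise across neurons. Passing tests therefore
demonstrate correctness of the analysis chain and its statistical
calibration, not that real cortex behaves like the stereotypes.

## Spike density functions

Spikes are counted per unit, stimulus and phase in 100 ms bins that are
right-aligned (each bin's value sits at its trailing edge, looking into the
past) so the SDF is causal; bins partially outside the phase at the
non-aligned edge are dropped. Reproduction trials of one stimulus differ in
duration, so each trial's reproduction spikes are first warped linearly onto
the stimulus' mean reproduced duration (spike counts preserved). Traces are
then linearly interpolated to a common number of bins (default 40 — roughly
the 3 s stimulus at 100 ms resolution, configurable) and z-scored **per unit
over the concatenation of its stimulus traces within a phase**. Per-trace
z-scoring would equalize amplitudes across stimuli and destroy exactly the
across-stimulus ordering the stimulus component must capture; the per-unit
convention removes cell-specific rate scales while keeping stimulus
information. Linear interpolation preserves the center of mass of piecewise
smooth traces to first order (verified to <1% on closed-form ramps).

Two surrogates act as null models downstream: `shuffled` permutes unit
identities independently per stimulus (destroys cell-specific stimulus
organization), and `noise` permutes each trace's bins (destroys within-trial
timing while preserving the marginal value distribution). A causal
half-Gaussian kernel (3-bin SD, renormalized at the left edge) is available
for display only and enters no statistic.

## Correlation battery

All correlations are Pearson on the time-normalized, z-scored tensors:
pairwise unit correlations, across-unit population-vector correlations in
corresponding bins of the two phases, per-unit cross-phase correlations, and
population/per-unit correlations between stimulus pairs. Significance is the
t-distribution test for a correlation, two-sided, α=0.05, with no
multiple-testing correction (each entry is reported individually, and the
summary is simply the fraction significant). Zero-variance traces yield
undefined entries that are excluded from fractions. On white-noise
populations every mode's significant fraction sits at the nominal 5% level.

## Temporal scaling

The center of mass (COM) of a trace on `[0, T]` is `Σ tᵢwᵢ/Σ wᵢ` with bin
centers `tᵢ`. Because z-scored traces have negative values, weights are the
trace shifted by its minimum — applied identically to data and controls so
the convention cancels in comparisons. Scaling indices divide each unit's
COM (in seconds) by its COM at the 5.25 s reference stimulus; a unit whose
rate depends only on `t/s` has index `s/5.25` (0.57–1.43 on the grid), an
absolute-clock unit stays near 1. The control permutes unit labels
independently per stimulus before forming indices. Because full-sample KS
tests on thousands of units detect trivial differences, data and control
index distributions are compared by repeated two-sample KS tests on 10%
subsamples (without replacement; the fraction of runs with p<0.05 is the
summary). The KS p-value is computed exactly when subsamples are small
enough; note that the exact two-sample KS test is discrete and slightly
conservative below ~100 points per sample.

Reproduction-phase COMs use the per-stimulus mean reproduced duration as the
time base, consistent with the warping convention.

## Population decomposition

The z-scored tensor `X[u, s, i]` (units × stimuli × bins) is split
additively: the time marginal is the mean over stimuli and the stimulus
marginal is the remainder, which sums to zero over stimuli at every unit and
bin. SVD of each marginal gives time components (bins-long traces, identical
across stimuli by construction — demixing is exact, not approximate) and
stimulus components (per-stimulus traces whose bin-mean is the per-stimulus
amplitude), with per-unit scores and percent of total tensor variance per
component. The marginals are orthogonal in sum of squares, so time EV +
stimulus EV + residual = 100% exactly; stimulus × time interaction variance
is deliberately left in the residual rather than absorbed by cross-marginal
regression — planted-factor tests show the simple decomposition recovers
ramp and stimulus-ordered factors to <5° subspace angle, which is the
property the downstream categorization needs. Component signs are fixed
(largest-magnitude element positive) so decompositions are deterministic.

Conventional PCA is the same SVD applied to the full per-stimulus tensor; its
per-stimulus trajectories mix time-course and stimulus information.
Trajectory length per stimulus sums Euclidean steps of the population state
projected onto the leading components, and mean speed divides by the
stimulus' real duration: absolute-clock populations give equal speeds and
length ∝ duration; time-rescaling populations give equal lengths and speed ∝
1/duration.

The bootstrap refits the demixed decomposition on stratified 10% unit
subsamples (strata are, e.g., animals of origin), aligns component signs to
the full fit, and aggregates components, explained variances and the
correlation between time-PC scores and stimulus-PC scores.

## Response-type categorization

A unit's traces are reconstructed as the score-weighted sum of a fixed
candidate set (measurement: time PC 1 + stimulus PC 1; reproduction: time
PCs 1–3 + stimulus PC 1). Units whose full reconstruction explains less
variance than a phase threshold (defaults 6% and 28%; configurable, since
these cut-offs derive from a specific data set's cumulative explained
variance) are 'unrelated activity'. Otherwise the strongest component
(largest |score|) contributes, and another component contributes iff
`arctan(|score_j|/|score_strongest|) > 22.5°`, i.e. iff its absolute score
exceeds `tan 22.5° ≈ 0.414` of the strongest. For this comparison all
candidate components are normalized to unit Frobenius norm in the common
(stimuli × bins) space, with scores rescaled accordingly — a time component
replicated over S stimuli otherwise carries norm √S and the angle would be
biased against it. With K candidates the category lattice has 2^K members
(the empty set = unrelated); the rule is invariant to component sign flips,
and raising the EV threshold can only move units into 'unrelated'.

Chance-level counts come from surrogates that shuffle traces across stimuli
and cells before re-running decomposition and categorization; the empirical
two-sided p compares observed counts with the surrogate distribution. Note
what this surrogate preserves: single-trace shapes. It destroys consistent
stimulus ordering and cell identity, so stimulus-tuned categories are the
ones that exceed chance on tuned populations. Bootstrap-stabilized labels
project every unit onto each subsampled decomposition's components and take
the modal category, ties broken toward the smaller component set.

## Time decoding

The decoder is a Wiener filter: the design matrix R stacks each unit's
time-normalized z-scored SDFs over all stimuli (rows = stimuli × bins), the
target is real elapsed time `t = (i+1)/n_bins · duration(s)` — real seconds,
so final targets differ across stimuli, which is what makes a final-value
regression meaningful. Weights plus an unpenalized intercept solve
`[R, 1]·[β; c] = t` by least squares (minimum-norm for rank-deficient
designs). The intercept is part of the model: a population whose normalized
profiles are stimulus-invariant (ramp-to-threshold) then decodes the *mean*
duration at every stimulus — without the intercept the same population would
decode roughly half the mean, which misrepresents what such cells can encode.
Zero-mean Gaussian noise (σ=0.5, z-units) is added to R at fit time only, as
regularization against overfitting; decoding uses the clean SDFs.

The regression effect is the OLS slope of final decoded values on true
durations: ≈1 for linear-increasing populations, ≈0 for ramp-to-threshold
populations, intermediate for mixtures, and non-increasing in the
slope-changing fraction. Bootstrapping fits and decodes on random 20-unit
subsets (default 1000 runs; the shipped experiments use 200, which leaves
the median slope stable to <0.01) and reports mean ± SD of decoded series
plus median and IQR of slopes (regression per run, then the median — not a
regression on medians). Reproduction-phase durations are the per-stimulus
mean reproduced durations; measurement-phase durations the stimuli.

## Speed modulation

The speed response function counts spikes at each running speed (5 cm/s bins
from 10 to 100 cm/s) divided by occupancy time. The control circularly
shifts spike times by a uniform offset — preserving ISI structure, the
conservative choice among shuffles — recomputes the response 10 times, and
keeps the shuffle with the largest across-bin variance; a one-sided Levene
test then asks whether the true response's variance exceeds that control.
Because the control is the maximum of 10 exchangeable draws, this test is
deliberately robust and *conservative under the null* (its false-positive
rate is far below the nominal 5%), while retaining >90% power against
plausible linear speed gains. The modulation index contrasts the lowest and
highest 10% of occupied speed bins, `(r90−r10)/(r90+r10) ∈ [−1, 1]`;
'percentiles' are taken over the speed axis (lowest/highest occupied bins),
not over occupancy.

## Pipeline and determinism

`run_pipeline` executes simulate → behavior → SDF → correlations / scaling /
decomposition / categorization / decoding / speed in dependency order. Every
stage receives a sub-seed obtained by hashing (master seed, stage name), so
toggling or adding stages never perturbs the randomness of others; identical
config + seed yields byte-identical outputs. A manifest records each stage's
sub-seed, runtime and output hashes. Sessions are serialized both as HDF5
(group per unit, dataset per trial, phase markers as attributes, trial table
as a group) and as plain CSV (`trials.csv` + long-format `spikes.csv`).

## Problem sizes and numerical choices

The shipped tests and the reproduction script run at desk scale, chosen so
every statistical check retains its power: 40–60-unit stereotype pools with
200 bootstrap runs for decoding experiments; 200–400-unit populations for
null calibrations; 1000 trials per stimulus for observer recovery; 100 seeds
for the time-rescaling audit (≤2 failures tolerated at α=0.01, the binomial
expectation). Degenerate inputs are defined rather than fatal: constant
traces z-score to zero, all-zero COM weights and zero-variance correlations
are NaN and excluded, rank-deficient decoders take the minimum-norm
solution, and zero-variance marginals yield zero components with 0% EV.

## Known limitations

* The demixed decomposition is the marginalization form: no regularization
  and no interaction terms. It is validated on planted factors, not claimed
  numerically identical to regularized demixed-PCA implementations.
* The EV thresholds (6%/28%) and the 22.5° angle are data-set-derived
  conventions exposed as parameters, not universal constants.
* The speed-significance test is conservative by design (see above); its
  null rate is not 5% and should not be interpreted as a calibrated
  false-positive rate.
* Phasic populations are generated and characterized but no decoding claims
  are made for them beyond the stereotype level.
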