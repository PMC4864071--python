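# Methods

## DTW core

Exact dynamic programming over the full cost matrix restricted to a
Sakoe–Chiba band `|i − j| ≤ w`; cells outside the band are +inf sentinels.
Step pattern is the symmetric unweighted three-move set (→, ↑, ↗); local
cost is `|x_i − y_j|` by default with a squared option.  The returned
distance is the raw cumulative cost — within a fixed-length template bank
path-length normalization only rescales, so it is off by default (exposed as
`normalize=True`).  Backtracking breaks ties deterministically: diagonal
first, then the i-decrement, then the j-decrement.  Band feasibility
requires `|n − m| ≤ w`; infeasible inputs, empty sequences and non-finite
values raise.  The inner loop is numba-jitted when numba is importable; the
pure-Python implementation is the reference and is exercised directly in the
tests.  Correctness is anchored to an exhaustive enumeration oracle over all
monotone banded paths for sequences up to length 8.

## DTW spectrum

Templates are sines (optionally sawtooths) at `f_lo, f_lo+Δf, … , f_hi`,
phase 0 at the first sample, z-standardized.  Defaults: 8–13 Hz, Δf
0.1 Hz (0.5 Hz wherever speed matters more than grid density), 1 s of data
at 50 Hz, warping window 20 samples.  Both segment and template are
z-standardized before DTW so that frequency content, not amplitude, drives
the dissimilarity; `standardize=False` is available.  The matched DFT
spectrum is evaluated by direct projection of the mean-removed segment on
exactly the same grid (not an FFT on padded data), keeping the two spectra
bin-aligned for rank correlation and for the GLM layer.  Each spectrum is
reduced to its sample SD across the band; the SD is invariant to adding a
constant to all bins.

Numerical behaviour worth knowing: with the template phase fixed at 0, the
warp path cannot wrap at the segment boundaries, so segments whose phase is
far from 0 pay a frequency-dependent edge cost.  Recovery of a noiseless
sine's frequency is exact for phase-aligned segments (100% of bins, and
stays exact under 10 dB white noise); under uniformly random phase,
nearest-or-adjacent recovery drops to roughly 85–90%.  This is a documented
limitation of the single-phase bank, not noise sensitivity.

## Microstates

GFP is the population SD across channels per sample.  Peaks are strict
interior local maxima.  Clustering is a seeded k-means variant with the
polarity-invariant distance `1 − |spatial correlation|` (maps
average-referenced and unit-normalized before correlation); centroids are
polarity-aligned means, re-normalized; empty clusters reseed from the
worst-fit map; best of 10 restarts by total within-cluster dissimilarity,
100 iterations max with early stop.  Back-fitting labels every sample with
the argmax |correlation| map, ties to the lowest index.  k defaults to 12;
the recovery fixture plants k = 4 orthogonal maps.  Group-level maps pool
GFP-peak maps across subjects into one clustering (subsampled beyond 20 000
maps, seeded); the per-subject labeling that would precede pooling adds
nothing here and is omitted.  Trial measures: the maximal constant-label run
containing the trial sample gives `ms_length` (samples) and `mean_gfp`
(mean GFP over the run; `gfp_power=True` switches to mean GFP²).

## Avalanches

Channels are z-scored individually; an event is the onset sample of each
maximal excursion with `|z|` above threshold (two-sided by default;
`side` and per-sample marking flags exist).  Samples are partitioned into
bins of width 2; a cascade is a maximal run of occupied bins; its length is
counted in bins (event counts are carried alongside).  The threshold is the
candidate from {3.2, 3.5, 3.7} SD minimizing |cascade count − trial count|,
ties toward the larger threshold.  Per trial: the length of the cascade
containing the trial's bin, else the most recent cascade before it, else 0 —
this trial mapping replaces any literal down-sampling of cascades.

## Predictor

One-step prediction of a single channel from 41 lagged points (the
immediately preceding sample plus 40 more).  Architecture: one tanh hidden
layer the same size as the input, linear output, no regularization.
Training examples come only from each trial's 1 s pre-trial window (9
sliding targets per trial at 50 Hz); the channel is z-scored with statistics
of the training windows only.  Optimization is gradient descent on the batch
MSE in fixed partitions of 50 examples; defaults: learning rate 0.05, 200
epochs, seeded uniform init scaled by 1/√fan-in.  If the final training SSE
exceeds 0.5 × the SSE of the constant-mean predictor (a scale-free "fairly
strict" criterion), training restarts with the next seed, up to 10 times,
then raises.  Task models train on the first task block, rest models on the
second rest block (or the only one); SSE is reported for every trial of the
condition, so training-block trials are in-sample.  Horizon is fixed at
t+1, single channel.

## Statistics

Per-subject GLM: OLS of one measure on the other five (z-scored within
subject) plus intercept; rank-deficient designs raise.  Group inference: a
two-sided one-sample t-test of the per-subject betas against zero
(zero-variance-at-zero returns t = 0, p = 1; zero variance elsewhere raises
with the sign reported).  BH-FDR at α = 0.05 with the family = all 30
off-diagonal cells of one condition's matrix.  The permutation null shuffles
the *target's* trial order within each subject, refits and recomputes the
group t; `p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)`, so p ≥ 1/(n_perm+1).
n_perm defaults to 5000.  Pipeline repetitions (stochastic MLP/k-means
stages) average betas per subject before the group test; n_reps defaults to
20 but any list of repeated measure extractions is accepted.  The
double-gamma HRF uses gamma shapes 6 and 16 (unit scale, seconds),
undershoot ratio 1/6, 32 s kernel, peak-normalized, positive peak near 5 s.
For BOLD targets the same machinery runs with HRF-convolved, TR-resampled
trial-measure regressors; its permutation shuffles the target frames.

## Synthetic data

The generator emulates the study layout: 15 subjects, 5 alternating
task/rest blocks (task first) of 60 s at 50 Hz, 112 trials evenly spaced
within blocks with margins clearing the 1 s window plus MLP lags.  Signal
per channel is the sum of

* a microstate sequence: k = 4 orthonormal zero-mean maps, geometric dwell
  (mean 4 samples = 80 ms), oscillatory amplitude envelope;
* an alpha oscillation at 10 Hz whose channel loading fixes channel 0 as the
  alpha-rich measurement channel; amplitude 1.0 in task, 1.2 in rest, with
  lognormal waxing/waning (CV 0.4, ~4 s timescale) so trial-to-trial band
  power varies; phase follows a random walk with step SD 0.02 rad/sample in
  task and 0.7 in rest — the designed predictability contrast
  (phase-locked task alpha is learnable one step ahead; wandering rest alpha
  is not);
* 1/f-amplitude-shaped Gaussian background (SD 0.3, ×1.5 in rest);
* rare multi-channel transients (~0.37/s, matching the trial count over a
  recording) at 4–5.5 SD with staggered per-channel onsets over up to 10
  samples, so cascades span multiple bins.

Design notes from building it: pink noise is the *most* predictable
component one step ahead, so making rest merely noisier does not make it
less predictable — the phase-coherence contrast does; and transient
amplitude trades off against the SSE measure (very large spikes dominate
per-trial SSE), so transients sit just above the detection thresholds.
What the generator does **not** emulate: volume conduction/leadfields,
neural-mass dynamics, non-stationary artifacts, realistic microstate
syntax, or any coupling between the six measures beyond what the explicit
`coupling` knob plants.  Passing tests therefore show the *measures and
statistics behave as specified on controlled structure*, not that the
paper's empirical findings hold on real EEG.

Auxiliary generators: a microstate-only fixture (16 channels, 6000 samples,
SNR 3 at the envelope peak); alpha-burst pre-trial segments (unit sine at a
uniform 8–13 Hz frequency and random phase over pink noise at 10 dB) used
for the inverted-spectra property; independent standard-normal measure
tables (exchangeable null, optional planted linear couplings); and
BOLD-style network courses (beta-weighted HRF-convolved measure regressors
plus white noise; pure-noise networks on request) standing in for
data-driven network time courses.  Every generator is reproducible from its
seed.

## Problem sizes

The acceptance script runs, per seed: 200 oracle pairs (length ≤ 8); 11
noiseless + 100 noisy recovery trials; 200 burst segments; 10 microstate
seeds; 10 single-subject predictability seeds; 500 null replicates at
n_perm = 200 for calibration; 50 coupling seeds at n_perm = 99; and one
6-subject full-pipeline pass (0.5 Hz grid, n_perm = 200, single
repetition).  These sizes keep the whole run near 15 s on one CPU while
leaving every estimate's Monte-Carlo error well inside the margins of the
properties being checked; all defaults scale up through the public
configuration objects.

## Known limitations

* Single-phase template banks: edge-phase cost (above).
* `ava_length` on quiet recordings can be constant across a condition's
  trials; the GLM z-scoring maps such a column to zeros rather than raising,
  which silently removes it from that subject's fit.
* The permutation scheme (target trial order within subject) is one of
  several defensible choices (residual or subject-level schemes exist); it
  preserves predictor covariance exactly and is the one implemented.
* EDF or BrainVision input is out of scope; the interchange format is a
  plain matrix + JSON sidecar.
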