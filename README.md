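# dtwspec

Template-based spectral estimation of short EEG segments with dynamic time
warping, together with companion per-trial measures of neural dynamics and a
group-level statistical framework to cross-predict them between task and
rest states.

## The problem and the method

A discrete Fourier transform tells you how much a segment *correlates* with a
sinusoid at each frequency, but high power at a bin need not mean an actual
oscillation is present there.  The **DTW spectrum** asks the more direct
question: *how dissimilar is this segment from a sinusoid at frequency f,
once timing jitter is allowed for?*

For a segment `x` of n samples at rate `fs`, and unit-variance sine templates
`s_f` on a grid `f = f_lo, f_lo+Δf, …, f_hi` (default 8–13 Hz, the alpha
band), the spectrum is

    D(f) = DTW_w( z(x), s_f )

where `z(·)` is z-standardization and `DTW_w` is exact dynamic-programming
DTW with symmetric steps (→, ↑, ↗), absolute local cost `|x_i − s_j|`, and a
Sakoe–Chiba band `|i − j| ≤ w` (default w = 20 samples).  Warping absorbs
phase offsets, so one zero-phase template per frequency suffices.  `D(f)` is
minimal where the segment most resembles an oscillation — the DTW spectrum is
an *inverted* analogue of the power spectrum (strongly negative rank
correlation with a bin-aligned direct DFT).  Per trial both spectra are
condensed to their standard deviation across the band (`dtw_sd`, `dft_sd`).

Around this core the package computes, for the 1 s window preceding each
trial marker, four further measures of momentary brain state:

* `sse` — one-step prediction error of a single-hidden-layer MLP (41 lagged
  inputs, tanh hidden layer of the same size, batch gradient descent,
  separate models per subject and condition with held-out test blocks);
* `ms_length`, `mean_gfp` — length of, and mean global field power over, the
  EEG microstate in force at trial time (GFP peaks → polarity-invariant
  k-means with k = 12 → back-fitting);
* `ava_length` — length in 2-sample bins of the neuronal avalanche (run of
  consecutive bins with ≥ 1 suprathreshold point-process event) at or before
  the trial, with the z-threshold chosen from {3.2, 3.5, 3.7} SD so the
  cascade count matches the trial count (n = 112).

A statistics layer cross-predicts the six measures: per-subject OLS GLMs
(each measure regressed on the other five, z-scored, intercept included), a
one-sample group t-test on the betas, Benjamini–Hochberg FDR at α = 0.05
over each condition's 30-cell matrix, and a within-subject permutation test
(target trial order shuffled; p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1)).
BOLD-style network time courses can be targets too, with HRF-convolved
(double-gamma), TR-resampled trial measures as regressors.

Because no public dataset accompanies the method, a seeded synthetic
generator produces the full study layout — 15 subjects, 5 alternating
task/rest blocks at 50 Hz, 112 trials — with band-limited alpha
(phase-locked in task, wandering in rest), piecewise-constant topographic
states, 1/f background and rare multi-channel transients, plus ground truth
for every planted structure.

## Worked example

`python examples/dtw_spectrum_demo.py` sweeps the 8–13 Hz bank against a
noisy 10.5 Hz burst:

```
freq(Hz)  DTW-dissimilarity  DFT-power
    8.0              26.95        4.6
    ...
   10.5              13.80      627.3
   11.0              24.72      247.6
    ...
   13.0              30.16       16.1

DTW minimum at 10.5 Hz (true 10.5), DFT maximum at 10.5 Hz
DTW-spectrum SD 4.41, DFT-spectrum SD 193.9 (the two per-trial scalars used downstream)
median Spearman(DTW, DFT) over 100 alpha bursts: -0.65 (strongly negative: the spectra are mutually inverted)
```

The dissimilarity dips exactly where the power peaks: both spectra locate
the oscillation, and their inverted relationship is the method's calling
card.  The other scripts in `examples/` demonstrate microstate recovery,
avalanche detection, task-vs-rest predictability (e.g. mean SSE 1.32 in task
vs 6.87 in rest for one generated subject), and the group GLM layer
recovering a planted `sse ← dtw_sd` coupling at FDR p ≈ 3e-11 while 28 of 30
cells stay null.

A `dtwspec` CLI wraps the same functions for file-based use:
`dtwspec simulate | spectrum | microstates | avalanches | predict | compare | dtw`.

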