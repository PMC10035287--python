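# Methods

## The transform

`wavedisc` uses the maximal overlap discrete wavelet transform (MODWT)
rather than the decimated DWT because classification features should not
depend on where a trial's time axis happens to start: the MODWT produces
`N` coefficients at every level, is equivariant under circular shifts, and
partitions the input energy exactly across detail levels and the final
smooth (both properties are asserted by the test suite, the first to 1e-10
against a direct-convolution oracle, the second to a relative 1e-8).

Filters are the orthonormal pairs `haar, d4, d6, d8, la6, c6` — Haar,
Daubechies extremal-phase of lengths 4–8, the least-asymmetric (symlet)
filter of length 6, and the Coiflet of length 6. Coefficients are taken
from the PyWavelets tables; the package fixes the convention itself:
`sum(g) = +√2` and `h_l = (−1)^l g_{L−1−l}`, with the MODWT pair
`(h̃, g̃) = (h, g)/√2` — division, not multiplication, since only division
by `2^{j/2}` yields an energy-preserving non-decimated transform. The
transform is computed by the pyramid algorithm (per-level filtering of the
previous smooth with the base filter upsampled by `2^{j−1}`), `O(N·J·L)`;
the explicit level-`j` filter construction exists only as a test oracle.

Level depth is bounded by the largest `J` with `J < log2(N/(L−1) + 1)`,
i.e. the deepest level whose equivalent filter width
`L_j = (2^j − 1)(L − 1) + 1` still fits inside the series. Requesting a
deeper `J` warns instead of failing — such configurations are occasionally
wanted for exploration — but levels past the bound contribute no
non-boundary coefficients and therefore no usable features.

## Features

Each channel is standardized with the population-σ convention before
decomposition; any consistent convention would do, since every downstream
feature is invariant to per-channel affine gain (asserted as a property
test). The candidate set is

- wavelet variance per channel and level: the *uncentered* mean square of
  the non-boundary coefficients, `(1/M_j) Σ W̃²`, the natural band-power
  estimate (detail coefficients of a standardized series have mean ≈ 0, so
  centering would change nothing material, and the uncentered form is the
  estimator's definition);
- wavelet correlation per channel pair and level: the Pearson correlation
  of the two channels' non-boundary coefficients, which is bounded in
  [−1, 1] by construction. Correlations are computed within a level only;
  the catalog count `J·(P + P(P−1)/2)` — 22,176 at `P = 63, J = 11` —
  confirms that reading.

The smooth coefficients `Ṽ_J` are not treated as an extra feature level:
after a high-pass acquisition chain the lowest band carries little
class-relevant structure, and the J-level catalog is the configuration the
count law above describes. Deterministic catalog order (variances
channel-major, then correlations level-major with pairs in channel order)
makes selection reproducible and tie-breaking well defined.

## Selection

Greedy forward selection by the Lawley-Hotelling trace
`V = (n − g)·tr(W⁻¹B)`: at each step every unselected candidate is
evaluated as part of the augmented set and the argmax added, until
`n_select` features are chosen. Numerical choices:

- `W` is never inverted explicitly; `tr(W⁻¹B)` is computed through a solve.
- A candidate whose augmented `W` has reciprocal condition number below
  1e-12 is skipped at that step and recorded — with tens of thousands of
  candidates and a few hundred trials, exact collinearity is routine.
- Ties within relative 1e-9 go to the lower catalog index, so permuting
  feature columns changes nothing except the resolution of exact ties.
- There is no improvement-threshold stopping rule; steps whose V gain is
  below 1e-6 are logged but kept, since the contract is "select exactly
  `n_select`".

The per-step argmax is verified exactly against an exhaustive brute-force
oracle on small instances (p ≤ 6).

## Classification and evaluation

Linear (pooled covariance) and quadratic (per-group covariance) Gaussian
discriminants with equal class priors (the intended datasets are balanced
by design). Covariances are regularized as `(1−λ)S + λ·diag(S)`; the
default `λ = 1e-4` is a numerical floor that keeps the fit well-posed when
the number of selected features approaches the number of trials, not a
tuned hyperparameter; `λ = 0` is allowed and used in closed-form tests.

Evaluation is leave-one-out cross-validation tallied into a confusion
matrix against a declared positive class (default: lexicographically first
label). Sensitivity `TP/(TP+FN)`, specificity `TN/(FP+TN)`, precision
`TP/(TP+FP)`, F-measure; a metric whose denominator is zero is reported as
undefined (`None`), never as 0.

**Selection placement.** By default features are selected once on the full
dataset and only the classifier is cross-validated. With a large candidate
pool this estimate is optimistically biased: on a no-effect dataset of 100
trials and ~170 candidate correlations, the default placement measures
LOOCV accuracy around 0.7 purely from selection leakage. The
`selection_within_folds` option re-runs the stepwise selection inside every
fold, which removes the bias (the same null dataset then measures ~0.5);
the chance-calibration checks in the test suite and the acceptance script
use this mode. For real effect sizes well above the detection threshold
both modes agree.

## Synthetic data

The generator emulates only the statistical structure the pipeline
exploits: white Gaussian channels plus (a) shared band-limited latent
sources inducing class-dependent cross-channel correlation and (b)
class-dependent band-limited power on single channels. Latent sources are
4th-order Butterworth band-passed white noise, zero-phase filtered so the
coupling appears without lag, drawn independently per trial; the coupling
gain is solved from the target in-band correlation `c` via
`gain² = c/(1−c) · σ²·bw/(fs/2)`, and level bookkeeping uses the octave map
`level j ≈ [fs/2^{j+1}, fs/2^j]` Hz.

The study-scale default profile is 200 trials per class, 63 channels, 5500
samples at 1000 Hz; simulation-based tests use a small profile (8 channels,
512 samples, 1000 Hz) so the suite runs in well under a minute of
simulation per test. The generator does **not** emulate 1/f spectra,
volume conduction, artifacts or non-stationarity, so a passing recovery
test demonstrates that the pipeline detects the kind of band-limited
coupling it targets at realistic effect sizes — not that it would reach any
particular accuracy on real EEG.

## Problem sizes used in the shipped checks

- Parameter recovery: one pair coupled at 0.9 vs 0.0 (16–30 Hz), 40 trials
  per class, 8 channels, correlations only, 5 variables, linear
  discriminant — LOOCV accuracy ≥ 0.95 and the first selected feature is
  the coupled pair at a level overlapping the band.
- Chance calibration: no-effect dataset, 100 trials, 8 channels, 3
  variables selected within folds — accuracy inside the 99% binomial band
  around 0.5.
- Oracle equivalences: MODWT vs direct convolution at N ≤ 64, J ≤ 3 for all
  six filters; greedy selection vs exhaustive oracle on 20 random instances
  with p ≤ 6; Lawley-Hotelling against term-by-term brute force.

## Known limitations

- The greedy forward search is not optimal; a variance+correlation pool can
  select a set that classifies worse than correlations alone, and no remedy
  (floating/backward steps) is attempted.
- Equal priors and the two-class confusion-matrix summary assume balanced
  designs; `g > 2` groups are supported by the statistic and classifiers
  but the metrics are binary.
- EDF/real-EEG ingestion is an extension point: the reader consumes the
  manifest + CSV layout only.
- The electrode-category map (e.g. motor vs non-motor cortex) is
  user-supplied input; no montage is hard-coded.
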