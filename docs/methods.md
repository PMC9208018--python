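# Methods

## The measures

### Ordinal symbolization

A window of `n` samples taken `tau` apart, `(x_t, x_{t+tau}, ...,
x_{t+(n-1)tau})`, is reduced to its ordinal pattern: the permutation of
amplitude ranks, where the highest amplitude receives rank 1 and the lowest
rank `n`. There are `n!` possible patterns; each is encoded as the
lexicographic index of its rank vector. Two conventions are worth calling
out because they silently differ between permutation-entropy codebases:

* **Rank direction.** We rank the *largest* sample first. Libraries built
  on `argsort` usually rank the smallest first. Entropy values are
  unaffected (the map between conventions is a bijection of patterns), but
  raw symbol indices are not comparable across conventions.
* **Ties.** Ties are broken by temporal order: the earlier sample gets the
  better (lower) rank. Continuous-valued signals have ties with probability
  zero, but quantized or synthetic inputs need a deterministic rule.

The embedding dimension must satisfy `n! <= T/10` for an epoch of length
`T` so that the pattern histogram is adequately sampled. This is enforced
where the configuration meets the epoch geometry (`PipelineConfig`), not in
`symbolize` itself, so that short diagnostic sequences can still be
symbolized in isolation.

### Permutation entropy (PE)

PE is the Shannon entropy (natural log) of the pattern distribution,
normalized by `log(n!)`, hence in `[0, 1]`: 0 for a strictly monotone
signal, 1 for a uniform pattern distribution. PE is invariant under
strictly increasing amplitude transforms.

### Inverted joint permutation entropy (JPE_inv)

For two simultaneously recorded channels, the joint distribution of
time-aligned symbol pairs is an `n! x n!` matrix. Volume conduction /
source leakage produces instantaneous mixing, which loads mass onto pairs
of *identical* patterns and — when signals superpose with opposite
polarity — *mirrored* patterns (every rank complemented, `r -> n+1-r`,
i.e. the pattern of the amplitude-inverted signal). Those `2*n!` cells
(identical plus mirrored; the sets are disjoint for `n >= 2` because no
pattern of distinct ranks equals its own complement) are excluded. The
retained cells are renormalized to a probability distribution, their
Shannon entropy is divided by `log(n!*n! - 2*n!)` — the log-count of
retained bins, computed from the actual mask rather than hard-coded — and
the result is inverted:

    JPE_inv = 1 - H_retained / log(#retained bins)

so that higher values mean stronger coupling. Time-reversed patterns are
*not* treated as mirrored.

Numerical/degenerate choices:

* If the retained mass is below `1e-9` (e.g. `y = x` or `y = -x`), all
  dependence is attributable to zero-lag mixing and `JPE_inv := 0` with a
  logged warning. Scoring such pairs as maximally coupled would defeat the
  correction.
* Renormalizing the retained mass keeps JPE a true entropy of a
  distribution, which guarantees `JPE_inv in [0, 1]`. A
  `renormalize=False` switch computes the entropy of the un-renormalized
  retained mass instead, for sensitivity analysis.
* An `corrected=False` variant disables the exclusion entirely (normalizer
  `log(n!*n!)`); it exists to demonstrate what the correction absorbs.
* Retained-cell sums are accumulated in sorted order, which makes
  `jpe_inv(x, y) == jpe_inv(y, x)` bit-exact (the excluded set is
  transpose-symmetric, so the retained multiset is identical either way).

The connectivity matrix over a multichannel epoch symbolizes each channel
once and reuses the symbol sequences across all pairs; the per-ROI profile
is the mean of each row excluding the diagonal.

## Spectral processing

Epochs are consecutive, non-overlapping windows from sample 0 (default 20
epochs of 4096 samples at 1250 Hz, i.e. 3.2768 s each). Band-pass
filtering is a per-epoch brick-wall FFT filter: forward rFFT, bins outside
`[f_low, f_high)` zeroed (DC always zeroed), inverse transform. No taper
or padding is used; edge ringing and the spectral leakage of off-bin
components are accepted properties of this filter. Half-open band edges
make the canonical bands (theta 4–8, alpha 8–13, beta 13–30, broadband
0.5–45 Hz) a partition: 8 Hz belongs to alpha.

Relative band power is the ratio of summed squared rFFT magnitudes over the
band's bins to the sum over the 0.5–45 Hz reference band (the pipeline's
own broadband definition; the reference is configurable).

The band-adapted time delay rule is `tau = round(fs / (3 * f_high))` with
a floor of 1 (e.g. 9 for broadband, 52 for theta at 1250 Hz), rounded
half-up; with `tau_rule: fixed` (default) `tau = 1` everywhere.

## Synthetic cohort generator

The generator exists so every stage is testable without clinical
recordings. Each channel of a subject is a weighted sum of unit-variance
components:

| parameter | default | meaning |
| --- | --- | --- |
| `osc_freq` / `osc_bandwidth` | 10 Hz / 1.5 Hz | dominant AR(2) resonance (pole radius `exp(-pi*bw/fs)`, angle `2*pi*f0/fs`) |
| `theta_fraction` | 0.15 | weight of a second AR(2) resonance inside 4–8 Hz |
| `theta_freq` / `theta_bandwidth` | 6 Hz (7 Hz in the group templates) / 3 Hz (2 Hz in templates) | center/width of that theta component |
| `noise_sd` | 1.0 | amplitude of 1/f background (inverse-FFT-shaped Gaussian noise) |
| `coupling` (kappa) | 0.4 | blend weight of a shared lagged drive |
| `coupling_lag` | 10 samples (8 ms) | channel `i` receives the drive delayed by `i*lag`, so every pair is coupled at a non-zero lag and survives the exclusion rule |
| `leakage` (lambda) | 0.0 | zero-lag nearest-neighbour mixing `x_i <- (1-lambda)x_i + lambda*mean(neighbours)` |

The shared drive uses the same oscillatory recipe as the private signal
(no 1/f term): a smooth drive stays autocorrelated across the coupling
lag, so its ordinal footprint survives the lag and registers as genuine
lagged coupling, whereas broadband noise would decorrelate within a few
samples.

The two-group templates emulate an early-Alzheimer contrast with 18
subjects per group and 80 ROIs: the control-like template (`scd_like`)
has a 10 Hz peak, `theta_fraction = 0.15` and `coupling = 0.45`; the
patient-like template (`mci_like`) has its peak slowed to 9 Hz,
`theta_fraction = 0.35` and `coupling = 0.25`. Both templates place the
pathological theta component at 7 Hz with a 2 Hz bandwidth: the theta
increase of early AD largely reflects the dominant rhythm slowing into
*upper* theta, and upper-theta content is also what raises theta-band
ordinal complexity (more extrema per window), so the patient-like group
shows higher theta PE as well as higher relative theta power, while its
weaker lagged coupling (and higher local entropy) lowers theta JPE_inv.
Per-subject parameters jitter `coupling` and `theta_fraction` by ±10%
(uniform, clipped) to create between-subject variance; per-subject seeds
derive from the master seed.

What the generator does **not** emulate: biophysical neural-mass dynamics,
beamformer field spread with realistic geometry (leakage is
nearest-neighbour only), artifacts, non-stationarity, or inter-individual
spectral diversity beyond the two jittered parameters. Passing tests
therefore show that the measures and statistics behave as designed on
signals with known structure — not that the clinical effect sizes of real
MEG cohorts are reproduced.

## Statistics

* **Permutation test.** Per-ROI statistic `|mean_A - mean_B|` (two-sided;
  the simplest statistic consistent with comparing group means). Labels are
  randomly repartitioned preserving group sizes (default 10,000 draws,
  shared across ROIs), and `p = (#{T_perm >= T_obs} + 1)/(n_perm + 1)`; the
  +1 correction guarantees a valid Monte-Carlo test with `p > 0`
  (`plus_one=False` recovers the raw proportion).
* **FDR.** Benjamini–Hochberg step-up (independence variant), applied per
  band across ROIs; significance at `q < 0.05`.
* **Classification.** Unregularized maximum-likelihood logistic regression
  of diagnosis on one global (ROI-averaged) feature; in-sample ROC over
  fitted probabilities; AUC by trapezoidal integration (equal to the
  midrank Mann–Whitney `U/(n1*n2)` of the oriented score); 95% CI by the
  DeLong structural-components method, which is deterministic. Under
  perfect separation the ML fit diverges; the report is flagged and the
  score falls back to the feature oriented by the direction of separation.
  In-sample AUC on a small cohort is optimistic by construction.
* **ANCOVA.** `y ~ 1 + covariate + group`, F-test of the group term with
  `(1, N-3)` df via full-vs-reduced residual sums of squares, partial
  `eta^2 = SS_group / (SS_group + SS_residual)`.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` exercise the full default
cohort (18 vs 18 subjects, 80 ROIs, 20 x 4096-sample epochs) for the
end-to-end group-contrast check, and scaled-down generator settings
(8 ROIs, 2 x 2048-sample epochs, 20 seeds) for the leakage and
parameter-recovery grids — sizes at which the grid means are stable across
seed batches. Null calibration uses 50 cohorts of 36 subjects with 80 ROIs
and one 1024-sample epoch, `n_perm = 2000`. The coupling grid is evaluated
on theta-band-filtered epochs, the band in which the pipeline's group
contrast is read out.

## Known limitations

* Brick-wall filtering spreads off-bin tone energy (a 6 Hz tone at
  fs = 1250, T = 4096 retains ~98% of its energy in theta, not 100%) and
  rings at epoch edges — accepted as part of the procedure.
* JPE_inv mixes local complexity and interregional coupling by design; it
  is not a pure connectivity measure.
* The exclusion rule is conservative: genuinely instantaneous *neural*
  coupling is discarded along with volume conduction.
* No artifact handling and no cross-validation of the classifier; both are
  out of scope.
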