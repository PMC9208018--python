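# netpe — network-level permutation entropy for multichannel recordings

`netpe` quantifies local signal complexity and interregional coupling in
multichannel neurophysiological time series (source-reconstructed MEG/EEG
region-of-interest signals) with ordinal-pattern symbolic dynamics, and
compares two diagnostic groups with nonparametric statistics. It is aimed
at researchers evaluating entropy-based biomarkers — e.g. for predementia
Alzheimer's disease, where oscillatory slowing and altered network
coupling are candidate markers.

## The measures

A window of *n* samples spaced τ apart is reduced to its **ordinal
pattern** π: the permutation of amplitude ranks (highest amplitude →
rank 1; ties broken by temporal order). With pattern probabilities p(π),

* **Permutation entropy** PE = H/log(n!) with H = −Σ p(π) log p(π) — the
  normalized Shannon entropy of the pattern distribution of one channel;
  0 for a monotone signal, 1 for equiprobable patterns.
* **Inverted joint permutation entropy** of two channels is computed from
  the n!×n! joint distribution of simultaneous symbol pairs, after
  excluding the 2·n! cells of identical and mirrored (rank-complemented)
  pairs — the signature of zero-lag volume conduction / field spread:

      JPE_inv = 1 − H(retained pairs) / log(n!·n! − 2·n!)

  Higher JPE_inv means stronger (non-instantaneous) coupling; an identical
  or amplitude-inverted channel pair scores exactly 0.

Around these sit: FFT brick-wall band filtering in canonical bands (theta
4–8, alpha 8–13, beta 13–30, broadband 0.5–45 Hz), relative band power,
epoch-wise estimation with per-subject averaging, group comparison by
permutation test (|Δmean|, 10,000 repartitions) with Benjamini–Hochberg
FDR, single-feature logistic ROC/AUC with DeLong CIs, and an ANCOVA that
controls the JPE_inv group effect for relative theta power. A synthetic
two-group cohort generator with known spectral content, lagged coupling
and zero-lag leakage makes the whole pipeline testable end to end. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from netpe import (OrdinalConfig, permutation_entropy, jpe_inv,
                   generate_subject, SubjectSpec, connectivity_matrix,
                   bandpass, DEFAULT_BANDS)

cfg = OrdinalConfig(n=4, tau=1)
rng = np.random.default_rng(0)
x = rng.standard_normal(4096)

print(permutation_entropy(np.arange(100.0), cfg))  # 0.0    (monotone ramp)
print(round(permutation_entropy(x, cfg), 3))       # 0.999  (iid noise ~ 1)
print(jpe_inv(x, 0.6 * x, cfg))                    # 0.0    (pure zero-lag copy)

# a synthetic subject: 8 ROIs with lagged common drive (coupling = 0.4)
rec = generate_subject(SubjectSpec(n_rois=8, n_epochs=2, epoch_len=2048, seed=1))
theta = bandpass(rec.data[:, 0, :], rec.fs, DEFAULT_BANDS[0])
conn = connectivity_matrix(theta, cfg, band="theta")
print(round(conn.matrix[0, 1], 3))                 # 0.464  (coupled pair, theta band)
print(round(float(conn.roi_profile.mean()), 3))    # 0.483  (mean ROI coupling profile)
```

The printed values mean: a strictly monotone signal has zero ordinal
complexity; long iid noise approaches the PE upper bound 1; a scaled copy
of a channel — the volume-conduction worst case — scores zero coupling;
and theta-band channels sharing a lagged drive score clearly above the
independent-noise floor (~0).

The same pipeline is available from a shell:

```bash
netpe all --seed 1 --out results/        # simulate default cohort + full analysis
netpe simulate --seed 1 --out cohort/    # or stage by stage
netpe compute --manifest cohort/manifest.yaml --out feats/
netpe compare --features feats/ --out results/
netpe classify --features feats/ --out results/
```

`results/summary.txt` reports per-band significant-ROI counts, the AUCs of
the three global theta features, and the ANCOVA; all outputs embed the
resolved configuration and seed.

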