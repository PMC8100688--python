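# Methods

This note records the generative model behind the synthetic studies, the
analysis procedure, every default parameter and why it was chosen, the
numerical decisions that are not obvious from the code, and the known
limitations.

## Generative model

A study consists of two groups ("A", "B") of subjects on a shared 3-D
voxel grid. Each subject's data matrix is `(V voxels, T volumes)`:

```
X = sigma * N + sum_c  m_c  s_c^T
```

* `s_c` — unit-variance, band-limited (0.01–0.08 Hz at TR 2.0 s) Gaussian
  timecourses, one per component, independent across components and
  subjects. Band-limiting is achieved by Butterworth-filtering white noise
  and restandardising.
* `m_c` — binary spatial supports, pairwise disjoint, drawn from one
  seeded permutation of the grid. The first `n_components − 1` supports
  are identical for every subject of both groups; the last support is
  drawn per group. The planted "common activated mask" is the union of the
  shared supports; the group masks add the group-unique support.
* `N` — i.i.d. standard normal scanner noise, scaled by `noise_sigma`.

Voxel ordering is canonical everywhere: linear index
`x + nx * (y + ny * z)` (x fastest), which equals Fortran raveling of the
volume. NIfTI files store volumes accordingly.

### Planted connectivity differences

A planted edge `(a, b, delta_r)` changes the Pearson correlation of voxels
`a` and `b` by exactly `delta_r` in group B only. Both endpoints must lie
in shared supports of *different* components (baseline correlation zero)
and a voxel may anchor at most one edge. The injection replaces a fraction
`gamma^2` of each endpoint's private noise with a shared latent `e`:

```
noise_a  ->  sqrt(1 - gamma^2) * n_a  +  gamma * e
gamma^2  =  |delta_r| * (1 + sigma^2) / sigma^2
```

with the sign of `delta_r` applied to `e` at endpoint `b`. This is
*variance-preserving*: every voxel variance and every non-planted
correlation is untouched on the raw data, so false-positive accounting
downstream is exact. The construction bounds the plantable effect:
`|delta_r| <= sigma^2 / (1 + sigma^2)` (0.5 at the default
`noise_sigma = 1`); the generator rejects edges beyond the bound.

The latent `e` is band-limited like the component sources, not white: a
neural connectivity effect lives in the BOLD band and must survive the
band-pass stage. (A white latent loses ~72 % of its covariance to the
0.01–0.08 Hz filter at TR 2.0 s, silently attenuating a raw `delta_r` of
0.5 to ~0.22 post-filter.) One honest side effect: after filtering, a
planted voxel carries slightly more in-band noise power than its
neighbours, so its edges to same-component voxels acquire small genuine
group differences. The planted edges remain the largest effects by a wide
margin; analyses that assert exact significant sets should use raw
(unfiltered) data, as the calibration tests do.

### What the generator does and does not emulate

Emulated: band-limited spontaneous fluctuations, sparse spatial
organisation, additive scanner noise, group-level activation overlap with
a group-unique component, exactly calibrated connectivity differences,
initial-volume transients (volumes to be dropped are generated like all
others). Not emulated: hemodynamic response convolution, spatial
autocorrelation / smoothness, head motion, physiological confounds,
registration error, field inhomogeneity, non-Gaussian noise. Absolute
voxel counts (mask sizes, region tables) therefore characterise the
synthetic design, not any real cohort.

## Analysis procedure and defaults

| Stage | Choice | Default | Rationale |
|---|---|---|---|
| Volume drop | first `n_drop` volumes | 10 of 160 | magnetisation-equilibration convention |
| Detrend | linear, least squares | — | removes scanner drift |
| Nuisance | global-mean regression (+ intercept) | `global_mean` | standard minimal confound model |
| Band-pass | Butterworth order 4, zero-phase (`sosfiltfilt`) | 0.01–0.08 Hz | resting-state BOLD band |
| Order | MDL on temporal covariance eigenvalues | per subject, harmonised by max | see below |
| ICA | FastICA, symmetric, logcosh, unit-variance whitening | tol 1e-5, max 1000 iter | standard spatial ICA; voxels are samples |
| Stability | ICASSO: cluster 20 runs, keep centrotypes | `n_runs = 20` | guards against FastICA local optima |
| Activation | \|z\| ≥ 2 in ≥ 1 component map | z = 2.0 | component maps are z-scored over voxels |
| Group mask | intersection across subjects | `min_subject_fraction = 1.0` | strict "activated in every subject" |
| Region filter | strict count > 10 AND ratio > 0.01 | — | excludes incidental overlaps |
| FC | Pearson over unordered voxel pairs | lexicographic edge order | constant series get r = 0, logged |
| Edge test | pooled-variance two-sample t | `welch`, `fisher_z` optional | BH step-up at q ≤ 0.05 (`fdr_by` optional) |
| SVM | linear, C = 1, features standardised | 100 stratified splits, test 0.2 | sensitivity = recall of group "B" |

`noise_sigma = 1.0` puts per-voxel signal and noise power on an equal
footing and is the smallest noise level at which a `delta_r` of 0.5 is
plantable.

## Numerical decisions

**MDL formulation.** Eigenvalues of the `T × T` temporal covariance
(voxels as the `V` samples), Wax–Kailath criterion
`-V * (p - k) * log(geometric/arithmetic tail mean) + 0.5 * k * (2p - k + 1) * log V`,
minimised over `k`. Two necessary adjustments:

1. *Rank truncation.* Detrending and centring leave exact-zero
   eigenvalues; including them collapses the geometric tail mean and drags
   the minimiser to `T − 2`. The spectrum is truncated to its numerical
   rank (`lambda > lambda_max * 1e-9`) first.
2. *Pre-band-pass estimation.* The band-pass filter colours the noise
   floor (a smoothly decaying stop-band tail), violating MDL's white-noise
   assumption — measured effect: order 94 instead of 8 on filtered data.
   The pipeline estimates order after drop/detrend/nuisance but **before**
   filtering.

**Order harmonisation.** Per-subject MDL estimates at the default SNR
spread over {6, 7, 8} when 8 components are present; a single subject
under-calling an order can empty the strict all-subject mask intersection.
The pipeline default (`order = "mdl_max"`) fits every subject with the
maximum of the per-subject estimates; `"mdl"` keeps per-subject orders and
an integer fixes the order outright. Per-subject estimates are always
recorded in `preproc/orders.json`.

**ICASSO details.** Child run seeds derive from one `SeedSequence`;
pooled maps are clustered by average linkage on `1 − |corr|`; each
cluster's centrotype (member with maximal total in-cluster similarity) is
kept; the stability index is mean within-cluster minus mean
between-cluster absolute correlation. Maps are z-scored over voxels and
sign-oriented to non-negative skewness, which makes the |z| ≥ 2 activation
rule well defined.

**Determinism.** All randomness flows from explicit seeds through
`numpy.random.SeedSequence` streams; FastICA and scikit-learn splitters
receive derived integer seeds (< 2^31). A pipeline run writes a SHA-256
manifest of every artifact and reruns reproduce it bit for bit.

## Classification protocols and known biases

* **Selection leakage.** The `paper` protocol selects the DFC edge set on
  *all* subjects and reuses it in every split, so test subjects influence
  feature selection. Under the global null this inflates accuracy far
  above chance (measured: 0.74 vs 0.43 with nested selection on identical
  data). The `nested` protocol recomputes selection inside each training
  split and is the honest estimate; the package implements both precisely
  so the bias can be demonstrated.
* **Anti-learning.** With ~16 training subjects and hundreds of noise
  features, a linear SVM can score systematically *below* 0.5 on held-out
  data (sample-mean cancellation between the training and test sets).
  Null-data checks in this package therefore assert "no above-chance
  accuracy" rather than "accuracy ≈ 0.5".

## Limitations

* MDL needs `V >> T`; on very small grids (hundreds of voxels) it
  under-estimates the order, so toy pipeline runs should fix `order`
  explicitly.
* The strict all-subject intersection is brittle as group size grows;
  `min_subject_fraction < 1` is the escape hatch.
* The toy atlas partitions the grid into contiguous blocks of the linear
  order; it exercises the region-report logic but has no anatomical
  meaning. Real parcellations can be loaded from NIfTI + TSV via
  `Atlas.from_files`.
* Edge-wise t tests treat correlations as plain responses by default;
  `fisher_z = True` is available and preferable near |r| ≈ 1.
* Planted-edge calibration is exact on raw data and approximate after
  band-passing (see above).
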