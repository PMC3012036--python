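# Methods

## The problem

Two-dimensional gel electrophoresis (2-DE) quantifies a proteome as
stained spot volumes on one gel per biological sample. After image
analysis the data form a spots × gels matrix of normalized volumes in
which a substantial fraction of cells — commonly 20–30% — is missing,
because spots present on the reference gel are not detected or matched
on every other gel. Missingness is not uniform: low-abundance spots
lose cells more often. Downstream, a two-condition experiment asks
which spots differ between groups, which requires (1) completing the
matrix, (2) testing each spot, and (3) controlling the multiple-testing
error. This package implements all three steps plus the Monte-Carlo
machinery to compare the choices at each step on data with known truth.

## Data model and pre-processing

A `SpotMatrix` holds non-negative volumes with `NaN` for missing cells
and a two-group gel design (each group ≥ 2 gels). Zeros are *not*
missing by default — zero-substitution by image software is one of the
practices this analysis replaces — but `zero_as_missing=True` is
available when a source file uses that convention.

*Mean normalization* divides every cell by its gel's total observed
volume, so each gel's observed volumes sum to 1. The divisor uses
observed cells only, since missing cells contribute no volume; the
operation is idempotent and preserves the missingness pattern.

*Majority-present filtering* keeps spots observed in a strict majority
of gels within **each** group (configurable to a whole-panel rule).
The per-group form is the default because imputation and testing both
operate within groups; a spot with nearly all of one group missing
would be reconstructed almost entirely from model assumptions.

*Quartile completeness* bins spots by the empirical 25/50/75
percentiles of mean observed intensity (boundary ties to the lower
quartile) and counts fully observed spots per bin — the standard
diagnostic for intensity-dependent missingness. The per-quartile
counts sum to the number of spots exactly when the matrix is complete.

## Synthetic data: the study conditions

No public 2-DE matrices with the needed two-group structure exist for
this design, so benchmarks run on a generator that emulates the
relevant statistics on the log scale:

    log x[i,j] = log_mean + s_i + g_j + delta·1[i DE, j in B] + e_ij

| parameter | default | meaning |
|---|---|---|
| `n_spots` | 70 | matched spots (a small real study) |
| `n_per_group` | 6 | gels per condition |
| `de_fraction` | 10/70 | truly differential spots |
| `effect_size` (delta) | 1.5 | log-scale shift in group B (≈ 4.5-fold) |
| `log_mean` | 0.0 | arbitrary scale; all statistics are scale-free |
| `log_sd` (s_i) | 1.0 | spot-to-spot abundance spread |
| `gel_effect_sd` (g_j) | 0.2 | residual per-gel loading/staining scale |
| `spot_noise_sd` (e_ij) | 0.2 | within-spot biological + technical noise |

Volumes are strictly positive and right-skewed (log-normal), matching
real spot-volume distributions.

**Why the gel effects survive.** Real matrices are normalized upstream
over *all* detected spots of a gel, of which the analyzed matched
subset is a small part, so residual gel-to-gel scale differences
remain in the analysis matrix. The generator therefore emits values in
"already-normalized" units with the gel effects retained
(`normalize=True` re-applies in-matrix normalization, which removes a
per-gel multiplicative factor exactly — and with it the structure that
distinguishes the array-covariance imputers from row averaging). A
per-gel factor changes column *scale*, not between-column Pearson
correlation; it is precisely the structure that regression on other
gels can model and equal-weight row averaging cannot.

Two masking operators create benchmark inputs: uniform masking of an
exact cell count (MCAR) and intensity-dependent masking with per-spot
probability ∝ logistic(−steepness · z(mean intensity)), rescaled to a
target overall fraction (steepness 0 reduces to Bernoulli MCAR). Both
redraw any mask that would leave a spot with fewer than two observed
cells in either group — below that, row averaging and the two-sample
tests are undefined; the weaker "≥ 1 observed anywhere" rule is
available via `min_per_group=1`. The masked cells and their true
values are recorded, so restoring them reproduces the source matrix
exactly. Replicate r of an experiment uses seed `base_seed + r`, and
within a replicate every method receives the identical masked matrix
(paired design — method contrasts are not diluted by mask noise).

What the generator does *not* emulate: spatial gel structure
(isoelectric point / molecular weight coordinates), spot-matching
errors that swap identities rather than delete values, heavy-tailed
outlier gels, and correlated blocks of co-regulated proteins. Passing
benchmarks therefore show that a method exploits abundance structure,
gel-scale structure and intensity-dependent missingness correctly, not
that it is robust to every artifact of real gels.

## Imputation methods

- **RowAve** — missing cell ← mean of the spot's observed cells. The
  baseline; maximally shrinks within-spot variance.
- **KNN(k)** — Euclidean distance over mutually observed gels, rescaled
  by √(n_gels/n_shared) so overlaps of different sizes are comparable;
  inverse-distance weighting with a zero-distance short-circuit (a
  perfect twin's value is taken outright); Pearson distance and uniform
  weights are options. Cells with no usable neighbor fall back to the
  row average (logged).
- **LSM.LS.G / LSM.LS.A** — for each missing cell, single regressions
  on the 10 most correlated spots (G) or gels (A), combined with
  weights w = (r²/(1−r²+ε))², ε = 1e-6. Neighbors with degenerate
  variance are skipped; the array variant is exactly the gene variant
  on the transposed matrix.
- **LSM.EM.G / LSM.EM.A** — EM under a Gaussian model with covariance
  across spots (G) or gels (A), initialized from the corresponding LS
  estimates. The E-step replaces missing cells by conditional
  expectations **and accumulates the conditional covariance of the
  missing block**; the M-step re-estimates mean and covariance from
  completed records plus those corrections. Without the correction the
  iteration is regression imputation, which progressively
  underestimates residual variance and over-extrapolates — measurably
  worse than row averaging on weakly structured data. Covariance is
  ridge-regularized (ε·I). Convergence: maximum change of an imputed
  cell relative to its magnitude, floored at the observed-data SD (a
  pure relative criterion stalls on cells imputed near zero);
  tolerance 1e-4, at most 100 iterations, with a flag set when the
  tolerance is not met (estimates plateau well before it).
- **LSM.LS.C / LSM.LS.Ad** — convex combinations p·gene + (1−p)·array.
  LS.C fits one global p by least squares on a seeded 5% hold-out of
  observed cells (p = 0.5 with a warning when the hold-out is
  infeasible); LS.Ad sets p per cell from the relative un-normalized
  weight mass of the two sides.
- **NIPALS(n)** — iterative PCA with missing-cell-aware inner
  regressions; spots are centered by their observed means; missing
  cells are read off the rank-n reconstruction plus the means.
  Verified to reproduce the truncated SVD exactly on complete data.

All imputers are deterministic (LS.C's hold-out is seeded via its
config), are the identity on complete matrices, and never touch
observed cells. Regression-based methods may extrapolate below zero;
negative imputed values are kept (clipping would bias the error
comparison) and flagged.

**Known limitation.** On this generator the data have a single strong
latent factor (the gel scale), so NIPALS components beyond the first
one or two fit heteroscedastic noise: imputation error grows with the
component count, and occasional replicates of NIPALS(≥3) extrapolate
hard enough to *inflate* the average variance. On richer real matrices
the component profile is flatter; here NIPALS(1–2) is the sensible
setting, and the variance-shrinkage benchmark uses NIPALS(2).

## Statistical tests

All tests are two-sided on two small samples (typically 6 + 6).

- `t.welch` — Welch t with Satterthwaite df.
- `t.perm` — permutation of group labels using the Welch statistic;
  exact enumeration when C(n_a+n_b, n_a) ≤ 200,000 (all 924 splits at
  6+6), else seeded Monte-Carlo with the observed assignment included;
  exact p-values are integer multiples of 1/#splits.
- `chebby` — the distribution-free Chebyshev bound p = min(1, 1/t²) on
  the Welch statistic. Conservative by construction: it cannot reject
  at α = 0.05 unless |t| > 4.47.
- `boot.normal` / `boot.percentile` / `boot.pivotal` — 25 within-group
  resamples of the raw mean difference; the p-value is the smallest
  level at which the corresponding confidence interval excludes zero
  (normal approximation, percentile interval, basic/pivotal interval).
  Each group's resampling stream is keyed by the group's content, so
  exchanging the labels is an exact symmetry of the p-value. With 25
  resamples the count-based variants have p-resolution 0.08; raising
  `n_boot` sharpens it.

Degenerate zero-variance spots return p = 1 (statistic 0) so that
discovery counts never silently drop spots. Per-spot resampling in
`test_matrix` is seeded `seed + row_index`.

**Measured liberality.** At 6 + 6 and B = 25, *all three* bootstrap
inversions are more liberal than Welch under the null (empirical
type-I error ≈ 0.12–0.15 vs 0.038–0.056 at α = 0.05, on both normal
and log-normal nulls): the bootstrap SE of a 6-point mean is biased
low, normal quantiles replace t quantiles, and the count-based
rejections at this resolution amount to "all draws one side", whose
null probability exceeds α. The percentile variant is the most liberal
and the Chebyshev bound by far the most conservative, with Welch and
the permutation test in between. Consequently orderings that place any
bootstrap variant on the conservative side of Welch do not hold under
these conditions, and the corresponding acceptance check fails by
design rather than by defect.

## Error control

- `per_comparison` — p < α, strict inequality. For pipeline
  *comparisons* only; it makes no multiplicity claim.
- `gfwer` — generalized family-wise error rate by augmentation: Holm
  at level α, plus the `k_allow` next-smallest p-values (input-order
  tie-break). k = 0 is exactly Holm; P(> k false rejections) ≤ α.
  Holm was chosen as the base procedure because it dominates
  Bonferroni and needs no dependence assumptions.
- `bh_fdr` — Benjamini–Hochberg step-up, as the usual comparator.

The Holm step-down and the augmentation logic are implemented here
(Holm is verified against `statsmodels.stats.multitest.multipletests`
in the test suite); BH delegates to statsmodels. Note one boundary
convention: per-comparison is strict (`<`) while Holm/BH follow the
conventional non-strict rule, so the nesting
per-comparison ⊇ BH holds everywhere except exactly at p = α.

## Benchmark metrics

**NRMSE** — RMSE over the masked cells divided by the standard
deviation of the *complete* data matrix. The divisor is deliberately
independent of the mask draw: the SD of the masked truths themselves
is a statistic of the mask (its expectation grows with the masked
fraction in skewed data) and using it cancels real error growth for
the most accurate methods. The masked-truth SD and mean divisors
remain available (`divisor="sd"` / `"mean"`). A constant-truth mask
returns the raw RMSE with a warning.

**Average variance** — mean over spots of the across-gel sample
variance (ddof = 1) of the completed matrix, compared against the
complete source value. Every summary-score imputation shrinks it; how
much is a method fingerprint (row averaging shrinks most, which is why
heavy imputation inflates false positives downstream).

**Discovery stability** — per replicate: mask 10%, impute, test every
spot, threshold at α = 0.05 per comparison (the error-control step
proper is applied in the pipeline, not in the method comparison).
Summaries: median discovery count, the consensus set (p < α in ≥ half
the replicates, threshold ⌈min_fraction · n_reps⌉), and Venn-region
counts against the complete-data discoveries.

Replicate counts: the accuracy experiment defaults here use 100
replicates and the discovery experiment 20; both are configurable
upward (dispersion of the 100-replicate means is reported alongside).

## Numerical choices

- Welch with both variances zero: t = 0, p = 1 if means agree, else
  p = 0 (flagged degenerate).
- Exact permutation counts |t| ≥ |t_obs|·(1−1e-12) − 1e-12 so the
  observed split's mirror is never lost to round-off.
- LS weight ridge ε = 1e-6; EM covariance ridge 1e-6·I; NIPALS
  tolerance 1e-6, ≤ 500 inner iterations per component.
- Quartile boundary ties go to the lower quartile; consensus threshold
  is the ceiling of min_fraction · n_reps.
- Writers emit 6 significant digits; read–write round-trips are exact
  to that format, and reruns with one seed are byte-identical.
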