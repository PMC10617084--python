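# Methods

## Model and test

Expression is modelled per gene by a shared linear model: for sample i,
`Y_i ~ MVN_q(X_i B, Σ)`, with an `n × p` design `X` of full column rank
and a single-degree-of-freedom contrast `c` (k = 1; multi-column interest
blocks are out of scope because every enrichment score consumes one signed
statistic per gene).  Fitting goes through one QR decomposition of the
design after an orthogonal change of coefficients that makes the contrast
the last fitted coordinate.  Each gene then reduces to a (d+1)-vector
`t_g = (u_g, r_g1..r_gd)` with `u_g = effect_g / sqrt(c'(X'X)⁻¹c)` and
`||r_g||² = RSS_g`, `d = n − p`.

Variance moderation fits a scaled-F prior to the sample variances by
matching the mean and variance of `log s²` to the log-F distribution
(digamma/trigamma inversion; Newton iteration at tolerance 1e-8, max 50
steps).  Prior degrees of freedom above 1e7 are reported as infinite, in
which case the prior collapses to a point mass estimated by the arithmetic
mean of the sample variances.  Genes with `s² = 0` are excluded from the
prior fit and receive the posterior `d0·s0²/(d0+d)`.  Moderated t-values
(`d + d0` df) are z-transformed through the Student-t survival function;
the enrichment scores consume z by default (`use_z=False` switches to raw
moderated t) — the z-scale matters mostly at small d, where the t
distribution is heavy-tailed and would distort genome-wide centering.

A rotation applies one Haar-distributed orthogonal `(d+1) × (d+1)` matrix
(QR of a standard-normal matrix with R's diagonal signs forced positive —
plain QR is not Haar) to every gene's `t_g`.  Only the first row is
needed: the rotated effect is `u'_g = w·t_g` and the rotated residual
variance follows from norm conservation, `s²' = (||t_g||² − u'²)/d`.  The
prior `(d0, s0²)` and the z-transform degrees of freedom are estimated
once on the observed data and held fixed across rotations; re-estimating
per rotation would change the null and triple the cost.  The identity
rotation reproduces the observed statistics exactly, which the tests
assert.

P-values use the `(1 + exceedances)/(n_rot + 1)` convention, so they are
exactly valid, never zero, and have granularity `1/(n_rot+1)` (500
rotations by default).  Directional scores are two-sided with the observed
direction annotated; absmean is upper-tail.  All sets in one run share the
same rotations, so results for duplicated sets are identical and
cross-set comparisons are not distorted by resampling noise.
Benjamini–Hochberg FDR is applied per score across retained sets
(retention window 5–500 measured genes by default).

## Score conventions

Ranks are decreasing in δ with average-rank ties, then stable gene order;
the KS thresholds inherit this.  Competitive centering/scaling uses all q
genes (the set included), sd with the n−1 divisor, and mad without a
consistency factor.  In maxmean, `sgn(0)` matches both directions (a zero
gene contributes zero either way); if the mean score is exactly zero no
gene is zeroed and a warning is emitted.  The KS running difference is
evaluated at the in-set ranks, where its maxima occur; because the walk is
pinned after the last in-set step, the extremes — and therefore ksmax and
ksmean — are antisymmetric under negation of δ only up to one walk step,
unlike the other directional scores, which are exactly antisymmetric.
The ksmax weights are `|δ_i − δ̄|^k` and the ksmean weights
`|(2ρ_i + q + 1)/2|^k` as specified; the latter are strictly positive and
increasing in rank, which makes the k > 0 ksmean asymmetric between the
up- and down-regulated tails — `ksmean_centered_weights=True` substitutes
the reversal-symmetric centered rank `(q+1)/2 − ρ_i` for users who want
tail symmetry.  The default exponent is k = 1 (k = 0 gives the classical
unweighted KS).

## Effective signature size

The diagnostic asks how many randomly chosen genes would give a set score
as variable under rotations as the testing set's (`v_s`, sample variance
over rotations).  For each m in a grid (about 15 log-spaced integers from
1 to `min(q−1, 4·m0)`, always including m0), L = 50 random sets are drawn
uniformly from all q genes (without replacement within a set, the testing
set not excluded) and scored on the *same* rotations;
`pval(m) = 2·min(p_R, 1−p_R)` with `p_R = L⁻¹ Σ I(v_R > v_s)`.  The curve
is the primary output; the point estimate is the argmax (smallest m on
ties) — a deliberately least-committal summary, since the curve, not a
point, is the meaningful object.

Two caveats are inherent to the estimator, not the implementation.
First, the rotation null conditions on the observed residual geometry:
with d+1 rotation dimensions, chance gene–gene correlations of order
`1/sqrt(d+1)` contribute to every set's score variance, so at very small n
(say 10) the single-instance point estimate scatters widely (roughly a
factor of two) around the independence-equivalent size.  From n ≈ 40 the
estimate stabilizes; the recovery checks therefore run at n = 40–100 and
compare medians over independent instances.  Second, `v_s` itself varies
between dataset realizations, which moves the argmax between neighbouring
grid points even when the curve is sharp.

## Synthetic data

The generator reproduces the statistical structure of two-group
differential expression studies at reduced dimension, with parametric
stand-ins for empirical covariance and counts (user matrices are
accepted wherever a base matrix is consumed):

- **Covariance**: block-exchangeable correlation — `rho_within` (default
  0.3) among the m0 = 30 target genes, `rho_background` (default 0)
  elsewhere — shrunk towards the identity, `Σ = (1−λ)C + λI` with λ = 0.1.
  The realized in-set correlation (1−λ)·0.3 = 0.27 matches the upper end
  of what curated signature collections show (mean intra-set correlations
  of roughly 0.1–0.3); `rho_within = 0` gives the uncorrelated control.
  Positive definiteness is certified by Cholesky (guaranteed for
  0 ≤ rho_background ≤ rho_within < 1).
- **Scenarios**: SC0 null; SC1 uniform shift of all set genes; SC2 shift
  of a contiguous sub-block (`active_fraction`, default 0.3); SC3 two
  sub-blocks shifted +e and −e (net set mean zero); SC4 a few outliers
  (default: ⌈0.1·m0⌉ genes at 5× the base effect).  Samples split n/2
  versus n/2 with the shift added to group 1.
- **Effect sizes**: defaults were calibrated once by simulation at the
  default conditions (q = 1000, n = 10, m0 = 30, rho_within = 0.3) so that
  power at n = 10 is informative rather than saturated — SC1 0.9 (mean
  score power ≈ 0.7), SC2 1.2, SC3 0.7, SC4 0.4 log2 units — and are
  fixed; they are package defaults, not values carried over from any
  external study.
- **Counts**: negative-binomial base counts (log-normal gene means,
  dispersion 0.1) thinned binomially — per gene and sample the count is
  downsampled with probability `2^(lfc·x_j)` normalized to a maximum of 1
  across samples, implanting exact expected log2 fold changes without
  touching the best-covered group.  Log-CPM regularization is
  `log2(CPM + 0.5)`: the pseudocount lives on the CPM scale, making the
  transform exactly invariant to sequencing depth (a zero count maps to
  log2(0.5)).  This is a deliberately simple regularization; the choice
  is orthogonal to the scores under test.

What the simulations do **not** emulate: empirical covariance beyond one
exchangeable block (no long-range co-expression structure), mean–variance
trends across genes on the microarray side, batch effects, outlier
samples, or library-composition biases.  A green simulation suite
therefore demonstrates calibration and relative power under the stated
correlation structure, not performance on any particular real dataset.

## Evaluation machinery

Recovery rates are rejection proportions at α = 0.05 over independent
instances.  The benchmark-ranking measures compare a GSA ranking I(i)
(1 = most significant of p sets) with non-negative relevance scores ρ:
`M1 = Σ ρ_i (1 − I(i)/p)`; M2 restricts the sum to sets ranked in the top
50 (configurable).  The permutation p-value counts random rankings whose
M1 strictly exceeds the observed value, divided by the number of
permutations; ties count as non-exceedances, and a `plus_one` flag
switches to the (1+count)/(n_perm+1) convention.

## Numerical and design notes

- All seven scores run vectorized over rotation rows; the KS walk uses a
  closed-form out-of-set count when ranks are untied (the generic path
  handles ties) and the linear scores (mean, absmean, meanrank) reduce to
  a single matrix product in the effective-size loop.
- Simulation studies in the test-suite run at q = 1000, n = 10, m0 = 30,
  500 rotations and 200 instances per condition (1000 instances for the
  null-uniformity check at reduced q, and in `scripts/acceptance.py`);
  these sizes were chosen so each study carries enough Monte-Carlo
  precision for the bound it checks.
- Degenerate inputs fail loudly rather than silently: zero genome spread
  in competitive centering, all-zero KS weights, saturated models (all
  residual variances zero), rank-deficient designs, missing values.
- Gene matching between GMT and expression is exact, case-sensitive
  string equality with an opt-in case-insensitive mode, because silent
  case folding is a reproducibility hazard.

## Known limitations

Only k = 1 contrasts are supported (no F-mode over multi-column interest
blocks); no observation weights, duplicate-correlation, or
variance-trend priors; restricted/approximate rotations for very large n
are not implemented (each rotation draws a full (d+1)² Haar matrix, fine
up to a few hundred samples); the effective-size point estimate should be
read alongside its curve, for the reasons above.
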