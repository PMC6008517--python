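# Methods

## Probability of superiority as a moment

For paired observations the sample PS statistic counts same-side-of-mean
pairs, with a half count when a pair sits exactly at both means and a zero
contribution when exactly one coordinate is at its mean (the statistic's
denominator always stays `n`).  "At the mean" is decided after centering
with a relative guard of `1e-12 · sd(x)`, because discrete scores minus a
rational mean need not center exactly in floating point; for continuous
data the guard never fires.  A constant vector makes every pair a tie and
returns 0.5 with a warning rather than an error, since 0.5 is the
statistic's no-information value.

For a bivariate normal pair with correlation `r`, the population PS is the
orthant probability `asin(r)/pi + 0.5`; the sample statistic converges to
it (checked by simulation at n = 10^6 within ±0.003).  The PS matrix
**S_PS** places `pi_jk · sqrt(Var_j Var_k)` off the diagonal and the
(n−1)-denominator sample variances on it.  The n−1 convention is used for
every variance in the package so that PS-based and Pearson-based inputs
differ only in their off-diagonal association measure.  Under
independence the PS off-diagonals sit at `0.5 · sqrt(Var_j Var_k)`, not at
zero: **S_PS** is a moment-like matrix, not a covariance, which is exactly
why feeding it to covariance-structure estimators is a substantive
modeling decision rather than a relabeling.

Since the entries of **S_PS** are probabilities, the matrix can be
indefinite in small samples.  `ensure_estimable` repairs a matrix whose
smallest eigenvalue falls below a floor (default 1e-6) by spectral
clipping with the diagonal restored; if restoring the diagonal breaks
definiteness again it instead shrinks the off-diagonal block toward the
diagonal by the smallest factor that reaches the floor.  Repairs are
recorded on the matrix's warning list.

## Estimation

The implied structure is `Sigma(theta) = Lambda Phi Lambda' + Theta` with
standardized latent variables: factor variances fixed at 1, factor
correlations free, residual variances free and diagonal.  When factors
are regressed on observed exogenous covariates the reduced form is used
(`Phi_eff = Gamma Phi_x Gamma' + Psi`, `Sigma_yx = Lambda Gamma Phi_x`,
`Sigma_xx = Phi_x` saturated via its Cholesky factor).  Free-parameter
count `t` and `df = (p+q)(p+q+1)/2 − t`; the study model (4 factors × 5
items) has t = 46 and df = 164.

ML minimizes `tr(S Sigma^-1) + log|Sigma| − log|S| − (p+q)` directly;
WLS/ULS minimize the vech-space quadratic form, WLS with the inverse of
the ADF weight `W[ij,kl] = m_ijkl − s_ij s_kl` estimated from centered
raw data (a warning is issued when `n ≤ p(p+1)/2`, where that estimate is
singular and a pseudo-inverse is used).  The normal-theory weight
`0.5 D'(S^-1 ⊗ S^-1) D` is implemented for cross-checks: the tests verify
it reproduces the ML discrepancy to first order near the optimum, so the
two presentations of the ML estimator agree where it matters.

Bounds are enforced by reparameterization — log for variances, atanh for
correlations — so the optimizer (L-BFGS-B) runs unconstrained.  Gradients
are analytic for pure measurement models (the dominant path in the
simulations; verified against finite differences) and numerical when a
structural block is present.  Convergence requires gradient sup-norm
below 1e-5 (or a discrepancy below 1e-10, i.e. perfect fit); on failure
up to five jittered restarts are attempted from the default start values
(loadings 0.5, correlations 0.2, residuals at half the observed
variances).  A residual variance under 1e-3 or a factor correlation above
0.995 in magnitude flags a Heywood case without interrupting the fit.

Chi-square uses the conventional Wishart scaling `(n−1) · F` for every
estimator, including PS-fed ones (whether an effective n would be more
appropriate for PS inputs is an open question; the uniform choice keeps
estimators comparable).  ULS values are scaled for reporting but flagged
as not chi-square distributed.  The independence baseline is solved in
closed form (`F = −log|R|` for ML; a diagonal-restricted linear solve for
the quadratic discrepancies), and
`CFI = 1 − max(chi2−df, 0)/max(chi2_b−df_b, chi2−df, 0)` (clipped to
[0, 1], 1 when both non-centralities vanish),
`RMSEA = sqrt(max(chi2−df, 0)/(df (n−1)))`.

Standard errors: inverse curvature of the (n−1)-scaled discrepancy at the
optimum for ML/WLS/ULS; `mlr` keeps ML's point estimates and replaces the
SEs by the Huber–White sandwich `A^-1 B A^-1` with casewise numerical
scores, which requires raw data.  For exactly multivariate normal data
the two agree asymptotically (tested at n = 10^5 within 5%).

## Data generators

All generators are pure functions of (parameters, seed), seeded through
`numpy.random.SeedSequence(master, cell, rep)` so that study cells can run
in parallel in any order with identical results.

**Linear conditions.** Continuous data are multivariate normal draws from
the model-implied covariance.  Ordinal b-point data (b ∈ {2, 3, 5, 7})
are produced through a Gaussian copula: the latent normal correlations
are first *raised* to the intermediate values whose equal-probability
b-category discretization returns the target Pearson correlations (solved
by bisection on exact bivariate-normal rectangle probabilities, cached
per (r, b)), then cut at standard-normal quantiles.  A plain cut without
the compensation would attenuate the correlations — by the classic factor
(2/pi)² ≈ 0.64 at b = 2, ≈ 0.89 at b = 5 — and the linear-ordinal cells
would no longer be a "linear relation holds" condition at all; the
compensation is what makes them a fair baseline.

**PS conditions.** Each normal score is replaced by a draw that retains
only the side of the column mean it fell on:

* continuous — uniform on (0, √12/2) above the mean, (−√12/2, 0) at or
  below, so the marginal SD is 1;
* 2-point — the indicator of exceeding the mean;
* b-point (b odd) — the cutoff `c = b/2 + 0.01` splits the b integer
  categories `{−⌊c⌋, …, ⌊c⌋}` into disjoint sides: uniform on
  `{0, …, ⌊c⌋}` above the mean, on `{−⌊c⌋, …, −1}` at or below.

Because the two sides are disjoint in every transform, the side-of-mean
pattern — and hence the sample PS between any two columns — is carried
over exactly: the population PS between transformed columns equals the
orthant probability of the generating correlation at every measurement
scale.  (An alternative reading of the ordinal transform that lets both
sides draw the midpoint 0 was considered and rejected: midpoint draws
then erase the side information, the PS of the transformed columns drifts
toward 0.5, and the PS estimators' population values would differ by
scale — contradicting the design's intent that the ten scales share one
population structure.  The transformed column mean always falls strictly
between −1 and 0, so the disjoint reading is also self-consistent under
sample-mean centering.)  The Pearson correlation of the transformed
columns, by contrast, is attenuated — by exactly 3/4 in the continuous
case (`corr(z_j, z_k) = (3/4)(2 pi_jk − 1)`) — which is precisely the
mechanism the simulation isolates.

The bivariate Blomqvist-type generator draws x from a chosen marginal and
places y on the same side of its mean with probability γ (uniform
magnitudes up to c, default √3 so Var(y) ≈ 1, y pinned to its mean when x
is at its mean); the sample PS of the output converges to γ.

## The Monte Carlo study

Full design: 10 measurement scales × 4 sample sizes (400–1600), 1000
replications, seven estimators; per replication all estimators see the
same dataset, conventional ones through the Pearson matrix, PS ones
through **S_PS**.  Both inputs are rescaled to unit diagonal before
fitting, so estimates are standardized and directly comparable to the
generating loading 0.70 across ordinal scales whose raw score variances
differ; for PS inputs this makes the off-diagonals the raw PS values, the
analogue of requesting a PS correlation matrix.

Percentage bias `(mean estimate − true)/true` is averaged over the 20
loadings and 6 factor correlations.  Conventional estimators are
referenced to the generating values.  PS estimators are referenced to
their *pseudo-true* values — the parameters recovered from the population
PS matrix (off-diagonals `asin(rho)/pi + 0.5`), which this model fits
exactly: `lambda* = sqrt(asin(0.49)/pi + 0.5) ≈ 0.8143`,
`phi* = (asin(0.147)/pi + 0.5)/lambda*² ≈ 0.8250`, identical across the
five PS scales by the sign-preservation property.  A PS coefficient of
0.81 is a probability statement, not an inflated loading; judging it
against 0.70 would compare quantities on different scales.  Because the
population PS matrix is fitted exactly, the pseudo-true values do not
depend on which discrepancy computes them.  Non-converged replications
(rare: none observed for the correctly specified model at n ≥ 400) are
dropped from averages and counted; a cell with under 50% convergence is
flagged unusable.

Empirical SE is the SD (reps − 1) of the replicate estimates.  Fit
indices are averaged per cell; the reproduced warning pattern is that
conventional ML keeps mean CFI ≈ 0.995 and mean RMSEA ≈ 0.006 even on PS
data where its loadings are ~20–30% attenuated.

**Problem sizes.** The package's desk-scale profile — chosen as the
default because the grand means stabilize well before the full design —
uses 100–150 replications at n ∈ {400, 1600}, with the linear kind at the
continuous and 5-point scales and the PS kind at all five scales
(`scripts/acceptance.py`; about a minute on one CPU).  The full
1000-replication, 40-cell design runs through `pssem simulate --full` in
a few hours.  With 150 replications the Monte Carlo SE of a grand-mean
bias is under 0.002, an order of magnitude inside the evaluation band of
±0.10.

## Known limitations

* The PS transforms emulate data whose *only* structure is the
  side-of-mean pattern; real PS-related data would also carry magnitude
  information, skewness, or measurement error that these generators do
  not model.  Passing tests show the estimators recover the intended
  population quantities under the stated generating processes, not that
  any particular real dataset is PS-related.
* The sampling distribution of PS-fed discrepancies is not formally
  chi-square; CFI/RMSEA from PS fits are reported with the conventional
  (n−1) scaling and should be read comparatively, not as calibrated test
  statistics.
* No mean structures, multiple groups, missing-data estimators, or
  scaled chi-square corrections; `mlr` adjusts standard errors only.
* WLS at n = 400 with 20 indicators sits near the ADF weight's stability
  limit (210 moment equations); its known small-sample erraticism is
  reproduced, not repaired.
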