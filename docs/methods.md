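# Methods

`twingxe` implements a psychometric-genetic analysis pipeline for polytomous
twin questionnaire data, built around the Wilson-Patterson-style
conservatism/liberalism scale: homogeneity scaling of nominal responses,
generalized partial credit (GPCM) item response modelling, and a joint
Bayesian ACE variance decomposition with genotype-environment interaction
estimated simultaneously with the measurement model.

## The generative and inferential model

### Measurement: three-category GPCM

An item k with discrimination `a_k > 0` and step thresholds `b_k1`, `b_k2`
assigns a respondent with latent trait `theta` the categories
"no" (0), "?" (1), "yes" (2) with probabilities proportional to the step
weights

    w0 = 1,   w1 = exp(a_k (theta - b_k1)),   w2 = w1 * exp(a_k (theta - b_k2)),

normalized by `w0 + w1 + w2` (the standard partial-credit normalizer: every
unnormalized category weight enters the denominator).  The PCM is the
restriction `a_k = 1` for all items.  Reverse-coding an item is equivalent to
negating the trait and negating-and-swapping the thresholds, an identity the
tests verify exactly.

Two identification conventions coexist and a conversion helper
(`irt.rescale_item_params`) maps between them:

* stand-alone marginal-maximum-likelihood fitting fixes the trait at
  N(0, 1) and frees all discriminations (the convention of standard MML
  software);
* the Bayesian joint model fixes the phenotypic mean at zero, frees two
  thresholds per item, and fixes the discrimination of one reference item
  (by default the third item in input order) to 1, leaving the trait
  variance free to decompose.

### Biometric model with A x E and A x C moderation

The latent trait of twin j in family i decomposes into additive-genetic (A),
common-environment (C) and unique-environment (E) parts.  Environmental
variances depend exp-linearly on the genetic value (the exponential keeps
variances positive):

MZ pairs (A shared):

    A_i ~ N(0, sigma2_A)
    C_i ~ N(0, exp(gamma0 + gamma1 A_i))
    theta_ij ~ N(A_i + C_i, exp(beta0 + beta1 A_i))

DZ pairs (genetic correlation 1/2, built hierarchically):

    A1_i ~ N(0, sigma2_A / 2);  A2_ij ~ N(A1_i, sigma2_A / 2)
    C_i ~ N(0, 1);  C2_ij = C_i * sqrt(exp(gamma0 + gamma1 A2_ij))
    theta_ij ~ N(A2_ij + C2_ij, exp(beta0 + beta1 A2_ij))

`beta1` measures A x E, `gamma1` measures A x C.  MZ moderation uses the
pair-shared genetic value while DZ moderation uses each twin's own `A2`;
this asymmetry is part of the model and is preserved deliberately.
Heritability is computed per posterior draw as
`h2 = sigma2_A / (sigma2_A + exp(gamma0) + exp(beta0))`.  Note that summary
tables published for this model report component means (0.43, 0.29, 0.07)
whose ratio is 0.43/0.79 ~ 0.54, yet print h2 = 0.43; this package applies
the stated formula per draw and surfaces the resulting value, so its `h2`
row follows the formula, not the printed headline number.

### Priors

* `sigma2_A ~ InvGamma(1, 1)` (shape/scale; density proportional to
  `x^-2 exp(-1/x)`), conjugate given the latent genetic values.
* log-variance intercepts `beta0, gamma0 ~ N(-1, 2)`; the hyperparameters are
  mean and **variance** (not precision).  The notation
  "exp(beta0) ~ N(-1, 2)" in the source material is read as the log-variance
  being normal, consistent with the exponential link.
* slopes `beta1, gamma1 ~ N(0, 10)`; thresholds `~ N(0, 10)`;
  log-discriminations `~ N(0, 10)`.
* in variants without an interaction the corresponding variance
  `exp(intercept)` gets an `InvGamma(1, 1)` prior instead (applied through
  the change of variables; the log-variance parameterization is kept so all
  four variants share one code path).

### Sampler

`biometric._run_chain` is a fully vectorized Metropolis-within-Gibbs sampler:

* conjugate Gibbs draws for `sigma2_A`, the MZ common effects, the DZ `A1`
  and the DZ common effects (all Gaussian or inverse-gamma conditionals);
* adaptive random-walk Metropolis for every trait value (one proposal scale
  per individual), every genetic value, every item-parameter triple and the
  four global variance parameters, with Robbins-Monro adaptation toward
  0.44 (scalar) / 0.234 (block) acceptance, frozen after burn-in to preserve
  detailed balance;
* **non-centered moves** that are essential for this posterior's geometry:
  (a) genetic-value proposals that move `A` together with the common effect
  and the trait, holding the *standardized* residual fixed, so the Gaussian
  density terms cancel against the Jacobian and only the A-prior and the
  item likelihood decide acceptance; (b) global moves for
  `beta0, beta1, gamma0, gamma1` that rescale every common effect and trait
  around its mean in the same standardized sense; (c) family-level A-vs-C
  "swap" moves that exchange genetic and common-environment allocation while
  leaving the trait untouched.  Without these moves the chains stall on the
  A-versus-C ridge and in the funnel created by `exp(beta0 + beta1 A)`
  spanning two orders of magnitude at the published `beta1 = -2.81`.

Joint fits start from data-informed values computed once per fit — a quick
marginal-maximum-likelihood GPCM fit whose item estimates and EAP traits are
rescaled to the fixed-discrimination convention, with the variance components
split by MZ/DZ covariance moments — and each chain jitters these starts with
its own RNG so the between-chain PSRF diagnostic retains meaning.  This keeps
the prescribed burn-in lengths adequate; naive starts need several times
longer to traverse the measurement-error-versus-E-variance ridge.

Chains are seeded from one `SeedSequence`; identical seed and configuration
reproduce chains bit-for-bit.  Convergence is monitored with the
within/between-chain potential scale reduction factor; parameters whose PSRF
exceeds 1.1 are attached to the fit as explicit warnings, never swallowed.

Deviance focus: `D = -2 log p(Y | theta, item parameters)` (observed nodes
given their parents), matching the convention of general-purpose Gibbs
engines; `pD = mean(D) - D(posterior means of theta and item parameters)`
and `DIC = mean(D) + pD`.  Because DIC is focus-dependent the focus is
recorded in the CLI output metadata.

Presets: the survey-scale preset uses 6 chains with 20,000 burn-in and
20,000 retained iterations each (120,000 retained in total); the reduced
preset uses 3 chains, 2,000 burn-in, 3,000 retained; the sum-score model
defaults to one chain, 10,000 burn-in, 15,000 retained.

### Sum-score comparison model

`AceSumScoreModel` drops the measurement layer and treats the standardized
sum score (categories scored 0/1/2, reverse-keyed items flipped, complete
cases, rescaled to mean 0 and variance 1) as the phenotype directly.
Contrasting it with the joint fit on the same item data reproduces the
skewness artifact: with skewed category frequencies and a negative A x E
slope, the sum-score fit pulls `beta1` toward or above zero and flips the
A x C sign, while the joint fit keeps the generating signs.

## Homogeneity analysis

Nominal responses are expanded into a complete-case indicator matrix (rows
with any missing scored item are dropped; items with a single observed
category are degenerate and dropped with a warning).  Alternating least
squares minimizes the average squared distance between object scores and the
chosen categories' quantifications, with deterministic SVD initialization,
object scores centered and scaled to unit variance per dimension, and a
final rotation to principal axes so dimensions are ordered by their
discrimination eigenvalues.  The loss is non-increasing by construction
(each half-step is an exact constrained least-squares solve) and the ALS
stops when the relative loss change drops below 1e-8 (500 iterations
maximum, error with the loss trace otherwise).  An item's loading on a
dimension is the correlation between its quantified scores and the object
scores — the component-loading convention of nominal-PCA software.  The
eigenvalue scale follows this normalization and is comparable only within
the package.

The item-selection rule retains items whose absolute loading on the
designated trait dimension strictly exceeds the absolute loading on the
"?"-separation dimension; ties are excluded.  Category points are the
centroids of the individuals choosing each category; the ordinality check
verifies that the "?" point lies between the "no" and "yes" points on the
chosen dimension, the prerequisite for applying an ordinal partial-credit
model.

Classical statistics: Cronbach's alpha `k/(k-1) (1 - tr(S)/sum(S))`,
Guttman's lambda-2 `(sum_offdiag(S) + sqrt(k/(k-1) sum_offdiag(S^2))) /
sum(S)` (always >= alpha), and item-total correlations (uncorrected by
default; the item-rest variant is available because published item-total
ranges do not state which was used).

## Item fit

Item fit compares observed and expected response frequencies across
equal-frequency bins of the total score.  Expected frequencies are
*conditional on the total score* under the fitted model, computed exactly
with the Lord-Wingersky recursion over the remaining items.  A plug-in
construction that evaluates category probabilities at a bin's mean estimated
trait inherits the part-whole dependence between an item and its own total
score and rejects the true model almost surely at survey sample sizes
(chi-square/df near 15 under the null in our measurements); the
score-conditional construction stays calibrated (chi-square/df near 1 under
the null), which is what makes the statistic usable for model criticism.
Degrees of freedom are `bins x (categories - 1) - m_item` with `m_item` the
per-item parameter count and the realized bin count after merging tied score
values.

## Synthetic data

The generator (`twingxe.simulate`) emulates the structure of the Virginia
30K twin survey scale: 2,795 MZ and 3,280 DZ pairs by default, the published
9-item GPCM parameters as the default instrument, the published biometric
posterior means as default generating truth, and independent per-cell
missingness (missing-at-random) at rate 0.05 — the survey's item-level
missing rate is not published, so 0.05 is a package default, stated here
once and not revisited.  Families are emitted MZ-block-first with
deterministic ordering and all randomness flows from a single seeded
generator.

What the generator does *not* emulate: parent phenotypes and assortative
mating, age/sex structure, non-random missingness, local item dependence,
and any multidimensionality beyond the explicit trait + "?"-propensity
construction used in the psychometric tests.  Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to the full messiness of survey data.

## Problem sizes used by the test suite

All checks run unconditionally on one CPU; stochastic end-to-end checks use
fixed seeds and reduced problem sizes chosen up front:

* parameter recovery: 300 MZ + 350 DZ pairs, 2 chains (2,000 burn-in /
  3,000 kept); the acceptance script runs the full reduced design of
  700 MZ + 800 DZ pairs with 3 chains.
* DIC model selection: 3 replicates of 700 + 800 pairs, single chains.  The
  A x C increment is intrinsically small (a handful of DIC units at full
  survey scale), so the majority-of-replicates claim is the strongest
  statement the reduced design supports.
* sum-score artifact: 300 + 350 pairs, one joint chain and one sum-score
  chain.
* calibration: 20 replicates of 300 + 350 pairs with both slopes zero; the
  95% HPDs must cover zero in at least 16 of 20 replicates per slope.  At
  these sizes the A x C slope's posterior is skewed and slightly
  anti-conservative, so nominal-rate coverage is approached, not exactly
  attained; at full survey scale both slopes center on zero.
* psychometric structure: 3,000 individuals, 6 trait items + 3
  "?"-propensity items.

## Known limitations

* DIC differences of a few units are within Monte-Carlo error at reduced
  chain lengths; model selection between the A x E-only and the full model
  is only weakly resolved below survey scale.
* The A x C slope mixes most slowly of all global parameters; at small
  sample sizes single chains can understate its posterior spread.  Use
  multiple chains and heed the PSRF warnings.
* MZ-only data cannot separate A from C; the sampler runs and the two
  variance chains exhibit the expected strong negative correlation (a
  documented diagnostic, not an error).
* The homogeneity eigenvalue scale is package-specific; only qualitative
  comparisons with other nominal-PCA implementations are meaningful.
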