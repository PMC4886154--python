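# twingxe

Psychometric-genetic analysis of polytomous twin questionnaire data:
homogeneity (Gifi) scaling of nominal items, generalized partial credit
(GPCM) item response models, and a joint Bayesian ACE twin model with
genotype-environment interaction.

## The problem

Classical twin analyses of attitude scales such as the Wilson-Patterson
conservatism scale sum the item responses ("no"/"?"/"yes" scored 0/1/2) and
decompose the sum-score variance into additive-genetic (A),
common-environment (C) and unique-environment (E) parts.  Two things go
wrong with that recipe:

1. **The "?" category is not halfway between "yes" and "no".**  For many
   catch-phrase items a "?" mostly marks respondents without an opinion, so
   part of the scale measures opinionation rather than the trait.
   Homogeneity analysis (nominal principal components) makes this visible
   and motivates an item-selection rule that keeps only
   trait-discriminating items.
2. **Sum scores distort interaction effects.**  Skewed category frequencies
   skew the score distribution, and genotype-environment interaction
   estimates on a skewed scale are artifacts of the scale, not the biology.
   Modelling the interaction at the level of a latent trait, with the item
   measurement model estimated *simultaneously*, removes this artifact.

`twingxe` implements the full pipeline.  The biometric core is the ACE model
with exp-linear variance moderation: for MZ twin j in pair i,

    A_i ~ N(0, sigma2_A)
    C_i ~ N(0, exp(gamma0 + gamma1 * A_i))          # A x C interaction
    theta_ij ~ N(A_i + C_i, exp(beta0 + beta1 * A_i))  # A x E interaction

(DZ pairs use the hierarchical half-variance construction with genetic
correlation 1/2), and the trait theta feeds a three-category GPCM for the
observed item responses.  All latent variables and parameters are estimated
by an adaptive Metropolis-within-Gibbs sampler with non-centered moves;
model variants (with/without each interaction) are compared by DIC, and
posteriors are summarized with means, SDs, 95% HPD intervals and
Gelman-Rubin PSRF.  Heritability is `h2 = sigma2_A / (sigma2_A +
exp(gamma0) + exp(beta0))` per draw.

Because the underlying survey data (Virginia 30K twin sample) are not
publicly deposited, the package ships a first-class synthetic-data module
that generates twin families and item responses with exactly this structure,
defaulting to the published 9-item GPCM parameters and biometric posterior
means.

## Worked example

```python
from twingxe import (McmcConfig, ModelSpec, mcmc_fit_joint,
                     reference_generating_params, simulate_dataset)

params = reference_generating_params(n_mz=300, n_dz=350, seed=3)
data = simulate_dataset(params)          # 1300 rows x 9 items, 5% missing
fit = mcmc_fit_joint(data, ModelSpec(include_axe=True, include_axc=True),
                     config=McmcConfig(n_chains=2, burn_in=2000,
                                       n_kept=3000, seed=7))
print(fit.summary_.loc[["sigma2_A", "exp_gamma0", "exp_beta0",
                        "beta1", "gamma1", "h2"]].round(3))
```

prints (about a minute on one CPU):

```
             mean     sd  hpd_low  hpd_high   psrf  significant
parameter
sigma2_A    0.462  0.128    0.245     0.732  1.007         True
exp_gamma0  0.476  0.122    0.221     0.700  1.000         True
exp_beta0   0.103  0.061    0.017     0.227  1.000         True
beta1      -3.086  0.496   -4.044    -2.175  1.001         True
gamma1      0.659  0.428   -0.350     1.439  1.002        False
h2          0.448  0.110    0.238     0.655  1.000         True
```

Read: the additive-genetic variance is estimated at 0.46 (the generating
value 0.43 lies inside the 95% HPD), the unique-environment variance
intercept exp(beta0) at 0.10, and the A x E slope at -3.1 — individuals with
a low genetic value for liberalism show *more* unique-environment variance;
its HPD excludes 0 (significant).  The A x C slope is recovered positive
(0.66) but at 650 pairs its HPD still covers 0.  PSRF near 1 signals
converged chains.  Every generating parameter of this simulation is
recovered within its highest-posterior-density interval.

The same pipeline is scriptable from the shell:

```
twingxe simulate --n-mz 700 --n-dz 800 --seed 1 --out twins.csv
twingxe psychometrics --input twins.csv --out-dir out/psy
twingxe fit-irt      --input twins.csv --out-dir out/irt
twingxe fit-biometric --input twins.csv --preset reduced --out-dir out/bio
twingxe compare      --input twins.csv --preset reduced --out-dir out/dic
```

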