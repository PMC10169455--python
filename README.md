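# ordmi

Multiple imputation and cluster-weighted GEE for **multilevel ordinal
outcomes with informative cluster size**.

## The problem

In clustered studies the number of members per cluster is often itself
informative about the outcome: in periodontal research, subjects with
severe disease have fewer teeth, so tooth-level outcomes (e.g. ordinal
clinical attachment loss scores) are correlated with cluster size.  On top
of that, outcomes are frequently missing on existing members.  Ordinary
GEE is biased under informative cluster size (ICS), and naive handling of
the missing outcomes (complete-case analysis) is biased under anything but
MCAR.  `ordmi` provides, in one tested package:

- a **simulator** for clustered ordinal data with controllable
  within-cluster correlation (ICC, tau), degree of ICS (nu), and
  MCAR/MAR/MNAR missingness calibrated to target rates, built on the
  bridge random-effect distribution so the marginal model is exactly
  proportional-odds logistic;
- **CWGEE**: the marginal proportional-odds model
  `logit Pr(Y_ij <= c) = eta_c + x_i' beta` fitted by cluster-weighted
  generalized estimating equations
  `sum_i (1/n_i) sum_j D' V^{-1} (U_ij - mu_ij) = 0` with the robust
  sandwich covariance `H^{-1} M H^{-1}`;
- two multilevel **multiple-imputation** engines for the incomplete
  ordinal variables — FCS (chained random-intercept cumulative-probit
  Gibbs samplers) and JM (a multivariate latent-normal random-intercepts
  sampler with max-latent decoding) — each with an optional cluster-size
  covariate in the imputation model ("+CS");
- **Rubin pooling** of per-imputation CWGEE fits, and a **Monte-Carlo
  harness** comparing Full / CCA / FCS / FCS+CS / JM / JM+CS on mean
  estimate, mean SE, empirical SE, relative bias, coverage and MSE.

See `docs/methods.md` for the models and all numerical choices.

## Worked example

```python
import numpy as np
from ordmi import (GenerativeSpec, simulate_full_table, make_missingness_model,
                   default_aux_models, apply_missingness, fit_cwgee, wald_ci,
                   FCSConfig, fcs_impute, rubin_pool)
from ordmi.simulate import calibrated

rng = np.random.default_rng(7)
spec = GenerativeSpec(n_clusters=250, icc=0.3, ics_degree=0.4)
table = simulate_full_table(spec, rng)              # complete panel

outcome = calibrated(make_missingness_model("mar", 0.2), [table])
aux = tuple(calibrated(m, [table]) for m in default_aux_models())
amputed = apply_missingness(table, outcome, aux, rng)

cfg = FCSConfig(m=5, burn_in=500, between=200, include_cs=True)
completed = fcs_impute(amputed, {v: 4 for v in ("y", "m1", "m2", "m3")}, cfg, rng)
pooled = rubin_pool([fit_cwgee(d, 4) for d in completed.datasets])
print(pooled.ci().round(3))
```

Output (truth: eta = (−0.4, 0.8, 1.6), beta = (−0.2, −0.5)):

```
        estimate     se  lower  upper         df
eta_1     -0.460  0.090 -0.637 -0.283   1687.739
eta_2      0.714  0.095  0.528  0.899  16600.717
eta_3      1.505  0.116  1.276  1.734    119.730
beta_x    -0.187  0.032 -0.250 -0.125   7802.759
beta_z    -0.677  0.130 -0.932 -0.423    419.408
```

Every 95% interval covers its generating parameter even though 20% of
outcomes were missing at random and cluster size is strongly informative
(nu = 0.4); the pooled SEs combine the robust sandwich variance with the
between-imputation spread, and the large Rubin degrees of freedom show the
five imputations agree closely here.

The same pipeline is available from the shell:

```bash
ordmi simulate --seed 1 --out data.csv
ordmi ampute --mechanism mar --rate 0.2 --seed 2 --in data.csv --out amputed.csv
ordmi impute --method fcs --include-cs --m 5 --burnin 500 --between 200 \
             --seed 3 --in amputed.csv --out completed.csv
ordmi pool --in completed.csv --categories 4
ordmi study --mechanism mar --rate 0.2 --reps 100 --preset reduced --seed 7 --out results/
```

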