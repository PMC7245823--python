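# partgmm

Marginal logistic regression for longitudinal binary outcomes in which the
effect of each **time-dependent covariate** is *partitioned* by lag —
a cross-sectional coefficient plus one coefficient per wave of separation —
estimated by **two-step generalized method of moments (GMM)** with a
data-driven screen for valid moment conditions.

## The problem

In a panel study a covariate measured at wave *s* can affect a binary
outcome measured at the same wave and at later waves, and the strength and
even the sign of that influence can change with the separation *t − s*.
Standard GEE/GMM fits return a single coefficient per covariate — an average
over those separations. `partgmm` instead fits, for subject *i* at wave *t*,

```
logit(μ_it) = β₀ + β_F x_F + Σ_j [ β_j⁰ x_ijt + β_j¹ x_ij(t−1) + … + β_j^(T−1) x_ij1 ]
```

where `β_j⁰` is the immediate (cross-sectional) effect of covariate *j* and
`β_j^k` its lag-*k* (delayed) effect.  The design matrix stacks one
lower-triangular block per covariate: the lag-*k* column carries the value
measured *k* waves before the outcome row, and a structural zero where no
such measurement exists.  With *J* covariates and *T* waves the matrix has
*NT* rows and at most *(J × T) + 1* columns plus one per time-independent
covariate.

Estimation uses product-moment conditions `E[x·(y − μ)] = 0`.  Same-row
(cross-sectional and in-model lagged) pairings identify the coefficients and
give the step-1 working-independence fit.  The remaining (covariate wave
*s*, outcome wave *t*) pairs are valid only if the covariate does not
respond to earlier outcomes; each is screened with a bivariate Pearson
correlation between `x_ijs` and the standardized residual at *t*, referred
to a Fisher-*z* null.  Step 2 minimizes `Q(β) = ḡ(β)ᵀ W ḡ(β)` over the
selected moments, with `W` the inverse sample second-moment matrix of the
per-subject moment vectors at the step-1 estimate.  The surplus moments
yield the over-identification statistic `J = N·Q ~ χ²_{m−p}`.

The package targets applied longitudinal analyses — e.g. multi-wave health
surveys of ageing cohorts, where one asks whether exercise or mobility
measured years ago still shifts today's odds of good health — and ships a
synthetic-data generator so the whole pipeline is testable without any
restricted survey download.

## Worked example

```python
import partgmm as pg

spec = pg.SyntheticSpec(n_subjects=500, seed=3)   # N=500, T=4, J=2, known truth
data = pg.generate_panel(spec)
model = pg.PartitionedGMM().fit(data)             # screen moments + two-step GMM
print(model.summary())
```

```
Cross sectional
Covariate          OR            95% CI        p
(Intercept)      1.53      [1.22, 1.92]   <0.001
x_fixed          1.67      [1.36, 2.06]   <0.001
x1               2.48      [1.98, 3.10]   <0.001
x2               0.55      [0.44, 0.69]   <0.001

One time period lag
Covariate          OR            95% CI        p
x1               1.22      [0.96, 1.55]     0.11
x2               1.55      [1.21, 1.99]   <0.001

Two time period lag
Covariate          OR            95% CI        p
x1               1.10      [0.82, 1.46]     0.52
x2               0.86      [0.64, 1.15]     0.30

Three time period lag
Covariate          OR            95% CI        p
x1               1.58      [1.08, 2.31]     0.02
x2               1.01      [0.68, 1.49]     0.97

N = 500, p = 10, m = 22, J = 6.532 (df 12), objective = 1.306e-02
```

The generator's true odds ratios here are exp(1.0)=2.72 and exp(−0.6)=0.55
cross-sectionally, exp(0.4)=1.49 and exp(0.25)=1.28 at lag 1, and so on;
at N=500 the fit recovers them within sampling error.  `m = 22` means all
12 screened extra moments were declared valid (the covariates are exogenous
by construction), and the J statistic 6.53 on 12 df (p ≈ 0.89) correctly
fails to reject the moment set.  Fitted attributes (`coef_`, `bse_`,
`conf_int_`, `moment_test_`, `j_stat_`, `results_`, …) follow sklearn
conventions; `PartitionedGMM` supports `get_params`/`set_params`/`clone`
and `predict_proba`.

The same pipeline is available from a shell:

```bash
partgmm simulate --out panel.csv            # default synthetic spec
partgmm fit --input panel.csv --config cfg.yaml --out-dir out/
partgmm describe --input panel.csv --config cfg.yaml
```

where `cfg.yaml` maps columns, e.g.
`{id: id, wave: wave, outcome: y, fixed: [x_fixed], time_dependent: [x1, x2]}`.

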