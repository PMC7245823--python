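# Methods

## Model

For subject *i* (*i* = 1..N) at wave *t* (*t* = 1..T), with binary outcome
`y_it`, time-independent covariates `x_F` and time-dependent covariates
`x_ijt` (*j* = 1..J), the marginal (population-averaged) model is

```
logit(μ_it) = β₀ + β_Fᵀ x_F + Σ_j Σ_{k=0}^{min(t−1, K)} β_j^[k] · x_ij(t−k)
```

`β_j^[0]` is the cross-sectional effect, `β_j^[k]` the lag-*k* effect; K
(`max_lag`, default T−1) truncates the partition.  Outcomes of different
subjects are independent; within-subject dependence is left unspecified
(no random effects) — the coefficients describe population-averaged odds.

The design matrix stacks, per subject, T rows: an intercept column, the
repeated fixed covariates, and per covariate a lower-triangular block whose
lag-*k* column holds `x_ij(t−k)` for rows with t > k and 0 otherwise.  With
all lags the matrix is NT × (1 + F + J·T).  Column order (intercept, fixed,
then lag-ascending blocks per covariate) is fixed so coefficient vectors
are comparable across runs.  An optional wave-indicator block absorbs
secular drift in prevalence; the default omits it, keeping a single β₀.

## Estimation

**Step 1 (identification).**  Each design column *c* contributes the moment
`(1/N) Σ_i Σ_t z_itc (y_it − μ_it) = 0`.  Solving these p equations is
pooled logistic regression under working independence, computed by IRLS
(damped Newton, step-cap 5 on the max component; convergence when the step
max-norm falls below 1e−10).  Divergence with a vanishing weight is
reported as separation, naming the runaway column.  Before fitting, a
greedy Gram–Schmidt screen (tolerance 1e−8 relative) drops all-zero and
collinear columns; columns are scanned in lag-ascending order so that when
a dependency exists the later lag is dropped, deterministically.  Dropped
coefficients are reported as absent (dashes in the rendered table).

**Moment screening.**  Beyond the identifying pairings, each (covariate
wave *s*, outcome wave *t*) product-moment is a candidate over-identifying
condition.  Candidates are the pairs not already contained in a baseline
pairing: t < s always, plus t − s > K when the partition is truncated.
These are exactly the conditions that fail when a covariate responds to
past outcomes (feedback/endogeneity).  For each candidate the Pearson
correlation across subjects between `x_ijs` and the standardized (Pearson)
residual `e_it = (y_it − μ̂_it)/√(μ̂_it(1−μ̂_it))`, evaluated at the step-1
estimate, is tested two-sided with the Fisher-z statistic
`z = atanh(r)·√(N−3)`; the candidate is kept when p ≥ α (default α = 0.05,
no multiplicity adjustment; Bonferroni available).  Screening is not
iterated with re-estimation, avoiding a selection/estimation feedback loop.
Zero-variance candidates are excluded with a warning.  Decisions are a
function of (r, N, α) only, hence invariant to subject order.

**Step 2 (efficiency).**  With the selected m ≥ p moments, per-subject
moment vectors `g_i(β)` stack the baseline column sums and the extra
per-pair products.  The weight is `W = S⁻¹`, `S = (1/N) Σ g_i g_iᵀ` at the
step-1 estimate, inverted by symmetric pseudo-inverse with a ridge
`λ = 1e−8·tr(S)/m` added first when the condition number exceeds 1e12.
`Q(β) = ḡᵀWḡ` is minimized by Gauss–Newton — direction
`−(GᵀWG)⁻¹GᵀWḡ` with `G = ∂ḡ/∂β` computed analytically
(`−(1/N)ZᵀDZ` for the baseline block, D = diag(μ(1−μ)), and the matching
single-wave rows for extras) — under a halving line search that only
accepts descent steps, so the objective is monotone across accepted steps.
Convergence: gradient norm < 1e−8 or step norm < 1e−10, budget 200
iterations.  The analytic Jacobian is verified against central finite
differences in the test suite.

**Inference.**  `vcov = (GᵀWG)⁻¹/N`; for the just-identified case this is
the robust sandwich of the pooled estimating equations.  Per coefficient:
Wald z against the normal reference, OR = exp(β), 95% CI
exp(β ± 1.96·se) with the 1.96 critical value fixed by reporting
convention.  Over-identification: `J = N·Q(β̂) ~ χ²_{m−p}`; J is ~0 with
df 0 when m = p.

## Synthetic-data generator

`SyntheticSpec` defaults define the reference simulation conditions:
N = 2000 subjects, T = 4 waves, J = 2 binary covariates, one binary fixed
covariate (prevalence 0.5, β_F = 0.3), intercept β₀ = 0.5, true lag
coefficients

```
x1: 1.0 (lag 0), 0.4, 0.2, 0.3          x2: −0.6 (lag 0), 0.25, 0.0, 0.0
```

— moderate, realistically decaying lagged effects with a sparse lag-3
(only x1), the pattern typical of ageing-cohort risk factors.  Covariates
follow stationary first-order Markov chains (initial prevalence 0.5,
p01 = 0.3, p11 = 0.7 → wave-1 autocorrelation 0.4), giving the
within-subject persistence real survey covariates show.

Outcomes: with ρ = 0 (default), `y_it ~ Bernoulli(μ_it)` independently
across waves given the covariates, so the fitted marginal model is exactly
true — the cleanest surface for parameter-recovery checks.  With ρ > 0 a
Gaussian copula induces exchangeable within-subject dependence: latent
`z_it = √ρ·a_i + √(1−ρ)·b_it` thresholded at `Φ⁻¹(μ_it)`, which preserves
every marginal mean exactly (verified to 3 MC standard errors in the
suite).  Feedback enters the covariate process, not the outcome model:
the transition log-odds of covariate j at wave t are shifted by
`feedback_j · y_{i,t−1}`, the canonical mechanism by which a
time-dependent covariate becomes non-exogenous; generation interleaves
covariates and outcomes in that case.  All output is a pure function of
the spec including its seed.

What the generator does **not** emulate: attrition/mortality, survey
weights and stratification, unequal calendar spacing between waves (lags
are counted in waves), measurement error, and covariate dependence beyond
first-order Markov.  Passing tests therefore demonstrate correctness of
the estimator under its own assumptions, not robustness to those survey
features.

### Demonstration fixture

`make_clhls_like_fixture()` builds a deterministic 2021-subject × 4-wave
panel with six binary covariates and one fixed covariate, its per-wave
prevalences tuned to declared targets (a declining health-like outcome from
~95% to ~87%, covariates from ~20% to ~99.7%).  Constant Markov transitions
cannot track non-monotone prevalence paths, so the fixture calibrates each
wave's transition probabilities to the realized previous-wave prevalence
with a fixed persistence gap (p11 − p01 = 0.35, clamped), and solves a
per-wave intercept (Brent's method) so the outcome mean hits its target
given the realized covariates; outcome correlation ρ = 0.3.  It is labelled
synthetic throughout: a stand-in with survey-like margins, not survey data.

## Simulation sizes

The statistical checks in the test suite use: parameter recovery — 200
replications of the default N = 2000 spec (seeds 1..200), asserting
per-coefficient absolute Monte-Carlo bias < 0.05 and pooled 95% CI
coverage in [0.92, 0.97]; moment-screen size — 1000 replications at
N = 500, each candidate's rejection rate inside the exact binomial 99%
band around α; power — 300 replications with feedback shift 1.0; J-test
calibration — 500 replications at N = 1500 (a size at which the χ²₁₂
reference is plausible) with all 12 extra moments valid by construction.
`scripts/acceptance.py` recomputes the same quantities at 150/400/200/300
replications.  Coverage is asserted pooled over coefficients because at
200 replications the per-coefficient binomial standard error (≈1.5%) is
of the same order as the band's width; the per-coefficient rates are still
computed and reported in the failure message.

## Numerical choices and edge cases

- Mean probabilities within 1e−12 of 0/1 make standardized residuals
  undefined and raise a degenerate-fit error (separation surfaced upstream).
- The Fisher-z test requires N > 3 and non-degenerate inputs; r is clipped
  away from ±1 by 1e−15 before atanh.
- Unbalanced panels are rejected by default, naming the first offending
  subject; `drop_incomplete` removes such subjects with a logged count.
  Missing values are rejected — no imputation.
- Wave labels (e.g. calendar years) are mapped ordinally to 1..T.
- Binary covariates are the tested default; continuous time-dependent
  covariates are supported (scaling equivariance is covered by a test).
- p-values print as "<0.001" below that threshold; full precision is kept
  in the CSV artifacts.

## Open design choices made

- Two-step GMM (not iterated or continuously-updating): standard in this
  methodology and cheapest; the optimizer is Gauss–Newton with monotone
  line search rather than a generic quasi-Newton, so the stated tolerances
  are enforced exactly.
- The validity screen tests each (s, t) pair separately rather than pooling
  across equal separations; pooling is a possible variant but per-pair
  decisions compose directly with the per-pair extra moments.
- A single intercept is the default even though wave prevalences may
  drift; `wave_effects=True` provides wave indicators when drift matters
  (the fixture uses the per-wave-intercept analogue internally).
- Small-sample refinements (e.g. Windmeijer-type corrections) are out of
  scope; at the default simulation sizes the uncorrected two-step
  intervals already attain nominal coverage.
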