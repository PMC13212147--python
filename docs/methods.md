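# Methods

`hfpmediate` implements a multiple-mediation analysis of a cluster-randomized
homestead food production (HFP) trial: it quantifies how much of an
intervention's effect on women's dietary diversity travels through home
gardening, poultry production, nutrition knowledge and market activity. This
note records the model, its assumptions, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## The path model

Variables are observed at the woman level. The outcome Y is the mean dietary
diversity score (DDS, 0–10 food groups) over up to four survey rounds (or the
proportion of rounds meeting minimum dietary diversity, MDD ≥ 5 groups).
Treatment T is the settlement-level intervention indicator. Mediators M are
crop species richness, garden-practices score, poultry owned, eggs produced,
food-group knowledge, diet-diversity knowledge, and the market-activity score
(0–3). Baseline covariates X (religion, wealth-quintile indicators,
log-transformed land sizes, baseline crop richness, baseline market score,
education, six empowerment scores, baseline DDS) enter every equation as
mediator–outcome confounders.

The system is recursive ("a/b/d" paths):

    M_j      = α_j + a_j T + Γ_j X + ζ_j                       (j = 1..6)
    market   = α_m + a_m T + Σ_j d_j M_j + Γ_m X + ζ_m
    Y        = α_y + c' T + Σ_j b_j M_j + b_m market + Γ_y X + ζ_y

Residuals are correlated within the garden/poultry block and within the
knowledge pair; all other residual covariances are fixed at zero. Because the
directed graph is acyclic, B (the endogenous coefficient matrix) is strictly
lower triangular and the reduced form is η = (I−B)⁻¹(α + Γx + ζ).

Under linearity, no exposure–mediator interaction and no unmeasured
mediator–outcome confounding, indirect effects are products of coefficients:
a_j·b_j through mediator j, a_j·d_j·b_m sequentially through the market, and
a_m·b_m through market activity alone. They add: the total effect equals the
direct effect c′ plus the total indirect effect, and also equals the
reduced-form T coefficient — the decomposition code asserts this identity on
every fit.

## Estimation: FIML

Parameters are estimated by full-information maximum likelihood: each woman
contributes the Gaussian log-density of her *observed* sub-vector, valid under
missing-at-random. Rows are grouped by missing-data pattern; the grouped
likelihood is contractually identical to casewise evaluation (tested).

Two exogenous-handling modes exist:

* **fixed** (conditional): T and X are conditioned on; requires complete
  exogenous data. The modelled vector is η | x.
* **saturated**: (T, X) get free jointly-normal moments (μx, Σxx), so
  covariates may themselves have holes.

Both modes agree to 1e-4 on complete data (tested). The default is *auto*:
fixed when the exogenous columns are complete, saturated otherwise — the
saturated moments are only needed when covariates have holes, and the fixed
mode is substantially cheaper at identical estimates.

Residual-covariance blocks (and Σxx) are parameterized by Cholesky factors
with log-transformed diagonals, so every optimizer proposal is positive
definite by construction. Gradients are fully analytic: the casewise
likelihood is differentiated with respect to the implied moments and chained
through the moment structure; the chain is verified against finite
differences in the test suite. Optimization runs L-BFGS from equation-wise
complete-case least-squares starts (for this block-recursive specification
with identical regressors per residual block, complete-data ML *equals*
equation-wise OLS, so complete-data fits converge immediately), followed by
Newton polishing with a finite-difference Hessian of the analytic gradient.
Convergence requires max |gradient| < 1e-5; non-convergence is reported with
the best-found parameters and gradient norm, never silently.

## Cluster-robust inference

The trial randomized settlements, not women. The coefficient covariance is
the sandwich A⁻¹BA⁻¹ with A the observed information (Hessian of the negative
log-likelihood at the optimum) and B the sum over settlements of outer
products of within-settlement summed score vectors. With no cluster column
the estimator degenerates to the per-row heteroskedasticity-robust sandwich
(tested against a numeric per-row oracle). A small-sample factor G/(G−1) is
available but off by default. Wald tests are two-sided normal.

## Fit indices

χ² = 2(ℓ_sat − ℓ_model) against the saturated model on the same missing-data
patterns. The saturated log-likelihood comes from an EM fit of the
unrestricted multivariate normal; in fixed mode the conditional saturated
log-likelihood is the joint saturated value minus the closed-form marginal
log-likelihood of the (complete) exogenous block, which is exact because the
joint likelihood factorizes when x is observed everywhere. The baseline
(independence) model frees every modelled variable's mean and variance with
all covariances zero — recorded explicitly because the Tucker–Lewis index is
sensitive to this convention. CFI, TLI and RMSEA use the standard
likelihood-ratio formulas; when χ² ≤ df, RMSEA is reported as 0, and at
df = 0 the TLI is undefined (reported as NaN) while CFI = 1.

Degrees of freedom are moment counts minus free parameters. For the default
specification the model's df is 8 in either exogenous mode (the only
restrictions relative to the saturated conditional model are the excluded
residual covariances).

## Effect decomposition and Monte Carlo CIs

Point estimates of all 14 individual effects (6 a·b products, 6 a·d·b market
legs, market-alone, and the summed market legs), 7 domain sums (garden,
poultry, knowledge, each with and without market legs, plus market activity),
direct, total indirect and total are exact products/sums of fitted
coefficients. Confidence intervals draw coefficient vectors from a
multivariate normal centered at the estimates with the cluster-robust
covariance (the naive covariance is available by flag), evaluate every effect
expression per draw, and report 2.5th/97.5th percentiles. Percentile rather
than symmetric intervals are used because products of normals are skewed.
Draws use only the sub-covariance of the coefficients entering effect
expressions; 10,000 repetitions by default, seeded. A non-positive-semidefinite
covariance aborts with a diagnostic rather than being silently repaired.

Proportions mediated are each effect divided by the total effect, as a
percent; they are computed from unrounded estimates, so recomputing them from
3-decimal rounded tables can differ by ±0.1 %. When |total| is below 1e-8 the
proportions are refused as unstable.

## Total-effect models

Per-indicator random-intercept (settlement) linear models via statsmodels
MixedLM; ML by default so log-likelihoods are comparable across fixed-effect
sets, REML by flag. Outcome models adjust for baseline DDS, the crop model
for baseline crop richness, the market model for baseline market score. Wald
95% intervals (β ± 1.96 se). A boundary estimate σᵤ² = 0 is flagged, not an
error.

## The synthetic-data generator

The generator emulates the trial's design: 96 settlements randomized 1:1
(assignment independent of covariates), ~27 women per settlement (Poisson
sizes; n ≈ 2,600), baseline covariates drawn to match the trial's descriptive
table (e.g. baseline DDS 3.9 ± 1.35, two-thirds Muslim households), mediators
and outcome generated from the structural equations above with settlement
random effects in every equation, and MCAR missingness: the number of
observed diet rounds follows the reported (75, 12, 5, 8)% pattern over
(4, 3, 2, 1) rounds, and per-mediator missingness rates are derived from the
reported per-indicator sample sizes (e.g. 32.4% for food-group knowledge,
whose assessment was cut short).

The default *true* path coefficients are the published ones: a-paths from the
total-effect table (5.4, 4.8, 1.0, 1.7, 0.6, 0.4, 0.3) and b/d-paths
back-solved so each product a_j·b_j and a_j·d_j·b_m equals the corresponding
published component. The implied true total indirect effect is 0.433 and the
total 0.423, exactly. All derived defaults live in
`src/hfpmediate/defaults.yaml`, not in code. Structural intercepts are solved
so that implied control-arm means hit the published control means.

Deliberate departures from realism, and why:

* **No truncation of DDS to [0, 10] by default.** The estimand is the linear
  path system; clamping would attenuate the configured effects and break
  exact recovery. A `discretize_dds` flag rounds per-round scores to integer
  0–10 and emits food-group indicators, with the documented attenuation.
* **Round-level noise.** Per-round DDS is the woman-level structural value
  plus independent noise (sd 1.0), so observed woman means are unbiased for
  the structural outcome but mildly heteroskedastic in the number of observed
  rounds; point estimates remain consistent and the cluster-robust sandwich
  covers the inference.
* **ICC.** The trial reports no intraclass correlations; the default 0.07 per
  equation is a conventional community-trial figure, is configurable, and is
  *not* an estimate of the trial's ICC. The outcome's marginal ICC exceeds
  the per-equation value because cluster effects propagate through mediators.
* **Residual correlations** (0.2 within the garden/poultry block, 0.3 for the
  knowledge pair) and covariate loadings are plausible round figures, chosen
  once; they matter for realism, not for the identities being tested.
* **MCAR, not MAR.** FIML assumes MAR; MCAR satisfies it trivially. A
  MAR-on-baseline stress option can be emulated by editing the config.

Consequently, passing tests show that the pipeline recovers the truth of a
linear-Gaussian, MAR world with the published effect sizes — they do not
validate linearity, no-interaction or no-unmeasured-confounding in any real
dataset.

## Scale of the shipped simulations

Parameter-recovery and interval-coverage checks run 100 replicates at 40
settlements × ~15 women (about a quarter of the trial's size), with
2,000-draw Monte Carlo intervals. These sizes give Monte Carlo standard
errors small enough to detect meaningful bias (SE of the mean total indirect
≈ 0.01) while keeping a full evaluation run to minutes; the full-scale
configuration remains the generator default for interactive use.

## Known limitations

* Categorical covariates (religion, wealth quintiles) are treated as numeric
  columns under the joint-normality approximation in saturated mode — the
  standard SEM practice, logged as a caveat.
* The MDD-proportion outcome is modelled linearly; fitted values are not
  constrained to [0, 1] (checked on synthetic data, where the implied mean
  stays inside the unit interval).
* No latent variables, ordinal link, multiple imputation or bootstrap CIs;
  the estimator is the FIML path model with Monte Carlo intervals.
* Stratified analyses drop the stratifier from the covariate set and fit each
  stratum independently; no pooling or interaction tests.
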