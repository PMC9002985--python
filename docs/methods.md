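# Methods

## Structural model and estimand

The analysis unit is the adult offspring, clustered by parent (family).
Per parental line (paternal/maternal) and offspring-sex group, the model is
a serial two-mediator linear system on a latent scale: a probit equation
for the offspring's prepubertal overweight (latent response M₁\* with
threshold 0 and residual variance fixed at 1 — the "theta"-style
identification), a linear equation for adult height (cm) that regresses on
the *latent* M₁\*, and linear outcome equations (FEV₁/FVC in mL as
correlated parallel outcomes, or their ratio ×100 as a single outcome).
Exposure enters as two dummies against the never-overweight reference.
Parental education confounds the mediator equations; education, age and
smoking adjust the outcome equations. No exposure–mediator interactions are
modelled, so the counterfactual natural direct and path-specific indirect
effects reduce to exact path products and the four components sum to the
reduced-form total identically. The sons − daughters difference Δ of every
component summarises moderated mediation. The multi-group fits share
nothing across groups (no equality constraints), and the outcome residual
covariance is estimated per group.

Age enters linearly and uncentred; covariates never interact with exposure.
Study-centre structure is not modelled.

## Likelihood and optimisation

Conditional on covariates, (M₁\*, M₂, Y) is jointly Gaussian, so the
latent residual ε₁ marginalises in closed form: with V = (M₂, Y),

  f(M₁, V | X) = N(V; μ_V, Ω) · Φ(q (z_m + m)/τ),

where z_m is the mediator linear predictor, (m, τ²) are the conditional
moments of ε₁ given V, and q = ±1 encodes the observed threshold side. The
observed-data log-likelihood is therefore evaluated exactly — no quadrature
or simulation — and the same reduction yields the truncated-normal
conditional moments of M₁\* used by the EM algorithm (computed with
`erfcx`-based Mills ratios and `log_ndtr` for tail stability).

EM has closed-form M-steps: given E[M₁\*] and E[M₁\*²] per offspring, each
equation block updates by (multivariate) least squares on expected
sufficient statistics; the mediator equation's residual variance stays
fixed at 1. EM ascends the likelihood monotonically. Because convergence is
linear and slows along weakly identified directions (the latent paths d and
b₁ when the mediator is rare), each EM cycle also tries a squared-
extrapolation (SQUAREM-style) candidate in an unconstrained
parameterisation (log residual sd, log-Cholesky covariance); the candidate
is kept only when it improves the likelihood, preserving monotonicity.
Convergence is a relative log-likelihood change below 1e-9 (1e-8 for
bootstrap refits); the iteration cap is 500 evaluations for full fits
(1,500 for refits), with three jittered restarts on non-convergence, best
likelihood winning. Starting values come from a probit fit of the binary
mediator plus plug-in least squares with the inverse-Mills conditional mean
substituted for M₁\*.

One numerical consequence worth knowing: when d and b₁ carry little
information the likelihood has a nearly flat ridge, and the maximiser's
location along that ridge is only determined to ~1–2% at double precision
(a log-likelihood change of 1e-8 corresponds to a visible parameter move).
Estimates of those coefficients therefore wobble at that level across
numerically equivalent runs (e.g. after an outcome-unit change); the wobble
is far inside their statistical uncertainty.

`oracle_fit` estimates the same parameters by ordinary least
squares/projection treating the generator's latent column as observed; it
is the independent consistent estimator used to validate the FIML path.

## Synthetic cohort generator

The generator draws families from exactly the structural model above:
per parent, education, exposure category and a family size on {1, 2, 3}
(probabilities 0.70/0.25/0.05, ≈1.36 offspring/parent, matching the
published cluster multiplicity); per offspring, sex, age (uniform over the
published range), smoking by sex, then M₁\*, height and bivariate-normal
outcomes. Offspring of one parent share exposure and education; all
residuals are independent across offspring, so the likelihood's
conditional-independence assumption holds by construction.

Defaults are the published cohort conditions: exposure prevalences
(paternal 12.0/10.4/77.6%, maternal 25.0/22.9/52.1%), education, sex ratio,
age ranges, smoking, per-sex height and lung-function means/sds, offspring
overweight prevalences, and the published structural path estimates per
line × sex. Quantities the source tables do not pin down were chosen once
at physiologically plausible values and are documented in the code:
education effects on the latent mediator (+0.25) and height (−1.0 cm),
outcome covariate coefficients (age −25/−20 mL·yr⁻¹, smoking −80/−60 mL,
education −40/−50 mL for FEV₁/FVC), outcome residual correlation 0.7, and
a bronchodilator response (+130/−20 mL with 80 mL noise, available for 95%
of offspring) so post-bronchodilator reruns have data. Equation intercepts
and residual scales are then *solved in closed form* against the marginal
targets: everything is linear-Gaussian within discrete covariate cells, so
the implied mean and variance of each variable is an exact finite mixture
expression, and the residual variances absorb whatever the structural paths
do not explain. A configuration whose paths explain more variance than a
target sd allows is rejected with an explicit error.

What the generator does *not* emulate: genetic/assortative height
transmission, informative family size, missingness mechanisms (records are
complete by construction), measurement error in silhouette recall, centre
heterogeneity, and any exposure–sex dependence. Passing tests therefore
certify the estimation machinery under the model's own assumptions, not
robustness to the ways real cohort data violate them.

## Cluster bootstrap

Parents are resampled with replacement to the original parent count within
a line; a drawn parent contributes all offspring, duplicated parents get
distinct synthetic cluster ids, and sex groups are re-formed per resample.
Each resample refits both groups by EM warm-started at the full-sample
estimates; refits that fail or do not converge are dropped and counted,
with a hard error below 95% success. Intervals are plain percentile
intervals (linear interpolation between order statistics, no bias
correction or acceleration) of the per-resample effect distributions; Δ
intervals come from per-resample sons − daughters differences.
Significance = interval excludes zero, boundary inclusive. The shipped
pipeline default is 10,000 resamples; validation simulations in the test
suite use 100–500.

A property surfaced by the null coverage simulation (200 replicate null
cohorts of 2,000 families, 200 resamples each): intervals for the
height-mediated pathway are essentially nominal (94–96.5% coverage of
zero), but intervals for *products involving the probit path* (a·b₁,
a·d·b₂) are conservative — up to ~99% coverage — whenever both factors have
signal-to-noise near one. The bootstrap spread of each factor is calibrated
(bootstrap sd / sampling sd ≈ 0.99 for the probit path); the inflation is a
property of the product itself, whose resampled variance adds an
â²·var(b̂₁) term with E[â²] equal to the sampling variance of â under the
null. This is the familiar conservativeness of percentile intervals for
mediated-effect products; it makes significance calls for those pathways
err on the safe side.

## Unmeasured-confounder sensitivity module

A deliberately simplified single-exposure/single-mediator/single-outcome
framework: one or two confounders U ~ N(0, 0.001) act simultaneously on the
binary exposure (through a probit — configurable to logit — latent scale),
the mediator and the outcome with a common coefficient from the grid
0, 1, 3, 5, 7, 9. Outcomes are in decilitres; mediator and outcome noise is
unit variance. Each of the simulation runs (default 1,000; the acceptance
check uses 200) is analysed twice — adjusting for U and omitting it — with
a product-of-coefficients mediation fit and quasi-Bayesian percentile
intervals from 1,000 Monte-Carlo coefficient draws. The with/without
analyses share common random numbers (one standard-normal panel drawn at
the full with-U width), so a disagreement reflects the confounder
adjustment rather than Monte-Carlo noise. "Results match" is operationalised
as agreement of the significance conclusions for both the direct and the
indirect effect — the strictest natural reading, recorded in the output
metadata. Reported aggregates are the match proportion and the absolute
difference of the run-averaged NDE and NIE estimates. Base coefficients
default to a paternal-line sons' configuration (exposure prevalence 0.12,
E→M −0.53, M→O 2.7 dL, direct −1.6 dL, n = 197 subjects per run) and can be
derived from a fitted model via `scenario_from_paths`.

## Data handling

Reading is complete-case per analysis: rows failing completeness or
plausibility checks (age < 18, height outside 120–230 cm, lung volumes
outside 500–9,000 mL, missing key variables) are dropped with one logged
count per reason; no imputation. Post-bronchodilator values are kept only
as complete pairs. Silhouette scores (1–9) code overweight at ≥5 for males
and ≥4 for females; exposure is overweight before puberty (age 8 and/or
puberty), at 30 only, or never. Pre-coded flags win over silhouette scores
when both are present (with a warning). Booleans serialise as 0/1 and enums
as lowercase strings, making file round-trips value-exact. Summary
prevalences round half-away-from-zero to one decimal. Offspring with
inconsistent silhouette reports across stages are not specially handled
(validation only), since no principled rule is available.

## Problem sizes used in validation

Parameter recovery and FIML/oracle agreement run on one 50,000-family
synthetic cohort with 100-resample cluster-bootstrap standard errors; the
null coverage simulation uses 200 replicate cohorts of 2,000 families with
200 resamples each; the sensitivity null check uses 200 runs of 197
subjects; additivity is checked on 1,000 random coefficient sets. These
sizes were chosen so the full suite runs on a single desktop CPU while
keeping Monte-Carlo error well inside each check's tolerance.

## Known limitations

* Standard errors are bootstrap-only by design; no analytic (sandwich or
  delta-method) inference is provided.
* The percentile-bootstrap conservativeness for probit-path products
  (above) means low-powered indirect pathways are under-called rather than
  over-called.
* The FEV₁/FVC-ratio variant treats the ratio as a linear-Gaussian outcome,
  which is an approximation (the generator produces the ratio as a quotient
  of correlated normals).
* The sensitivity framework intentionally collapses the serial two-mediator
  chain to one mediator, mirroring its single-mediator design; its
  conclusions about unmeasured confounding do not automatically transfer to
  the serial pathways.
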