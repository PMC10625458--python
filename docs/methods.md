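# Methods

## Model and estimation

The outcome model throughout is the Cox proportional-hazards model
h(t | x) = h0(t)·exp(β′x) for right-censored follow-up, estimated by
maximizing the Breslow partial log-likelihood

    l(β) = Σ_i δ_i [ β′x_i − ln Σ_{l ∈ R(t_i)} exp(β′x_l) ],

with R(t) the risk set at t. The fitter is a damped Newton–Raphson: plain
Newton steps from β = 0, with Levenberg–Marquardt ridge damping plus step
halving engaged only when a step fails to increase the log-likelihood.
Convergence requires max |U(β)| < 1e-8 or a relative log-likelihood change
below 1e-9, within 50 iterations; a non-converged fit is returned flagged,
never silently. Constant or collinear covariate columns raise an error
naming the offending column (rank check on the centered design). Ties are
handled with the Breslow approximation everywhere, because it is the
convention under which the augmented-data Poisson model reproduces the
partial-likelihood MLE exactly. Times are study-entry relative; left
truncation, time-dependent covariates, stratification and Efron ties are
out of scope.

## Baseline hazard conventions

Two estimators of the cumulative baseline hazard are provided, both step
functions that are 0 before the first event time:

* `"km"` (default of `baseline_cumhaz`): H0(t) = −log Ŝ0(t) with the
  Kaplan–Meier-type factors Ŝ0 = Π (1 − d_i / Σ_{R(t_i)} exp(η̂_l)), the
  convention used by the R survival package's survfit output.
* `"breslow"`: the Nelson–Aalen-type increments d_i / Σ_{R(t_i)} exp(η̂_l).

Degenerate edge: at the last event time the KM factor's argument
d/Σexp(η̂) can reach or exceed 1 (sole subject at risk with η̂ < 0), where
−log(1−h) is undefined; the Breslow increment is substituted for that time.

Residuals default to the **Breslow** baseline, for two reasons: it is the
standard software convention for martingale residuals, and it is the only
choice under which the martingale residuals sum exactly to zero at the MLE
(with the KM form, Σ r_CS exceeds the event count by ≈ Σ h²/2, a visible
O(log n) excess). The KM form remains available via
`compute_residuals(..., baseline_method="km")`. A related consequence:
predicted survival probabilities are exactly invariant to covariate
centering under the Breslow estimator and only approximately under KM.

## Residuals

For subject i, r_CS,i = Ĥ0(t_i)·exp(β̂′x_i); martingale r_M,i = δ_i −
r_CS,i; deviance r_D,i = sign(r_M,i)·sqrt(−2[r_M,i + δ_i·ln r_CS,i]), with
the log term dropped for censored subjects. Martingale and deviance always
derive from the *unadjusted* Cox–Snell residual. An optional censoring
adjustment (add 1 or ln 2 to censored subjects' r_CS) compensates for their
unobserved remaining hazard; it defaults to off, since the screening offset
uses the raw residuals.

## The CS-adjusted Poisson screen

Stage one fits the k common covariates once and stores r_CS. Stage two
fits, per SNP, the Poisson GLM ln μ = β0 + β1·SNP + ln(r_CS) — the offset
enters with coefficient fixed at 1, so if the residuals are truly
unit-exponential the model is a censored-exponential likelihood and
exp(β1) estimates the incidence-density ratio, approximating the SNP
hazard ratio from the full (k+1)-covariate Cox fit. Statistical contract
choices:

* **Zero residuals.** Subjects censored before the first event time have
  r_CS = 0 and an undefined offset. Default policy `floor` adds 1e-10 to
  exactly-zero residuals (they stay in the risk pool with essentially no
  exposure); `exclude` drops them; `ln2` adds ln 2 to all censored
  residuals. Floor is the default because exclusion discards genuinely
  at-risk subjects and ln2 perturbs every censored residual.
* **Missing genotypes** are handled per SNP by complete-case masking
  (stage one is shared, so only stage two shrinks); `n_used` is recorded.
* **P-values** are two-sided Wald-normal for all engines, with no
  multiplicity correction: the workflow screens at fixed thresholds
  (0.001/0.002 conventions) rather than controlling FDR.
* A SNP group with zero events yields a wide-SE flag rather than a drop;
  monomorphic-after-masking SNPs are reported with status `degenerate`, so
  result row counts are always predictable (SNPs × passes × methods).

The deviance screen is the OLS slope of r_D on the SNP indicator — exactly
the difference of group mean residuals — z-tested. It needs no iterations
at all but agrees less well with the Cox gold standard, increasingly so
under heavy censoring; the package treats it as a triage tool and measures
its discordance explicitly.

## Augmented-data Poisson equivalence

With T distinct untied event times, block r contains the event case at
t_r (status 1) and every subject still at risk (status 0). A Poisson GLM
of status on the covariates, an intercept and T−1 block indicators (block
1 absorbed into the intercept — the identifiability convention here) has
the same score equations as the Cox partial likelihood, so the covariate
coefficients coincide with the Cox MLE and exp(β0), exp(β0 + β_{k+r})
are the Breslow hazard increments; partial sums rebuild Ĥ0. Tied event
times raise an explicit error (jitter or exclude upstream); a guard
refuses expansions beyond 1e7 rows unless overridden, since the block
table grows as Σ|R(t_i)|. The construction is used as an exactness oracle
for the fitter, not as a production screen.

## Proportional-hazards checking

The PH assumption is tested on the common covariates (not per SNP — at
screening scale that would defeat the purpose, and stage two inherits
stage one's covariate adjustment). Schoenfeld residuals at each event,
scaled by d·I⁻¹, are correlated with a transform of event time — KM rank
1 − Ŝ_KM(t) by default, identity optionally — and each covariate's
p-value comes from the Pearson correlation t-test on d − 2 degrees of
freedom. Fewer than 3 events makes the test non-computable and it is
returned flagged.

## Cross-validation and two-pass coding

Genotypes are coded binary: pass 1 is homozygous-reference vs rest, pass 2
homozygous-alternate vs rest, and the whole screen can run both passes
since the risk-carrying homozygote is unknown. s folds (default 5) are
formed by a seeded permutation into near-equal groups; analysis i refits
stage one and screens on the subjects outside fold i, so residuals are
never reused across folds. A (SNP, pass) is "promising" when p ≤ threshold
(default 0.001) in at least ⌈0.8·s⌉ analyses; the ceiling-with-≥ rule
resolves boundary ties. Raising the threshold can only grow the promising
set.

## Synthetic cohorts

The simulator emulates a discovery cohort: standard-normal covariates with
fixed mixed-sign effects; per-SNP Hardy–Weinberg genotypes at minor-allele
frequencies drawn from a configurable interval (default [0.1, 0.5]); event
times from the PH model via inverse cumulative hazard, H0⁻¹(E/exp(η)) with
E ~ Exp(1), under an exponential or Weibull baseline — the Weibull option
exists because a constant baseline hazard makes the Poisson approximation
trivially good, and a non-constant one stresses it honestly. Causal SNP
effects act on the pass-1 binary coding. Censoring is independent
exponential, its rate found by bisection so that the expected censored
fraction over the drawn latent times matches the target (no rejection
sampling); the realized fraction is stochastic within a few points of the
target. What the generator does *not* emulate: linkage disequilibrium,
population stratification, genotyping error, informative censoring, and
covariate-genotype correlation — so passing tests certify the statistical
machinery under a correctly specified PH world, not robustness to those
real-data features.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to run
comfortably on a single core: equivalence suites use 20 cohorts of n ∈
[10, 60]; the unit-exponential check n = 5000; screening fidelity 500 SNPs
at n = 1000 with k = 10; calibration 1000 null SNPs at n = 1000 plus 150
effect-recovery replicates at n = 2000; the censoring-ordering panel 400
SNPs at 70% censoring. Agreement between the Cox and augmented-Poisson
routes is asserted at 1e-4 (the GLM's own convergence scale), the
partial-likelihood oracle at 1e-6, offset invariance at 1e-8, and the
Nelson–Aalen slope of censored CS residuals within [0.95, 1.05]; the slope
is estimated through the origin on event-time points after trimming the
top 1% of residuals, where the Nelson–Aalen curve is noise-dominated.

## Known limitations

The incidence-density ratio is not the hazard ratio; agreement degrades
as |z| grows, and the screen is a triage device, not an inferential
replacement for the Cox fit on the retained SNPs. Only binary
homozygote-vs-rest coding is supported (no additive/dosage models), no
SNP×SNP interactions, and no relatedness adjustment beyond user-supplied
covariates. The augmented-data route requires untied event times; real
data with heavy ties must be screened directly (Breslow handling) and the
oracle reserved for continuous-time settings.
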