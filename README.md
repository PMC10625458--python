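# snpscreen

Fast two-stage screening of SNP associations with time-to-event outcomes.

## The problem

In a survival GWAS, the standard analysis refits a Cox proportional-hazards
model — the SNP of interest plus the same k clinical covariates — once per
SNP and per outcome. With millions of SNPs, several outcomes, two coding
passes (which homozygote carries the risk is unknown a priori) and s-fold
cross-validation, the iterative (k+1)x(k+1) fitting becomes the bottleneck
of the whole study.

`snpscreen` implements a two-stage shortcut. Stage one fits a single Cox
model h(t) = h0(t)·exp(β′x) to the k common covariates and computes each
subject's Cox–Snell residual

    r_CS,i = Ĥ0(t_i) · exp(β̂′x_i),

which is unit-exponentially distributed (up to censoring) when the model is
correct — so any SNP signal the covariates do not explain is still sitting
in the residual. Stage two tests each binary-coded SNP in a two-parameter
Poisson regression of the event indicator δ with ln(r_CS) as offset,

    ln μ_i = β0 + β1·SNP_i + ln(r_CS,i),

whose exp(β1) is an incidence-density ratio approximating the hazard ratio
the full Cox refit would give, at a fraction of the cost: no data sorting,
no (k+1)x(k+1) matrix inversions per SNP. An even cheaper screen regresses
the deviance residual on the SNP indicator (a closed-form z-test), trading
further speed for noticeably poorer agreement with the Cox gold standard,
especially under heavy censoring.

The package also ships the augmented-data Poisson formulation of the Cox
model (one block per distinct event time), which reproduces the Cox MLE
*exactly* when event times are untied — used here as a built-in correctness
oracle for the fitter and the Breslow baseline hazard — plus Schoenfeld-
residual checks of the proportional-hazards assumption, Bland–Altman and
threshold-discordance diagnostics, s-fold cross-validation with two-pass
homozygote coding, a ground-truth cohort simulator, and PLINK/VCF/CSV I/O.

## Worked example

`examples/01_two_stage_screen.py` simulates 1000 subjects (10 covariates,
~30% censoring) and 200 SNPs, a quarter of them causal with |log HR| in
[0.3, 0.7], then screens every SNP with all three engines:

```
cohort: n=1000, events=679, censored=32.1%

cs_poisson vs cox_full:
  mean |z difference|     = 0.0171 (max 0.1378)
  Bland-Altman 99% limits = [-0.0699, 0.0742], bias 0.00217
  discordant calls at p<=0.002: 1/200

deviance vs cox_full:
  mean |z difference|     = 0.2723 (max 1.0832)
  Bland-Altman 99% limits = [-0.9008, 0.8772], bias -0.01184
  discordant calls at p<=0.002: 2/200
```

Read: the CS-adjusted Poisson screen reproduces the per-SNP Cox z-scores to
about ±0.07 at 99% agreement with negligible bias — screening calls at a
0.002 p-value threshold disagree for 1 SNP in 200 — while the deviance
screen's z-scores wander an order of magnitude further from the gold
standard. `examples/02_poisson_equivalence.py` shows the augmented-Poisson
route matching the Cox coefficient to 2.6e-12 and rebuilding the Breslow
cumulative hazard exactly; `examples/03_cross_validation.py` runs the
5-fold "promising SNP" workflow end to end.

The same pipeline is available from the shell:

```bash
snpscreen simulate --config sim.cfg --out-prefix data/sim --seed 1
snpscreen screen --pheno data/sim.pheno.tsv --geno data/sim \
          --method cs-poisson --coding both --threshold 0.001 \
          --folds 5 --seed 1 --out results.tsv
snpscreen concordance --results-a cox.tsv --results-b poisson.tsv \
          --thresholds 0.001,0.002 --out agreement
```

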