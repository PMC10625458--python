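"""Screen a simulated SNP panel with all three engines and compare them.

Simulates a cohort of 1000 subjects (10 clinical covariates, 30%
censoring) and 200 SNPs of which a quarter carry a true log hazard ratio
between 0.3 and 0.7, then screens every SNP with the gold-standard Cox
fit, the Cox-Snell adjusted Poisson screen and the deviance-residual
regression.
"""

import numpy as np

from snpscreen import bland_altman, discordance_table, run_screen, simulate_cohort
from snpscreen.simulate import SimConfig

cfg = SimConfig(n=1000, k=10, n_snps=200, causal_fraction=0.25,
                effect_range=(0.3, 0.7), target_censoring=0.3, seed=42)
cohort, genotypes, truth = simulate_cohort(cfg)
print(f"cohort: n={cohort.n}, events={cohort.event.sum()}, "
      f"censored={1 - cohort.event.mean():.1%}")

results = run_screen(cohort, genotypes, coding="pass1", threshold=0.001)
z = results.pivot(index="snp_id", columns="method", values="z")
p = results.pivot(index="snp_id", columns="method", values="p")

# how closely does each fast screen track the per-SNP Cox z-score?
for method in ("cs_poisson", "deviance"):
    gap = (z["cox_full"] - z[method]).abs()
    ba = bland_altman(z["cox_full"].to_numpy(), z[method].to_numpy(), level=0.99)
    disc = discordance_table(p["cox_full"].to_numpy(), p[method].to_numpy(), 0.002)
    print(f"\n{method} vs cox_full:")
    print(f"  mean |z difference|     = {gap.mean():.4f} (max {gap.max():.4f})")
    print(f"  Bland-Altman 99% limits = [{ba.lower:.4f}, {ba.upper:.4f}], bias {ba.bias:.5f}")
    print(f"  discordant calls at p<=0.002: {disc.discordant}/{disc.n_pairs}")

n_flagged = int(results[results["method"] == "cs_poisson"]["promising"].sum())
print(f"\nCS-Poisson screen flags {n_flagged} SNPs at p <= 0.001; "
      "small |z| gaps and few discordant calls mean the cheap screen can "
      "replace the per-SNP Cox refit for triage.")
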