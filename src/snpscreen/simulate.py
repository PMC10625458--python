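"""Synthetic cohorts with known ground truth.

Emulates a GWAS discovery cohort with a time-to-event endpoint: standard
normal common covariates, Hardy-Weinberg genotypes at per-SNP minor-allele
frequencies, proportional-hazards event times (exponential or Weibull
baseline) whose linear predictor combines covariate effects with the
log-hazard effects of a configurable causal fraction of SNPs (applied to
the binary pass-1 coding, homozygous-reference vs rest), and independent
exponential censoring calibrated by bisection to hit a target censored
fraction.  A registry of tiny hand-auditable fixtures supports oracle
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screening import GenotypeMatrix
from .survival import CohortData

__all__ = ["SimConfig", "simulate_cohort", "make_fixture", "FIXTURES"]


@dataclass
class SimConfig:
    """Generator settings; defaults sketch a mid-sized discovery cohort."""

    n: int = 1000
    k: int = 10
    n_snps: int = 100
    causal_fraction: float = 0.0
    effect_range: tuple[float, float] = (0.3, 0.7)
    maf_range: tuple[float, float] = (0.1, 0.5)
    baseline: str = "exponential"  # or "weibull"
    baseline_rate: float = 0.1
    weibull_shape: float = 1.5
    weibull_scale: float = 10.0
    target_censoring: float = 0.3
    covariate_effects: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("need n >= 10")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must be in [0,1]")
        if not 0.0 <= self.target_censoring < 1.0:
            raise ValueError("target_censoring must be in [0,1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not all(np.isfinite(self.effect_range)):
            raise ValueError("effect bounds must be finite")
        if self.baseline not in {"exponential", "weibull"}:
            raise ValueError("baseline must be 'exponential' or 'weibull'")
        if self.covariate_effects is None:
            # modest mixed-sign covariate effects, fixed pattern
            signs = np.resize([1.0, -1.0], self.k)
            self.covariate_effects = signs * np.linspace(0.3, 0.1, self.k) if self.k else np.zeros(0)
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if self.covariate_effects.shape != (self.k,):
            raise ValueError("covariate_effects must have length k")


def _inv_cumhaz(u: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Invert the baseline cumulative hazard: t with H0(t) = u."""
    if cfg.baseline == "exponential":
        return u / cfg.baseline_rate
    return cfg.weibull_scale * u ** (1.0 / cfg.weibull_shape)


def _calibrate_censoring(latent: np.ndarray, target: float) -> float:
    """Bisection on the exponential censoring rate c so that the expected
    censored fraction E[1 - exp(-c T)] over the drawn latent event times
    matches the target."""
    if target == 0.0:
        return 0.0

    def frac(c):
        return float(np.mean(-np.expm1(-c * latent)))

    lo, hi = 1e-12, 1.0 / max(np.mean(latent), 1e-12)
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("cannot reach target censoring")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(cfg: SimConfig):
    """Draw (CohortData, GenotypeMatrix, truth table) under the PH model.

    The truth table lists each SNP's true log hazard ratio (0 for
    non-causal SNPs) and its minor-allele frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    X = rng.standard_normal((cfg.n, cfg.k))
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    # HWE: alt-allele count ~ Binomial(2, maf); allele 'alt' is the minor one
    G = rng.binomial(2, mafs[None, :], size=(cfg.n, cfg.n_snps)).astype(np.int8)
    n_causal = int(round(cfg.causal_fraction * cfg.n_snps))
    causal_idx = rng.choice(cfg.n_snps, size=n_causal, replace=False) if n_causal else np.array([], int)
    effects = np.zeros(cfg.n_snps)
    if n_causal:
        mag = rng.uniform(cfg.effect_range[0], cfg.effect_range[1], size=n_causal)
        sign = rng.choice([-1.0, 1.0], size=n_causal)
        effects[causal_idx] = mag * sign
    # pass-1 coding: indicator of homozygous reference (zero alt alleles)
    snp_term = (G == 0).astype(float) @ effects
    eta = X @ cfg.covariate_effects + snp_term
    u = rng.exponential(size=cfg.n) / np.exp(eta)  # H0(T) = E / exp(eta)
    latent = _inv_cumhaz(u, cfg)
    c_rate = _calibrate_censoring(latent, cfg.target_censoring)
    if c_rate > 0.0:
        cens = rng.exponential(scale=1.0 / c_rate, size=cfg.n)
    else:
        cens = np.full(cfg.n, np.inf)
    time = np.minimum(latent, cens)
    event = (latent <= cens).astype(int)
    cohort = CohortData(
        time=time, event=event, covariates=X,
        subject_ids=np.array([f"S{i+1:06d}" for i in range(cfg.n)]),
        covariate_names=[f"x{j+1}" for j in range(cfg.k)],
    )
    snp_ids = [f"snp{j+1:05d}" for j in range(cfg.n_snps)]
    geno = GenotypeMatrix(
        genotypes=G, snp_ids=snp_ids,
        alleles=[("G", "A")] * cfg.n_snps,
        chrom=np.ones(cfg.n_snps, dtype=int),
        pos=np.arange(1, cfg.n_snps + 1) * 1000,
        sample_ids=cohort.subject_ids,
    )
    truth = pd.DataFrame({"snp_id": snp_ids, "true_log_hr": effects, "maf": mafs})
    return cohort, geno, truth


# --- registered hand-auditable fixtures -------------------------------------

def _cox6():
    """6 subjects, distinct times, 4 events, 1 covariate."""
    return CohortData(
        time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        event=np.array([1, 0, 1, 1, 0, 1]),
        covariates=np.array([[0.5], [-1.0], [1.5], [0.0], [2.0], [-0.5]]),
        subject_ids=np.array(["a", "b", "c", "d", "e", "f"]),
        covariate_names=["x1"],
    )


def _aug3():
    """3 subjects, all events at distinct times: blocks of sizes 3, 2, 1."""
    return CohortData(
        time=np.array([1.0, 2.0, 3.0]),
        event=np.array([1, 1, 1]),
        covariates=np.array([[0.0], [1.0], [-1.0]]),
        subject_ids=np.array(["a", "b", "c"]),
    )


def _censor_first():
    """One subject censored before the earliest event time (r_CS = 0)."""
    return CohortData(
        time=np.array([0.5, 1.0, 2.0, 3.0, 4.0]),
        event=np.array([0, 1, 1, 0, 1]),
        covariates=np.array([[0.2], [-0.3], [1.0], [0.4], [-1.2]]),
        subject_ids=np.array(["a", "b", "c", "d", "e"]),
    )


FIXTURES = {"cox6": _cox6, "aug3": _aug3, "censor-first": _censor_first}


def make_fixture(name: str) -> CohortData:
    """Return a registered small cohort by name ('cox6', 'aug3', 'censor-first')."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture '{name}'; available: {sorted(FIXTURES)}") from None
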