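"""Per-SNP association screening engines.

Three engines estimate the association between a binary-coded SNP and a
time-to-event outcome:

* ``cox_full`` — the gold standard: a fresh Cox PH fit of the SNP plus the
  k common covariates for every SNP.
* ``cs_poisson`` — the fast two-stage screen: the common covariates are
  fitted once, and each SNP is then tested in a two-parameter Poisson GLM
  of event status with the log Cox-Snell residual as offset, so the SNP
  coefficient estimates a log incidence-density ratio approximating the
  log hazard ratio.
* ``deviance`` — the fastest screen: ordinary least-squares slope of the
  deviance residual on the SNP indicator, z-tested.

Because which homozygote is the risk genotype is unknown a priori, every
screen can run two coding passes (homozygous-reference vs rest, then
homozygous-alternate vs rest).  s-fold cross-validation repeats the screen
on each leave-one-fold-out subset and calls a SNP promising when its
p-value clears the threshold in a required fraction of folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survival import (
    CohortData,
    NonIdentifiableError,
    compute_residuals,
    fit_cox,
)

__all__ = [
    "GenotypeMatrix",
    "SNPResult",
    "CVConfig",
    "code_snp",
    "screen_cox_full",
    "screen_cs_poisson",
    "screen_deviance",
    "run_screen",
    "crossvalidate",
    "METHODS",
]

METHODS = ("cox_full", "cs_poisson", "deviance")
RESULT_COLUMNS = ["snp_id", "pass", "method", "coef", "se", "z", "p", "n_used", "status"]
MISSING = -1
WIDE_SE = 50.0


@dataclass
class GenotypeMatrix:
    """n x N genotype matrix coded as alt-allele counts.

    Entries: 0 = homozygous reference, 1 = heterozygous, 2 = homozygous
    alternate, -1 = missing (always explicit, never silently zero).
    """

    genotypes: np.ndarray
    snp_ids: list[str]
    alleles: list[tuple[str, str]] = field(default_factory=list)
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.atleast_2d(np.asarray(self.genotypes, dtype=np.int8))
        if not np.isin(self.genotypes, [-1, 0, 1, 2]).all():
            raise ValueError("genotypes must be coded -1 (missing), 0, 1 or 2")
        if len(self.snp_ids) != self.genotypes.shape[1]:
            raise ValueError("snp_ids length must match number of SNP columns")
        if not self.alleles:
            self.alleles = [("A", "G")] * len(self.snp_ids)
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class SNPResult:
    """One screen outcome: SNP x coding pass x method."""

    snp_id: str
    coding_pass: str
    method: str
    coefficient: float
    std_error: float
    z: float
    p: float
    n_used: int
    status: str  # ok | degenerate | nonconverged
    reason: str = ""
    wide_se: bool = False
    intercept: float = math.nan  # populated by the cs_poisson engine

    def as_row(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "pass": self.coding_pass,
            "method": self.method,
            "coef": self.coefficient,
            "se": self.std_error,
            "z": self.z,
            "p": self.p,
            "n_used": self.n_used,
            "status": self.status,
        }


def _degenerate(snp_id, coding_pass, method, n_used, reason) -> SNPResult:
    return SNPResult(snp_id, coding_pass, method, math.nan, math.nan, math.nan, math.nan,
                     n_used, "degenerate", reason)


@dataclass
class CVConfig:
    """s-fold cross-validation settings for the promising-SNP call."""

    s: int = 5
    threshold: float = 0.001
    fold_fraction_required: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 2:
            raise ValueError("need at least 2 folds")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0,1)")
        if not 0.0 < self.fold_fraction_required <= 1.0:
            raise ValueError("fold_fraction_required must be in (0,1]")


def code_snp(genotype_column: np.ndarray, coding_pass: str = "pass1"):
    """Binary-code one SNP column; returns (coded vector, non-missing mask).

    pass1 codes homozygous-reference vs the rest, pass2 homozygous-alternate
    vs the rest (the reverse-coding pass).  Missing entries are masked out,
    excluding the subject for this SNP only.
    """
    g = np.asarray(genotype_column)
    if coding_pass == "pass1":
        coded = (g == 0).astype(float)
    elif coding_pass == "pass2":
        coded = (g == 2).astype(float)
    else:
        raise ValueError("coding_pass must be 'pass1' or 'pass2'")
    mask = g != MISSING
    return coded, mask


def _monomorphic(x: np.ndarray) -> bool:
    return x.size == 0 or np.ptp(x) == 0.0


def screen_cox_full(
    cohort: CohortData, coded: np.ndarray, mask: np.ndarray,
    snp_id: str = "snp", coding_pass: str = "pass1",
) -> SNPResult:
    """Gold-standard screen: Cox PH fit of the SNP plus all common covariates."""
    x = coded[mask]
    n_used = int(mask.sum())
    if _monomorphic(x):
        return _degenerate(snp_id, coding_pass, "cox_full", n_used, "monomorphic after masking")
    design = np.column_stack([cohort.covariates[mask], x])
    names = list(cohort.covariate_names) + [snp_id]
    try:
        sub = CohortData(cohort.time[mask], cohort.event[mask], design,
                         subject_ids=cohort.subject_ids[mask], covariate_names=names)
        fit = fit_cox(sub)
    except (NonIdentifiableError, ValueError) as exc:
        return _degenerate(snp_id, coding_pass, "cox_full", n_used, str(exc))
    coef = float(fit.coefficients[-1])
    se = float(fit.std_errors[-1])
    if not fit.converged or not np.isfinite(se):
        return SNPResult(snp_id, coding_pass, "cox_full", coef, se, math.nan, math.nan,
                         n_used, "nonconverged")
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return SNPResult(snp_id, coding_pass, "cox_full", coef, se, z, p, n_used, "ok",
                     wide_se=se > WIDE_SE)


def _prepare_offset(cs: np.ndarray, event: np.ndarray, policy: str):
    """Resolve zero Cox-Snell residuals before taking logs.

    floor: add a tiny epsilon to exactly-zero residuals; exclude: drop those
    subjects; ln2: add ln 2 to every censored subject's residual.
    Returns (residuals, keep-mask over the input).
    """
    r = cs.astype(float).copy()
    keep = np.ones(r.size, dtype=bool)
    if policy == "floor":
        r[r == 0.0] += 1e-10
    elif policy == "exclude":
        keep = r > 0.0
        r = r[keep]
    elif policy == "ln2":
        r = r + math.log(2.0) * (1.0 - event)
        if np.any(r <= 0):
            r[r == 0.0] += 1e-10
    else:
        raise ValueError("offset policy must be 'floor', 'exclude' or 'ln2'")
    return r, keep


def screen_cs_poisson(
    coded: np.ndarray, mask: np.ndarray, event: np.ndarray, cs_residuals: np.ndarray,
    snp_id: str = "snp", coding_pass: str = "pass1", offset_policy: str = "floor",
) -> SNPResult:
    """Cox-Snell adjusted Poisson screen.

    Fits a Poisson GLM of the event indicator on intercept + SNP with
    ln(r_CS) as offset — i.e. the log residual enters with coefficient fixed
    at 1 — so exp(coefficient) is the incidence-density ratio approximating
    the SNP hazard ratio from the full Cox model.
    """
    x = coded[mask]
    y = event[mask].astype(float)
    r = cs_residuals[mask]
    r, keep = _prepare_offset(r, y, offset_policy)
    x, y = x[keep], y[keep]
    n_used = int(x.size)
    if _monomorphic(x):
        return _degenerate(snp_id, coding_pass, "cs_poisson", n_used, "monomorphic after masking")
    X = np.column_stack([np.ones(n_used), x])
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(r))
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # separation / numerical failure
        return SNPResult(snp_id, coding_pass, "cs_poisson", math.nan, math.nan, math.nan,
                         math.nan, n_used, "nonconverged", str(exc))
    coef = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(coef) or not np.isfinite(se):
        return SNPResult(snp_id, coding_pass, "cs_poisson", coef, se, math.nan, math.nan,
                         n_used, "nonconverged")
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return SNPResult(snp_id, coding_pass, "cs_poisson", coef, se, z, p, n_used, "ok",
                     wide_se=se > WIDE_SE, intercept=float(res.params[0]))


def screen_deviance(
    coded: np.ndarray, mask: np.ndarray, deviance_residuals: np.ndarray,
    snp_id: str = "snp", coding_pass: str = "pass1",
) -> SNPResult:
    """Deviance-residual screen: OLS slope of the residual on the SNP indicator.

    For a binary predictor the slope is exactly the difference of group mean
    residuals; the z statistic is slope / SE with the normal reference.
    """
    x = coded[mask]
    d = deviance_residuals[mask]
    n_used = int(x.size)
    if _monomorphic(x):
        return _degenerate(snp_id, coding_pass, "deviance", n_used, "monomorphic after masking")
    n1 = x.sum()
    n0 = n_used - n1
    m1 = d[x == 1].mean()
    m0 = d[x == 0].mean()
    slope = m1 - m0
    sse = np.sum((d[x == 1] - m1) ** 2) + np.sum((d[x == 0] - m0) ** 2)
    if n_used <= 2:
        return _degenerate(snp_id, coding_pass, "deviance", n_used, "too few subjects")
    s2 = sse / (n_used - 2)
    se = math.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    if se == 0.0:
        return _degenerate(snp_id, coding_pass, "deviance", n_used, "zero residual variance")
    z = slope / se
    p = 2.0 * stats.norm.sf(abs(z))
    return SNPResult(snp_id, coding_pass, "deviance", slope, se, z, p, n_used, "ok")


def _coding_passes(coding: str) -> list[str]:
    if coding == "both":
        return ["pass1", "pass2"]
    if coding in ("pass1", "pass2"):
        return [coding]
    raise ValueError("coding must be 'pass1', 'pass2' or 'both'")


def run_screen(
    cohort: CohortData,
    genotypes: GenotypeMatrix,
    methods=METHODS,
    coding: str = "both",
    threshold: float = 0.001,
    offset_policy: str = "floor",
    censor_adjustment: str = "none",
) -> pd.DataFrame:
    """Screen every SNP with the selected engines; returns a tidy result table.

    Stage 1 (once per run): Cox fit of the common covariates and its
    residuals.  Stage 2: per SNP and coding pass, each engine in turn.
    Per-SNP failures are isolated as degenerate / nonconverged rows; output
    rows are sorted by (snp_id, pass, method) and carry a ``promising``
    column for p <= threshold.
    """
    if isinstance(methods, str):
        methods = (methods,)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if genotypes.n != cohort.n:
        raise ValueError(f"genotype rows ({genotypes.n}) != cohort size ({cohort.n})")
    needs_stage1 = {"cs_poisson", "deviance"} & set(methods)
    if needs_stage1:
        base_fit = fit_cox(cohort)
        resid = compute_residuals(base_fit, cohort, censor_adjustment=censor_adjustment)
        cs = resid.cox_snell
        dev = resid.deviance
    results: list[SNPResult] = []
    for j in range(genotypes.n_snps):
        col = genotypes.genotypes[:, j]
        sid = genotypes.snp_ids[j]
        for cpass in _coding_passes(coding):
            coded, mask = code_snp(col, cpass)
            for method in methods:
                if method == "cox_full":
                    res = screen_cox_full(cohort, coded, mask, sid, cpass)
                elif method == "cs_poisson":
                    res = screen_cs_poisson(coded, mask, cohort.event, cs, sid, cpass,
                                            offset_policy=offset_policy)
                else:
                    res = screen_deviance(coded, mask, dev, sid, cpass)
                results.append(res)
    df = pd.DataFrame([r.as_row() for r in results], columns=RESULT_COLUMNS)
    df = df.sort_values(["snp_id", "pass", "method"], kind="stable").reset_index(drop=True)
    df["promising"] = (df["p"] <= threshold).fillna(False)
    return df


def crossvalidate(
    cohort: CohortData,
    genotypes: GenotypeMatrix,
    cv: CVConfig,
    method: str = "cs_poisson",
    coding: str = "both",
    offset_policy: str = "floor",
):
    """s-fold cross-validated screen.

    The cohort is split into s near-equal folds by a seeded permutation;
    analysis i refits stage 1 and screens on the subjects outside fold i.
    A (SNP, pass) is promising when p <= threshold in at least
    ceil(fold_fraction_required * s) analyses.  Returns
    (per-fold results with a ``fold`` column, promising-set DataFrame).
    """
    n = cohort.n
    if cv.s > n // 10:
        raise ValueError(f"too many folds: s={cv.s} but only {n} subjects (need s <= n/10)")
    rng = np.random.default_rng(cv.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv.s)
    for i, fold in enumerate(folds, start=1):
        if cohort.event[np.setdiff1d(perm, fold)].sum() == 0:
            raise ValueError(f"fold {i}: analysis subset has zero events")
    frames = []
    for i, fold in enumerate(folds, start=1):
        analysis = np.setdiff1d(perm, fold)
        sub_cohort = CohortData(
            cohort.time[analysis], cohort.event[analysis], cohort.covariates[analysis],
            subject_ids=cohort.subject_ids[analysis],
            covariate_names=list(cohort.covariate_names),
        )
        sub_geno = GenotypeMatrix(
            genotypes.genotypes[analysis], genotypes.snp_ids, genotypes.alleles,
            chrom=genotypes.chrom, pos=genotypes.pos,
        )
        df = run_screen(sub_cohort, sub_geno, methods=method, coding=coding,
                        threshold=cv.threshold, offset_policy=offset_policy)
        df.insert(0, "fold", i)
        frames.append(df)
    all_folds = pd.concat(frames, ignore_index=True)
    need = math.ceil(cv.fold_fraction_required * cv.s)
    hits = (
        all_folds.assign(hit=all_folds["promising"].astype(int))
        .groupby(["snp_id", "pass", "method"], as_index=False)["hit"]
        .sum()
    )
    promising = hits[hits["hit"] >= need].rename(columns={"hit": "n_folds_significant"})
    promising = promising.sort_values(["snp_id", "pass", "method"], kind="stable").reset_index(drop=True)
    return all_folds, promising
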