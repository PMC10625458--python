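"""Cox proportional-hazards fitting and residual diagnostics.

This module holds stage one of the two-stage screening strategy: a single
Cox PH model h(t) = h0(t)·exp(beta'x) is fitted to the common (non-SNP)
covariates by maximizing the Breslow partial likelihood with a damped
Newton-Raphson iteration.  From that fit we derive the baseline cumulative
hazard, the Cox-Snell / martingale / deviance residuals that drive the
per-SNP screens, and a Schoenfeld-residual check of the proportional-hazards
assumption for the common covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CohortData",
    "CoxFit",
    "BaselineHazard",
    "ResidualSet",
    "PHTestResult",
    "NonIdentifiableError",
    "fit_cox",
    "cox_loglik",
    "baseline_cumhaz",
    "compute_residuals",
    "schoenfeld_ph_test",
]

CENSOR_ADJUSTMENTS = {"none": 0.0, "unity": 1.0, "ln2": float(np.log(2.0))}


class NonIdentifiableError(ValueError):
    """Raised when the covariate design is constant or collinear."""


@dataclass
class CohortData:
    """Right-censored cohort: follow-up times, event indicators, covariates.

    Times are study-entry relative (no left truncation).  ``covariates`` is
    an n x k float matrix; ``covariate_names`` defaults to x1..xk.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    subject_ids: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0] and self.covariates.shape[1] == self.time.shape[0]:
            self.covariates = self.covariates.T
        n = self.time.shape[0]
        if n < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if self.event.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError("time, event and covariates disagree on n")
        if np.any(self.time < 0):
            raise ValueError("follow-up times must be nonnegative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.event.sum() < 1:
            raise ValueError("cohort must contain at least one event")
        if not np.isfinite(self.covariates).all():
            raise ValueError("covariates must be finite (resolve missingness upstream)")
        if self.subject_ids is None:
            self.subject_ids = np.arange(n)
        else:
            self.subject_ids = np.asarray(self.subject_ids)
            if len(np.unique(self.subject_ids)) != n:
                raise ValueError("subject_ids must be unique")
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.covariates.shape[1])]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def k(self) -> int:
        return self.covariates.shape[1]


@dataclass
class CoxFit:
    """Maximum partial-likelihood estimate and its curvature."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    information: np.ndarray
    score: np.ndarray
    covariate_names: list[str]

    @property
    def z(self) -> np.ndarray:
        return self.coefficients / self.std_errors

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))


@dataclass
class BaselineHazard:
    """Step-function estimate of the cumulative baseline hazard H0(t).

    Zero before the first event time; right-continuous steps at each
    distinct event time.
    """

    event_times: np.ndarray
    cum_hazard: np.ndarray
    method: str = "km"

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.cum_hazard = np.asarray(self.cum_hazard, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(np.diff(self.cum_hazard) < 0) or (self.cum_hazard.size and self.cum_hazard[0] < 0):
            raise ValueError("cum_hazard must be nonnegative and nondecreasing")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("cumulative hazard undefined for negative time")
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[0.0], self.cum_hazard])
        out = padded[idx]
        return out if out.ndim else float(out)


@dataclass
class ResidualSet:
    """Per-subject Cox-Snell, martingale and deviance residuals.

    ``cox_snell`` carries the optional censoring adjustment (a constant
    added to censored subjects); martingale and deviance always derive from
    the unadjusted Cox-Snell residual, so r_M = delta - r_CS_raw holds.
    """

    cox_snell: np.ndarray
    martingale: np.ndarray
    deviance: np.ndarray
    censor_adjustment: float


def _check_design(X: np.ndarray, names: list[str]) -> None:
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            raise NonIdentifiableError(f"covariate '{names[j]}' is constant across subjects")
    centered = X - X.mean(axis=0)
    if X.shape[1] > 1:
        rank = np.linalg.matrix_rank(centered)
        if rank < X.shape[1]:
            # name one offending column: the first whose removal restores full rank
            for j in range(X.shape[1]):
                sub = np.delete(centered, j, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    raise NonIdentifiableError(f"covariate '{names[j]}' is collinear with the others")
            raise NonIdentifiableError("covariate matrix is rank deficient")


def _risk_sums(time, event, eta, X, order=None, need_info=True):
    """Breslow risk-set sums at each distinct event time.

    Returns (unique event times, d per time, S0, S1, S2) where
    S0 = sum over the risk set of w, S1 of w·x, S2 of w·x x', w = exp(eta).
    """
    n, k = X.shape
    if order is None:
        order = np.argsort(time, kind="stable")
    t_s, e_s, eta_s, X_s = time[order], event[order], eta[order], X[order]
    w = np.exp(eta_s)
    rc0 = np.cumsum(w[::-1])[::-1]
    rc1 = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
    ev_times = t_s[e_s == 1]
    uniq, d = np.unique(ev_times, return_counts=True)
    idx = np.searchsorted(t_s, uniq, side="left")
    S0 = rc0[idx]
    S1 = rc1[idx]
    S2 = None
    if need_info:
        outer = w[:, None, None] * (X_s[:, :, None] * X_s[:, None, :])
        rc2 = np.cumsum(outer[::-1], axis=0)[::-1]
        S2 = rc2[idx]
    return uniq, d, S0, S1, S2


def cox_loglik(beta, cohort: CohortData) -> float:
    """Breslow partial log-likelihood at ``beta`` (no derivatives)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = cohort.covariates @ beta
    uniq, d, S0, _, _ = _risk_sums(cohort.time, cohort.event, eta, cohort.covariates, need_info=False)
    return float(eta[cohort.event == 1].sum() - np.sum(d * np.log(S0)))


def _loglik_score_info(beta, cohort: CohortData):
    eta = cohort.covariates @ beta
    uniq, d, S0, S1, S2 = _risk_sums(cohort.time, cohort.event, eta, cohort.covariates)
    ll = float(eta[cohort.event == 1].sum() - np.sum(d * np.log(S0)))
    xbar = S1 / S0[:, None]
    ev = cohort.event == 1
    # sum of x over events, grouped by event time via the Breslow convention
    score = cohort.covariates[ev].sum(axis=0) - (d[:, None] * xbar).sum(axis=0)
    info = np.einsum("t,tij->ij", d, S2 / S0[:, None, None]) - np.einsum(
        "t,ti,tj->ij", d, xbar, xbar
    )
    return ll, score, info


def fit_cox(
    cohort: CohortData,
    *,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Fit the Cox PH model by damped Newton-Raphson on the partial likelihood.

    Ties are handled with the Breslow approximation.  Convergence is declared
    when every score component is below ``tol_score`` in magnitude or the
    relative log-likelihood change falls below ``tol_loglik``.  When a plain
    Newton step would decrease the log-likelihood, Levenberg-Marquardt
    ridge damping (with step halving) is applied until the step ascends.
    Non-convergence yields ``converged=False`` rather than an exception;
    constant or collinear covariates raise :class:`NonIdentifiableError`.
    """
    _check_design(cohort.covariates, cohort.covariate_names)
    k = cohort.k
    if k == 0:  # null model: nothing to estimate, baseline/residuals still defined
        ll = cox_loglik(np.zeros(0), cohort)
        return CoxFit(np.zeros(0), np.zeros(0), ll, 0, True, np.zeros((0, 0)), np.zeros(0), [])
    beta = np.zeros(k)
    ll, score, info = _loglik_score_info(beta, cohort)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol_score:
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise NonIdentifiableError(f"singular information matrix: {exc}") from exc
        lam = 0.0
        new_beta = beta + step
        new_ll, new_score, new_info = _loglik_score_info(new_beta, cohort)
        # halve-and-damp: only engaged when the Newton step is not an ascent
        inner = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and inner < 30:
            lam = 1e-4 * np.trace(info) / k if lam == 0.0 else 10.0 * lam
            step = np.linalg.solve(info + lam * np.eye(k), score)
            step *= 0.5**inner
            new_beta = beta + step
            new_ll, new_score, new_info = _loglik_score_info(new_beta, cohort)
            inner += 1
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < tol_score or rel_change < tol_loglik:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(score)):.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        converged = False
    return CoxFit(
        coefficients=beta,
        std_errors=se,
        loglik=ll,
        n_iterations=n_iter,
        converged=converged,
        information=info,
        score=score,
        covariate_names=list(cohort.covariate_names),
    )


def baseline_cumhaz(fit: CoxFit, cohort: CohortData, method: str = "km") -> BaselineHazard:
    """Estimate the cumulative baseline hazard at the fitted coefficients.

    ``method="km"`` (default) takes H0(t) = -log S0(t) with the
    Kaplan-Meier-type survival estimate S0(t) = prod(1 - d_i / S0_risk),
    matching the convention of the R survival package's survfit output;
    ``method="breslow"`` uses the Nelson-Aalen-type increments
    d_i / sum_{R(t_i)} exp(eta).  Where a KM increment is undefined
    (everyone at risk fails, d_i = S0_risk) the Breslow increment is
    substituted for that time.
    """
    if method not in {"km", "breslow"}:
        raise ValueError("method must be 'km' or 'breslow'")
    eta = cohort.covariates @ fit.coefficients
    uniq, d, S0, _, _ = _risk_sums(cohort.time, cohort.event, eta, cohort.covariates, need_info=False)
    h = d / S0
    if method == "breslow":
        inc = h
    else:
        inc = np.where(h < 1.0, -np.log1p(-np.minimum(h, 1.0 - 1e-15)), h)
        inc[h >= 1.0] = h[h >= 1.0]
    return BaselineHazard(event_times=uniq, cum_hazard=np.cumsum(inc), method=method)


def compute_residuals(
    fit: CoxFit,
    cohort: CohortData,
    censor_adjustment: str = "none",
    baseline_method: str = "breslow",
) -> ResidualSet:
    """Cox-Snell, martingale and deviance residuals from a fitted model.

    The raw Cox-Snell residual is H0(t_i)·exp(beta'x_i).  The optional
    ``censor_adjustment`` ("none", "unity", "ln2") adds a constant to the
    residuals of censored subjects only, compensating for their unobserved
    remaining hazard; martingale and deviance residuals always use the raw
    residual.  The default Breslow baseline makes the martingale residuals
    sum to zero at the MLE; the "km" baseline follows the -log(KM)
    convention instead and the zero-sum identity then holds only
    approximately.
    """
    if censor_adjustment not in CENSOR_ADJUSTMENTS:
        raise ValueError(f"censor_adjustment must be one of {sorted(CENSOR_ADJUSTMENTS)}")
    H0 = baseline_cumhaz(fit, cohort, method=baseline_method)
    eta = cohort.covariates @ fit.coefficients
    raw = H0(cohort.time) * np.exp(eta)
    delta = cohort.event.astype(float)
    if np.any((raw == 0) & (delta == 1)):
        raise RuntimeError("event with zero cumulative hazard: inconsistent fit state")
    mart = delta - raw
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(delta == 1, np.log(np.where(raw > 0, raw, 1.0)), 0.0)
    rad = -2.0 * (mart + delta * logterm)
    dev = np.sign(mart) * np.sqrt(np.maximum(rad, 0.0))
    const = CENSOR_ADJUSTMENTS[censor_adjustment]
    cs = raw + const * (1.0 - delta)
    return ResidualSet(cox_snell=cs, martingale=mart, deviance=dev, censor_adjustment=const)


@dataclass
class PHTestResult:
    """Schoenfeld-residual proportional-hazards check, one p-value per covariate."""

    p_values: np.ndarray
    correlations: np.ndarray
    transform: str
    n_events: int
    computable: bool


def _km_survival(time, event):
    """Plain Kaplan-Meier survival estimate at each distinct event time."""
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    at_risk = np.arange(len(t_s), 0, -1)
    uniq, d = np.unique(t_s[e_s == 1], return_counts=True)
    idx = np.searchsorted(t_s, uniq, side="left")
    n_risk = at_risk[idx]
    return uniq, np.cumprod(1.0 - d / n_risk)


def schoenfeld_ph_test(fit: CoxFit, cohort: CohortData, transform: str = "km") -> PHTestResult:
    """Test proportional hazards for each common covariate.

    Correlates the scaled Schoenfeld residuals with a transform of event
    time — ``"km"`` (default), i.e. 1 - KM(t), or ``"identity"`` — and
    returns the Pearson correlation t-test p-value per covariate.  A
    drifting correlation signals a time-varying effect.  With fewer than 3
    events the test is not computable and is flagged.
    """
    if transform not in {"km", "identity"}:
        raise ValueError("transform must be 'km' or 'identity'")
    k = cohort.k
    d_total = int(cohort.event.sum())
    if d_total < 3:
        return PHTestResult(
            p_values=np.full(k, np.nan),
            correlations=np.full(k, np.nan),
            transform=transform,
            n_events=d_total,
            computable=False,
        )
    eta = cohort.covariates @ fit.coefficients
    uniq, d, S0, S1, _ = _risk_sums(
        cohort.time, cohort.event, eta, cohort.covariates, need_info=False
    )
    xbar_at = dict(zip(uniq, S1 / S0[:, None]))
    ev = cohort.event == 1
    ev_times = cohort.time[ev]
    resid = cohort.covariates[ev] - np.array([xbar_at[t] for t in ev_times])
    vinv = np.linalg.inv(fit.information / d_total)
    scaled = resid @ vinv  # + beta-hat, constant, irrelevant to correlation
    if transform == "km":
        km_t, km_s = _km_survival(cohort.time, cohort.event)
        g = 1.0 - km_s[np.searchsorted(km_t, ev_times, side="right") - 1]
    else:
        g = ev_times.astype(float)
    pvals = np.empty(k)
    corrs = np.empty(k)
    for j in range(k):
        r, p = stats.pearsonr(g, scaled[:, j])
        corrs[j], pvals[j] = r, p
    return PHTestResult(
        p_values=pvals, correlations=corrs, transform=transform, n_events=d_total, computable=True
    )
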