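"""Statistical kernel: rank tests, contingency tests, logistic regression
by iteratively reweighted least squares, Wald odds ratios and
(covariate-adjusted) ROC/AUC.

The descriptive-comparison tests (Spearman, Mann–Whitney U, chi-squared,
Student's t) delegate to scipy with the conventions pinned down here. The
logistic fit and the AUC estimators are implemented in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit


class DegenerateInputError(ValueError):
    """The statistic is undefined on this input (constant vector, zero margin...)."""


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; p by the t approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spearman rho undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (midrank ties).

    Exact p when the smaller group has ≤ 8 observations and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r×c count table."""
    t = np.asarray(table, float)
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero marginal row or column")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def students_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sample t test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise DegenerateInputError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# logistic regression (IRLS / Newton-Raphson)

SEPARATION_BOUND = 15.0   # |beta| beyond this on the logit scale => separation


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    reason: str = ""
    n: int = 0

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(
    y: Sequence[int],
    X: np.ndarray,
    max_iter: int = 50,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares (Newton-Raphson on the log-likelihood).

    ``X`` must include the intercept column. Convergence is declared when
    the largest score component falls below ``tol_score`` or the relative
    log-likelihood change falls below ``tol_loglik``. A coefficient
    escaping beyond ±15 on the logit scale is flagged as (quasi-)complete
    separation and the fit is returned non-converged rather than silently.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("shape mismatch between y and X")
    if np.ptp(y) == 0:
        raise DegenerateInputError("outcome is constant")

    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    reason = "max_iter"
    converged = False
    cov = np.full((k, k), np.nan)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        W = p * (1.0 - p)
        score = X.T @ (y - p)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.max(np.abs(score)) < tol_score or (
            np.isfinite(ll_old)
            and abs(ll - ll_old) <= tol_loglik * (abs(ll_old) + 1e-30)
        ):
            converged = True
            reason = ""
            break
        ll_old = ll
        info = (X * W[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            reason = "singular_information"
            break
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            reason = "separation"
            break

    eta = X @ beta
    p = expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if converged:
        W = p * (1.0 - p)
        info = (X * W[:, None]).T @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            converged, reason = False, "singular_information"
    return LogisticFit(coef=beta, cov=cov, converged=converged, n_iter=it,
                       loglik=ll, reason=reason, n=n)


@dataclass
class AssociationResult:
    """Odds ratio with Wald 95% CI for one exposure term."""

    index_id: str
    outcome: str
    stratum: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int
    n_controls: int
    adjusted_for: tuple = ()
    defined: bool = True
    reason: str = ""


def odds_ratio(
    fit: LogisticFit,
    term: int,
    index_id: str = "",
    outcome: str = "",
    stratum: str = "",
    n_cases: int = 0,
    n_controls: int = 0,
    adjusted_for: tuple = (),
) -> AssociationResult:
    """Wald odds ratio for one coefficient: OR = exp(β), CI = exp(β ± 1.96 SE)."""
    if not fit.converged:
        return AssociationResult(
            index_id=index_id, outcome=outcome, stratum=stratum,
            odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
            n_cases=n_cases, n_controls=n_controls, adjusted_for=adjusted_for,
            defined=False, reason=fit.reason or "not_converged",
        )
    beta = fit.coef[term]
    se = fit.se()[term]
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return AssociationResult(
        index_id=index_id, outcome=outcome, stratum=stratum,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=p, n_cases=n_cases, n_controls=n_controls,
        adjusted_for=adjusted_for,
    )


# ---------------------------------------------------------------------------
# ROC / AUC

def auc(scores_cases: Sequence[float], scores_controls: Sequence[float]) -> float:
    """Mann–Whitney AUC: (concordant pairs + half ties) / (n1 * n2)."""
    a = np.asarray(scores_cases, float)
    b = np.asarray(scores_controls, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    u = r1 - len(a) * (len(a) + 1) / 2.0
    return float(u / (len(a) * len(b)))


@dataclass
class ROCResult:
    """AUC with bootstrap percentile CI for one index × outcome × stratum."""

    index_id: str
    outcome: str
    stratum: str
    auc: float
    ci_low: float
    ci_high: float
    adjusted: bool
    p_value: float = float("nan")
    n_cases: int = 0
    n_controls: int = 0
    defined: bool = True
    reason: str = ""


def adjusted_auc(
    flag: Sequence[float],
    age: Sequence[float],
    outcome: Sequence[int],
    bootstrap_reps: int = 1000,
    seed: Optional[int] = None,
    extra_covariates: Optional[np.ndarray] = None,
    index_id: str = "",
    outcome_label: str = "",
    stratum: str = "",
) -> ROCResult:
    """Covariate-adjusted AUC via logistic predicted probabilities.

    Fits outcome ~ intercept + flag + age (+ extra covariates), scores each
    subject with the fitted probability and takes the Mann–Whitney AUC of
    those scores. The 95% CI is the percentile interval over seeded
    nonparametric bootstrap resamples of subjects; the Wald p-value of the
    flag coefficient is carried along. Single-class strata and separated
    fits yield an explicitly undefined result rather than a number.
    """
    flag = np.asarray(flag, float)
    age = np.asarray(age, float)
    y = np.asarray(outcome, float)
    n = len(y)
    cols = [np.ones(n), flag, age]
    if extra_covariates is not None:
        extra = np.atleast_2d(np.asarray(extra_covariates, float))
        if extra.shape[0] != n:
            extra = extra.T
        cols.extend(extra.T)
    X = np.column_stack(cols)

    def undefined(reason: str) -> ROCResult:
        return ROCResult(index_id=index_id, outcome=outcome_label,
                         stratum=stratum, auc=np.nan, ci_low=np.nan,
                         ci_high=np.nan, adjusted=True,
                         n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum()),
                         defined=False, reason=reason)

    if n == 0 or np.ptp(y) == 0:
        return undefined("single_class")
    fit = fit_logistic(y, X)
    if not fit.converged:
        return undefined(fit.reason or "not_converged")
    prob = expit(X @ fit.coef)
    point = auc(prob[y == 1], prob[y == 0])
    z = fit.coef[1] / fit.se()[1]
    p_flag = float(2.0 * sps.norm.sf(abs(z)))

    if bootstrap_reps and bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if np.ptp(yb) == 0:
                continue
            fb = fit_logistic(yb, X[idx])
            if not fb.converged:
                continue
            pb = expit(X[idx] @ fb.coef)
            reps.append(auc(pb[yb == 1], pb[yb == 0]))
        if len(reps) < max(50, bootstrap_reps // 2):
            ci_low = ci_high = np.nan
        else:
            ci_low = float(np.percentile(reps, 2.5))
            ci_high = float(np.percentile(reps, 97.5))
    else:
        ci_low = ci_high = np.nan
    return ROCResult(
        index_id=index_id, outcome=outcome_label, stratum=stratum,
        auc=point, ci_low=ci_low, ci_high=ci_high, adjusted=True,
        p_value=p_flag, n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
    )
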