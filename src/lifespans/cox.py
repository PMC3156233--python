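"""Cox proportional-hazards regression by Newton-Raphson.

The model is ``h_i(t) = h0(t) exp(beta . x_i)``: each risk factor scales the
baseline hazard multiplicatively and ``exp(beta_k)`` is the hazard ratio per
unit of covariate ``k``.  The coefficients maximize the partial likelihood,
so the baseline hazard ``h0`` never needs to be estimated; only ``beta`` and
its uncertainty are reported.  Tied death times are handled with Breslow's
approximation by default (Efron's is available).  Model-based standard
errors come from the inverse observed information; the optional robust
standard errors use the score-residual sandwich estimator, which stays valid
when the proportional-hazards variance model is misspecified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import CoxDataset
from .results import TestResult

__all__ = ["CoxFit", "fit_cox", "cox_score_test"]

_DIVERGENCE_BOUND = 20.0


@dataclass(frozen=True)
class CoxFit:
    """Fitted coefficients of a proportional-hazards regression."""

    beta: np.ndarray
    se_model: np.ndarray
    se_robust: np.ndarray | None
    wald_z: np.ndarray
    wald_p: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_iter: int
    n_events: int
    n_subjects: int
    ties: str
    covariate_names: list[str]

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary_rows(self) -> list[dict]:
        rows = []
        for j, name in enumerate(self.covariate_names):
            row = {
                "covariate": name,
                "coef": float(self.beta[j]),
                "hazard_ratio": float(self.hazard_ratios[j]),
                "se_model": float(self.se_model[j]),
                "z": float(self.wald_z[j]),
                "p": float(self.wald_p[j]),
            }
            if self.se_robust is not None:
                row["se_robust"] = float(self.se_robust[j])
            rows.append(row)
        return rows


def _event_blocks(data: CoxDataset):
    """Sort subjects by time; group deaths by distinct event time."""
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    s = data.status[order]
    x = data.covariates[order]
    event_times = np.unique(t[s == 1])
    # risk set for time tt: subjects with t >= tt -> suffix starting at index
    risk_start = np.searchsorted(t, event_times, side="left")
    death_idx = [np.nonzero((t == tt) & (s == 1))[0] for tt in event_times]
    return t, s, x, event_times, risk_start, death_idx


def _loglik_grad_hess(beta, x, risk_start, death_idx, ties):
    n, k = x.shape
    eta = x @ beta
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = np.einsum("i,ij,il->ijl", w, x, x)
    # suffix (risk-set) sums: S0(t), S1(t), S2(t)
    s0_suf = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    s1_suf = np.concatenate([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros((1, k))])
    s2_suf = np.concatenate([np.cumsum(wxx[::-1], axis=0)[::-1], np.zeros((1, k, k))])

    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    for start, didx in zip(risk_start, death_idx):
        d = len(didx)
        s0 = s0_suf[start]
        s1 = s1_suf[start]
        s2 = s2_suf[start]
        xsum = x[didx].sum(axis=0)
        ll += float(eta[didx].sum())
        if ties == "breslow":
            ll -= d * np.log(s0)
            grad += xsum - d * s1 / s0
            hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        else:  # efron
            s0d = w[didx].sum()
            s1d = wx[didx].sum(axis=0)
            s2d = wxx[didx].sum(axis=0)
            for ell in range(d):
                frac = ell / d
                s0e = s0 - frac * s0d
                s1e = s1 - frac * s1d
                s2e = s2 - frac * s2d
                ll -= np.log(s0e)
                grad += xsum / d - s1e / s0e
                hess -= s2e / s0e - np.outer(s1e, s1e) / s0e**2
    return ll, grad, hess


def _score_residuals(beta, t, s, x, event_times, risk_start, death_idx):
    """Per-subject score residuals (Breslow form) for the sandwich estimator."""
    n, k = x.shape
    w = np.exp(x @ beta)
    s0_suf = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    s1_suf = np.concatenate(
        [np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1], np.zeros((1, k))]
    )
    s0 = s0_suf[risk_start]
    xbar = s1_suf[risk_start] / s0[:, None]
    d_counts = np.array([len(di) for di in death_idx], dtype=float)

    resid = np.zeros((n, k))
    # event part: delta_i (x_i - xbar(T_i))
    for tt_idx, didx in enumerate(death_idx):
        resid[didx] += x[didx] - xbar[tt_idx]
    # expected part: - sum_{t_k <= T_i} (d_k w_i / S0_k)(x_i - xbar(t_k))
    incr_a = np.cumsum(d_counts / s0)  # sum d_k / S0_k
    incr_b = np.cumsum((d_counts / s0)[:, None] * xbar, axis=0)  # sum d_k xbar_k / S0_k
    last_event = np.searchsorted(event_times, t, side="right") - 1
    inside = last_event >= 0
    a = np.where(inside, incr_a[np.maximum(last_event, 0)], 0.0)
    b = np.where(inside[:, None], incr_b[np.maximum(last_event, 0)], 0.0)
    resid -= w[:, None] * (a[:, None] * x - b)
    return resid


def fit_cox(
    data: CoxDataset,
    robust: bool = False,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards regression.

    Newton-Raphson from ``beta = 0`` with step-halving whenever a step would
    decrease the log partial likelihood; convergence is declared when the
    gradient's max-norm drops below ``tol``.  Wald p-values use the robust
    standard errors when ``robust`` is on, the model-based ones otherwise.

    Raises
    ------
    ValueError
        If there are no events, a covariate is constant, the information
        matrix is singular (collinear covariates), or the likelihood is
        monotone in some direction (complete separation of risk).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    n_events = int(data.status.sum())
    if n_events == 0:
        raise ValueError("no events (deaths) in the data; cannot fit")
    if np.any(np.ptp(data.covariates, axis=0) == 0):
        raise ValueError("collinear covariates: a covariate is constant")

    t, s, x, event_times, risk_start, death_idx = _event_blocks(data)
    k = x.shape[1]
    beta = np.zeros(k)
    ll, grad, hess = _loglik_grad_hess(beta, x, risk_start, death_idx, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise ValueError("collinear covariates: singular information matrix")
        # step-halving keeps the partial likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(
                cand, x, risk_start, death_idx, ties
            )
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            break
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > _DIVERGENCE_BOUND:
            raise ValueError(
                "complete separation of risk: coefficient diverging, the "
                "partial likelihood has no finite maximum"
            )
    else:
        it = max_iter
        converged = bool(np.max(np.abs(grad)) < tol)
    if np.max(np.abs(grad)) < tol:
        converged = True

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ValueError("collinear covariates: singular information matrix")
    se_model = np.sqrt(np.diag(cov))
    se_robust = None
    if robust:
        resid = _score_residuals(beta, t, s, x, event_times, risk_start, death_idx)
        meat = resid.T @ resid
        cov_robust = cov @ meat @ cov
        se_robust = np.sqrt(np.diag(cov_robust))
    se_for_p = se_robust if robust else se_model
    z = beta / se_for_p
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        beta=beta,
        se_model=se_model,
        se_robust=se_robust,
        wald_z=z,
        wald_p=p,
        log_partial_likelihood=float(ll),
        converged=converged,
        n_iter=it,
        n_events=n_events,
        n_subjects=data.n_subjects,
        ties=ties,
        covariate_names=data.covariate_names,
    )


def cox_score_test(data: CoxDataset, ties: str = "breslow") -> TestResult:
    """Score (Rao) test of ``beta = 0``.

    With a single binary covariate and no tied death times this statistic
    coincides with the two-sample log-rank chi-square exactly.
    """
    _, _, x, _, risk_start, death_idx = _event_blocks(data)
    k = x.shape[1]
    _, grad, hess = _loglik_grad_hess(np.zeros(k), x, risk_start, death_idx, ties)
    info = -hess
    stat = float(grad @ np.linalg.solve(info, grad))
    return TestResult(
        method="cox_score",
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df=k)),
        df=k,
    )
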