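"""Two-sample tests for differences in lifespan *length*.

Three tests compare where deaths fall in time:

* the log-rank (Mantel-Cox) test, optimal under a constant hazard ratio,
* its Fleming-Harrington G(rho, gamma) weighting, which stresses early
  (rho > 0) or late (gamma > 0) deaths, and
* Fisher's exact test on the alive/dead 2x2 table at the time the pooled
  sample reaches a given mortality (90% by default).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datasets import SurvivalDataset
from .km import km_estimate
from .results import TestResult

__all__ = [
    "logrank_test",
    "weighted_logrank_test",
    "fisher_exact_at_mortality",
]


def _pool(ds1: SurvivalDataset, ds2: SurvivalDataset) -> SurvivalDataset:
    t1, s1 = ds1.to_subjects()
    t2, s2 = ds2.to_subjects()
    return SurvivalDataset.from_subjects(
        "pooled", np.concatenate([t1, t2]), np.concatenate([s1, s2])
    )


def _counts_at(ds: SurvivalDataset, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deaths at each pooled time and number at risk just before it."""
    d = np.zeros(times.size, dtype=float)
    idx = np.searchsorted(times, ds.times)
    match = (idx < times.size) & np.isclose(times[np.minimum(idx, times.size - 1)], ds.times)
    d[idx[match]] = ds.deaths[match]
    removed = np.concatenate([[0], np.cumsum(ds.deaths + ds.censored)])
    pos = np.searchsorted(ds.times, times, side="left")
    n = ds.n_total - removed[pos]
    return d, n.astype(float)


def pooled_event_table(
    ds1: SurvivalDataset, ds2: SurvivalDataset
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per pooled death time: ``(t, d1, d, n1, n)``.

    ``d1``/``n1`` are group-1 deaths and at-risk counts, ``d``/``n`` the
    pooled ones; times with no pooled deaths are omitted.
    """
    all_times = np.unique(np.concatenate([ds1.times, ds2.times]))
    d1, n1 = _counts_at(ds1, all_times)
    d2, n2 = _counts_at(ds2, all_times)
    d = d1 + d2
    n = n1 + n2
    ev = d > 0
    return all_times[ev], d1[ev], d[ev], n1[ev], n[ev]


def _logrank_terms(ds1, ds2):
    if ds1.n_deaths == 0 or ds2.n_deaths == 0:
        raise ValueError("both groups need at least one death for a log-rank test")
    t, d1, d, n1, n = pooled_event_table(ds1, ds2)
    e = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(
            n > 1,
            d * (n1 / n) * ((n - n1) / n) * (n - d) / np.maximum(n - 1, 1),
            0.0,
        )
    return t, d1, d, n1, n, e, v


def logrank_test(ds1: SurvivalDataset, ds2: SurvivalDataset) -> TestResult:
    """Mantel-Cox log-rank test for equality of two survival functions.

    The statistic is ``(sum_i (d_1i - e_i))^2 / sum_i v_i`` over the pooled
    death times, with expected deaths ``e_i = d_i n_1i / n_i`` and the
    hypergeometric variance
    ``v_i = d_i (n_1i/n_i)(n_2i/n_i)(n_i - d_i)/(n_i - 1)`` (terms with
    ``n_i = 1`` contribute zero); the reference distribution is chi-square
    with one degree of freedom.
    """
    t, d1, d, n1, n, e, v = _logrank_terms(ds1, ds2)
    vsum = float(v.sum())
    if vsum <= 0:
        raise ValueError("log-rank variance is zero; groups never overlap in risk")
    obs_minus_exp = float((d1 - e).sum())
    stat = obs_minus_exp**2 / vsum
    return TestResult(
        method="logrank",
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df=1)),
        df=1,
        extras={"observed_minus_expected": obs_minus_exp, "variance": vsum},
    )


def weighted_logrank_test(
    ds1: SurvivalDataset,
    ds2: SurvivalDataset,
    rho: float = 0.0,
    gamma: float = 0.0,
) -> TestResult:
    """Fleming-Harrington G(rho, gamma)-weighted log-rank test.

    The weight at pooled death time ``t_i`` is
    ``w_i = S(t_i-)^rho (1 - S(t_i-))^gamma`` with ``S`` the left-continuous
    pooled Kaplan-Meier estimate; ``rho = gamma = 0`` recovers the plain
    log-rank test exactly.
    """
    if rho < 0 or gamma < 0:
        raise ValueError("rho and gamma must be non-negative")
    t, d1, d, n1, n, e, v = _logrank_terms(ds1, ds2)
    pooled_km = km_estimate(_pool(ds1, ds2))
    s_left = pooled_km.survival_at(t, side="left")
    w = s_left**rho * (1.0 - s_left) ** gamma
    denom = float((w**2 * v).sum())
    if denom <= 0:
        raise ValueError(
            "degenerate weights: every weighted variance term vanishes "
            f"(rho={rho}, gamma={gamma})"
        )
    num = float((w * (d1 - e)).sum())
    stat = num**2 / denom
    return TestResult(
        method="weighted_logrank",
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, df=1)),
        df=1,
        extras={"rho": rho, "gamma": gamma},
    )


def fisher_exact_at_mortality(
    ds1: SurvivalDataset,
    ds2: SurvivalDataset,
    mortality_fraction: float = 0.9,
) -> TestResult:
    """Fisher's exact test on alive/dead status at a pooled mortality point.

    The comparison time ``t*`` is the earliest pooled death time at which the
    pooled Kaplan-Meier mortality ``1 - S(t)`` reaches ``mortality_fraction``
    (90% by default).  Each group contributes (alive, dead) counts at ``t*``;
    subjects censored strictly before ``t*`` are excluded because their status
    at ``t*`` is unknown.  The two-sided p-value sums the hypergeometric
    probabilities of all tables with the observed margins that are no more
    likely than the observed one.
    """
    if not 0.0 < mortality_fraction <= 1.0:
        raise ValueError("mortality_fraction must be in (0, 1]")
    pooled_km = km_estimate(_pool(ds1, ds2))
    mortality = 1.0 - pooled_km.survival
    hit = np.nonzero(mortality >= mortality_fraction - 1e-12)[0]
    if hit.size == 0:
        raise ValueError(
            f"pooled mortality never reaches {mortality_fraction:.0%}; "
            "try a lower mortality fraction"
        )
    t_star = float(pooled_km.event_times[hit[0]])

    def group_counts(ds: SurvivalDataset) -> tuple[int, int]:
        dead = int(ds.deaths[ds.times <= t_star].sum())
        cens_before = int(ds.censored[ds.times < t_star].sum())
        alive = ds.n_total - dead - cens_before
        return alive, dead

    a, c = group_counts(ds1)
    b, d = group_counts(ds2)
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(
        method="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        extras={
            "time": t_star,
            "mortality_fraction": mortality_fraction,
            "table": table.tolist(),
        },
    )
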