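"""Kaplan-Meier estimation, lifespan descriptives and log cumulative hazard.

The product-limit estimator handles right censoring: at each distinct death
time ``t_j`` with ``n_j`` subjects still at risk and ``d_j`` deaths,

    S(t_j) = prod_{i <= j} (1 - d_i / n_i),

with subjects censored at ``t_j`` leaving the risk set *after* the deaths at
``t_j`` are counted.  Greenwood's formula gives the pointwise variance

    Var[S(t_j)] = S(t_j)^2 * sum_{i <= j} d_i / (n_i (n_i - d_i)).

The log cumulative hazard curve ``ln H(t)`` (with ``H = -ln S`` by default,
or the Nelson-Aalen sum ``H = sum d_i/n_i`` on request) is the input for the
slope-based shape and variance tests: under Gompertz mortality it is linear
in ``t``, its slope reads as the rate of aging and its intercept as the
initial hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import LifespanWarning, SurvivalDataset

__all__ = [
    "KMEstimate",
    "SummaryStats",
    "HazardCurve",
    "km_estimate",
    "summary_stats",
    "log_cumulative_hazard",
]


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate at the distinct death times."""

    event_times: np.ndarray  # strictly increasing death times
    survival: np.ndarray  # S(t_j)
    greenwood_var: np.ndarray  # Var[S(t_j)]
    at_risk: np.ndarray  # n_j just before deaths at t_j
    deaths: np.ndarray  # d_j
    censored_after: np.ndarray  # censored in (t_j, t_{j+1}] (incl. at t_j)
    n_total: int
    warnings_: tuple[str, ...] = field(default=())

    def survival_at(self, t: np.ndarray | float, side: str = "right") -> np.ndarray:
        """Step-function evaluation of S at arbitrary times.

        ``side='right'`` gives the right-continuous KM step S(t);
        ``side='left'`` gives the left limit S(t-), the convention needed for
        Fleming-Harrington weights.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right" if side == "right" else "left")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    @property
    def n_events(self) -> int:
        return int(self.deaths.sum())


@dataclass(frozen=True)
class SummaryStats:
    """Table-style lifespan descriptives for one experiment."""

    restricted_mean: float  # days; area under S up to tau
    restricted_mean_se: float
    ci95: tuple[float, float]
    median: float | None
    percentile_ages: dict[int, float | None]  # {25, 50, 75, 90, 100} -> days
    tau: float  # truncation time of the restricted mean


@dataclass(frozen=True)
class HazardCurve:
    """Log cumulative hazard point series ``(t_j, ln H(t_j))``."""

    times: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and y must be 1-d and equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.times.size)


def km_estimate(ds: SurvivalDataset) -> KMEstimate:
    """Kaplan-Meier product-limit estimate for one grouped experiment.

    Censored subjects recorded at a time ``t`` stay in the risk set for the
    deaths at ``t`` and leave afterwards.  A dataset with no deaths at all
    yields the degenerate estimate ``S == 1`` with a warning.
    """
    notes: list[str] = []
    n_total = ds.n_total
    if ds.n_deaths == 0:
        msg = f"dataset {ds.label!r} has no deaths; survival is identically 1"
        warnings.warn(msg, LifespanWarning, stacklevel=2)
        empty = np.array([], dtype=float)
        return KMEstimate(
            event_times=empty,
            survival=empty,
            greenwood_var=empty,
            at_risk=np.array([], dtype=np.int64),
            deaths=np.array([], dtype=np.int64),
            censored_after=np.array([], dtype=np.int64),
            n_total=n_total,
            warnings_=(msg,),
        )

    removed_before = np.concatenate([[0], np.cumsum(ds.deaths + ds.censored)[:-1]])
    at_risk_all = n_total - removed_before  # n at risk just before each record time
    ev = ds.deaths > 0
    n_j = at_risk_all[ev]
    d_j = ds.deaths[ev]
    t_j = ds.times[ev]

    frac = 1.0 - d_j / n_j
    surv = np.cumprod(frac)
    # Greenwood: S^2 * cumsum(d / (n (n - d))); last term infinite when S hits 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_j > d_j, d_j / (n_j * (n_j - d_j).clip(min=1)), 0.0)
    gw = surv**2 * np.cumsum(terms)

    # censored counts attributed to the preceding-or-equal event time
    cens_after = np.zeros(t_j.size, dtype=np.int64)
    slot = np.searchsorted(t_j, ds.times, side="right") - 1
    for s, c in zip(slot, ds.censored):
        if s >= 0:
            cens_after[s] += int(c)

    return KMEstimate(
        event_times=t_j.astype(float),
        survival=surv,
        greenwood_var=gw,
        at_risk=n_j.astype(np.int64),
        deaths=d_j.astype(np.int64),
        censored_after=cens_after,
        n_total=n_total,
        warnings_=tuple(notes),
    )


def _step_area(times: np.ndarray, surv: np.ndarray, tau: float) -> float:
    """Area under the right-continuous KM step from 0 to tau."""
    t = np.concatenate([[0.0], times[times <= tau], [tau]])
    s = np.concatenate([[1.0], surv[times <= tau]])
    widths = np.diff(t)
    return float(np.sum(widths * s[: widths.size]))


def summary_stats(
    km: KMEstimate,
    ds: SurvivalDataset,
    tau: float | None = None,
    percentiles: tuple[int, ...] = (25, 50, 75, 90, 100),
) -> SummaryStats:
    """Restricted mean lifespan with standard error, and ages at % mortality.

    The restricted mean is the area under the survival step function from 0
    to ``tau`` (default: the last observed time, death or censoring).  Its
    standard error uses the classic Kaplan-Meier area variance

        Var = sum_j A_j^2 d_j / (n_j (n_j - d_j)),   A_j = integral_{t_j}^{tau} S,

    and the 95% CI is the normal approximation ``mean +/- 1.96 SE``.  The age
    at q% mortality is the smallest event time with ``S(t) <= 1 - q/100`` (no
    interpolation); 100% mortality is undefined (``None``) when the longest
    survivor was censored.
    """
    if tau is None:
        tau = float(ds.times[-1])
    if km.event_times.size == 0:
        raise ValueError("summary_stats requires at least one death")

    rmean = _step_area(km.event_times, km.survival, tau)

    inside = km.event_times <= tau
    t_j = km.event_times[inside]
    s_j = km.survival[inside]
    n_j = km.at_risk[inside].astype(float)
    d_j = km.deaths[inside].astype(float)
    # A_j = area under S over (t_j, tau]
    grid = np.concatenate([t_j, [tau]])
    seg = np.diff(grid) * s_j  # area of each step segment
    a_j = np.cumsum(seg[::-1])[::-1]  # A_j = area under S over (t_j, tau]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = np.where(n_j > d_j, d_j / (n_j * (n_j - d_j).clip(min=1)), 0.0)
    rvar = float(np.sum(a_j**2 * var_terms))
    se = float(np.sqrt(rvar))
    ci = (rmean - 1.96 * se, rmean + 1.96 * se)

    last_is_censored = km.survival[-1] > 0
    ages: dict[int, float | None] = {}
    for q in percentiles:
        thresh = 1.0 - q / 100.0
        if q == 100 and last_is_censored:
            ages[q] = None
            continue
        hit = np.nonzero(km.survival <= thresh + 1e-12)[0]
        ages[q] = float(km.event_times[hit[0]]) if hit.size else None
    median = ages.get(50)
    if 50 not in ages:
        hit = np.nonzero(km.survival <= 0.5 + 1e-12)[0]
        median = float(km.event_times[hit[0]]) if hit.size else None
    return SummaryStats(
        restricted_mean=rmean,
        restricted_mean_se=se,
        ci95=ci,
        median=median,
        percentile_ages=ages,
        tau=tau,
    )


def log_cumulative_hazard(km: KMEstimate, estimator: str = "km") -> HazardCurve:
    """Log cumulative hazard curve at the event times with ``0 < S < 1``.

    ``estimator='km'`` (default) uses ``H(t) = -ln S_KM(t)``;
    ``estimator='nelson-aalen'`` uses ``H(t) = sum_{t_i <= t} d_i/n_i``.
    """
    if estimator not in ("km", "nelson-aalen"):
        raise ValueError(f"unknown estimator {estimator!r}")
    usable = (km.survival > 0) & (km.survival < 1)
    if not np.any(usable):
        raise ValueError("no event time with 0 < S < 1; cannot form hazard curve")
    if estimator == "km":
        h = -np.log(km.survival[usable])
    else:
        h = np.cumsum(km.deaths / km.at_risk)[usable]
    return HazardCurve(times=km.event_times[usable], y=np.log(h))
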