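"""Pairwise comparison reports, Bonferroni correction and p-value formatting.

A lifespan study rarely has only two arms; every test here is run on every
unordered pair of experiments and the per-method family of pairwise p-values
is Bonferroni-corrected (``p_corr = min(1, m p)`` with ``m`` the number of
pairs).  Warnings raised by individual tests are carried into the report
rather than printed into the data stream.
"""

from __future__ import annotations

import itertools
from typing import Any, Callable

import numpy as np
import pandas as pd

from .datasets import SurvivalDataset
from .km import km_estimate, log_cumulative_hazard, summary_stats
from .location import fisher_exact_at_mortality, logrank_test, weighted_logrank_test
from .results import TestResult
from .shape import chow_test, ks_test, neyman_smooth_test
from .variance import (
    normalized_chow_test,
    partial_slopes_ranksum_test,
    survival_time_f_test,
)

__all__ = [
    "run_compare",
    "format_pvalue",
    "describe",
    "survival_steps",
    "hazard_points",
    "METHODS",
]


def _curve_pair(ds1, ds2, fn, **kw) -> TestResult:
    h1 = log_cumulative_hazard(km_estimate(ds1))
    h2 = log_cumulative_hazard(km_estimate(ds2))
    return fn(h1, h2, **kw)


METHODS: dict[str, Callable[..., TestResult]] = {
    "logrank": lambda a, b, **kw: logrank_test(a, b),
    "weighted_logrank": lambda a, b, rho=0.0, gamma=0.0, **kw: weighted_logrank_test(
        a, b, rho=rho, gamma=gamma
    ),
    "fisher": lambda a, b, mortality_fraction=0.9, **kw: fisher_exact_at_mortality(
        a, b, mortality_fraction=mortality_fraction
    ),
    "ks": lambda a, b, n_perm=2000, seed=None, **kw: ks_test(
        a, b, n_perm=n_perm, seed=seed
    ),
    "neyman": lambda a, b, n_perm=2000, seed=None, max_dim=5, **kw: neyman_smooth_test(
        a, b, max_dim=max_dim, n_perm=n_perm, seed=seed
    ),
    "chow": lambda a, b, k=3, **kw: _curve_pair(a, b, chow_test, k=k),
    "f_test": lambda a, b, **kw: survival_time_f_test(a, b),
    "ranksum": lambda a, b, **kw: partial_slopes_ranksum_test(a, b),
    "normalized_chow": lambda a, b, k=1, **kw: _curve_pair(
        a, b, normalized_chow_test, k=k
    ),
}


def run_compare(
    datasets: list[SurvivalDataset],
    methods: list[str],
    alpha: float = 0.05,
    **method_kwargs: Any,
) -> pd.DataFrame:
    """All-pairs test matrix with per-method Bonferroni correction.

    Every unordered pair of datasets is tested with every requested method;
    within a method the correction factor is the number of pairs.  A method
    failing on one pair produces an ``error`` row instead of aborting the
    whole matrix.  Returns a tidy DataFrame with one row per (pair, method).
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to compare")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    pairs = list(itertools.combinations(range(len(datasets)), 2))
    m = len(pairs)
    rows: list[dict[str, Any]] = []
    for method in methods:
        fn = METHODS[method]
        for i, j in pairs:
            row: dict[str, Any] = {
                "group1": datasets[i].label,
                "group2": datasets[j].label,
                "method": method,
            }
            try:
                res = fn(datasets[i], datasets[j], **method_kwargs)
            except ValueError as exc:
                row.update(
                    {"statistic": np.nan, "p_value": np.nan,
                     "p_corrected": np.nan, "significant": False,
                     "error": str(exc)}
                )
            else:
                p_corr = min(1.0, res.p_value * m)
                row.update(
                    {
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "p_corrected": p_corr,
                        "significant": bool(p_corr < alpha),
                        "error": "",
                        "warnings": "; ".join(res.warnings),
                    }
                )
                for key, val in res.extras.items():
                    if np.isscalar(val) or isinstance(val, str):
                        row.setdefault(key, val)
            rows.append(row)
    return pd.DataFrame(rows)


def format_pvalue(p: float, floor: float = 1e-10, compat: bool = False) -> str:
    """Render a p-value in 2-decimal scientific notation with a floor.

    P-values below ``floor`` print as ``"<1.0E-10"`` by default; with
    ``compat`` on they print as ``"0.00E+00"``, mirroring the legacy output
    convention of older survival-analysis reports.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < floor:
        if compat:
            return "0.00E+00"
        exp = int(np.floor(np.log10(floor)))
        mant = floor / 10.0**exp
        return f"<{mant:.1f}E{exp:+03d}"
    return f"{p:.2E}"


def describe(ds: SurvivalDataset) -> dict[str, Any]:
    """Summary-table row for one experiment (restricted mean, % mortality ages)."""
    km = km_estimate(ds)
    st = summary_stats(km, ds)
    row: dict[str, Any] = {
        "name": ds.label,
        "n_subjects": ds.n_total,
        "n_deaths": ds.n_deaths,
        "restricted_mean": round(st.restricted_mean, 2),
        "restricted_mean_se": round(st.restricted_mean_se, 2),
        "ci95_low": round(st.ci95[0], 2),
        "ci95_high": round(st.ci95[1], 2),
    }
    for q, age in st.percentile_ages.items():
        row[f"age_at_{q}pct"] = "-" if age is None else age
    return row


def survival_steps(ds: SurvivalDataset) -> pd.DataFrame:
    """Step-function vertices of the KM curve, ready for any plotting tool."""
    km = km_estimate(ds)
    t = np.repeat(np.concatenate([[0.0], km.event_times]), 2)[1:]
    s = np.repeat(np.concatenate([[1.0], km.survival]), 2)[:-1]
    return pd.DataFrame({"time": t, "survival": s})


def hazard_points(ds: SurvivalDataset, estimator: str = "km") -> pd.DataFrame:
    """(t, log cumulative hazard) pairs for one experiment."""
    h = log_cumulative_hazard(km_estimate(ds), estimator=estimator)
    return pd.DataFrame({"time": h.times, "log_cum_hazard": h.y})
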