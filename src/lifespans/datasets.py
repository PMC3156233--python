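"""Core data containers for grouped and subject-level survival data.

A lifespan assay is recorded as a grouped table: at each observation time we
know how many subjects died and how many were censored (lost, bagged,
transferred) during the interval.  :class:`SurvivalDataset` holds one such
labelled experiment.  :class:`CoxDataset` holds subject-level records (one row
per animal) with covariates, the input shape proportional-hazards regression
needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurvivalDataset", "CoxDataset", "LifespanWarning"]


class LifespanWarning(UserWarning):
    """Non-fatal data issues (merged duplicate rows, dropped 0/0 rows...)."""


@dataclass(frozen=True)
class SurvivalDataset:
    """One labelled experiment of interval records ``(time, deaths, censored)``.

    Parameters
    ----------
    label : str
        Experiment identifier.
    times : array of float
        Strictly increasing observation times (typically integer days).
    deaths : array of int
        Number of deaths observed at each time.
    censored : array of int
        Number of subjects censored during the interval ending at each time.
    """

    label: str
    times: np.ndarray
    deaths: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.deaths, dtype=np.int64)
        c = np.asarray(self.censored, dtype=np.int64)
        if not (t.shape == d.shape == c.shape) or t.ndim != 1:
            raise ValueError("times, deaths and censored must be 1-d and equal length")
        if t.size == 0:
            raise ValueError(f"dataset {self.label!r} has no records")
        if np.any(t < 0):
            raise ValueError("negative observation time")
        if np.any(np.diff(t) <= 0):
            raise ValueError("record times must be strictly increasing")
        if np.any(d < 0) or np.any(c < 0):
            raise ValueError("negative death or censoring count")
        if np.any((d + c) == 0):
            raise ValueError("record with neither deaths nor censoring")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "censored", c)

    @classmethod
    def from_records(
        cls, label: str, records: list[tuple[float, int, int]]
    ) -> "SurvivalDataset":
        """Build from ``(time, deaths, censored)`` triples.

        Rows are sorted by time; duplicate times are merged by summing counts;
        all-zero rows are dropped.  Both repairs emit a :class:`LifespanWarning`.
        """
        if not records:
            raise ValueError(f"dataset {label!r} has no records")
        arr = np.asarray(records, dtype=float)
        kept = arr[(arr[:, 1] + arr[:, 2]) > 0]
        if kept.shape[0] < arr.shape[0]:
            warnings.warn(
                f"dataset {label!r}: dropped {arr.shape[0] - kept.shape[0]} "
                "row(s) with zero deaths and zero censored",
                LifespanWarning,
                stacklevel=2,
            )
        if kept.shape[0] == 0:
            raise ValueError(f"dataset {label!r} has no informative records")
        order = np.argsort(kept[:, 0], kind="stable")
        kept = kept[order]
        uniq, inv = np.unique(kept[:, 0], return_inverse=True)
        if uniq.size < kept.shape[0]:
            warnings.warn(
                f"dataset {label!r}: merged duplicate-time rows by summing counts",
                LifespanWarning,
                stacklevel=2,
            )
        d = np.zeros(uniq.size, dtype=np.int64)
        c = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(d, inv, kept[:, 1].astype(np.int64))
        np.add.at(c, inv, kept[:, 2].astype(np.int64))
        return cls(label=label, times=uniq, deaths=d, censored=c)

    @property
    def n_total(self) -> int:
        """Total number of subjects, ``sum(deaths + censored)``."""
        return int(self.deaths.sum() + self.censored.sum())

    @property
    def n_deaths(self) -> int:
        return int(self.deaths.sum())

    def to_subjects(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to subject-level ``(time, status)`` arrays (status 1 = died)."""
        times = np.repeat(self.times, self.deaths + self.censored)
        status = np.concatenate(
            [
                np.concatenate([np.ones(d, dtype=np.int8), np.zeros(c, dtype=np.int8)])
                for d, c in zip(self.deaths, self.censored)
            ]
        )
        return times, status

    @classmethod
    def from_subjects(
        cls, label: str, times: np.ndarray, status: np.ndarray
    ) -> "SurvivalDataset":
        """Aggregate subject-level ``(time, status)`` pairs into grouped records."""
        times = np.asarray(times, dtype=float)
        status = np.asarray(status)
        uniq = np.unique(times)
        d = np.array([(status[times == t] == 1).sum() for t in uniq], dtype=np.int64)
        c = np.array([(status[times == t] == 0).sum() for t in uniq], dtype=np.int64)
        return cls(label=label, times=uniq, deaths=d, censored=c)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class CoxDataset:
    """Subject-level risk-factor table for proportional-hazards regression."""

    field_names: list[str]
    time: np.ndarray  # observed time per subject, > 0
    status: np.ndarray  # 1 = event (death), 0 = censored
    covariates: np.ndarray  # shape (n_subjects, k)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.status, dtype=np.int64)
        x = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if x.shape[0] != t.size or s.size != t.size:
            raise ValueError("time, status and covariates row counts differ")
        if x.shape[1] < 1:
            raise ValueError("at least one covariate required")
        if np.any(t <= 0):
            raise ValueError("observed times must be positive")
        if not np.all(np.isin(s, [0, 1])):
            raise ValueError("status must be 0 (censored) or 1 (dead)")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "status", s)
        object.__setattr__(self, "covariates", x)

    @property
    def n_subjects(self) -> int:
        return int(self.time.size)

    @property
    def n_covariates(self) -> int:
        return int(self.covariates.shape[1])

    @property
    def covariate_names(self) -> list[str]:
        # first two fields are time and status by the format contract
        if len(self.field_names) >= 2 + self.n_covariates:
            return list(self.field_names[2 : 2 + self.n_covariates])
        return [f"x{j + 1}" for j in range(self.n_covariates)]
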