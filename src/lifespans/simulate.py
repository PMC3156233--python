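"""Synthetic lifespan-assay generation.

Death times are drawn from one of three families commonly used to model
mortality in aging cohorts:

* ``gaussian(mean, sd)`` — the spread of deaths around a characteristic
  lifespan; the model behind the variance-test validation scenarios,
* ``gompertz(a, b)`` — hazard ``a * exp(b t)``: exponentially accelerating
  mortality, which makes the log cumulative hazard plot linear in time
  (slope ``~b`` reads as the rate of aging),
* ``exponential(rate)`` — constant hazard, the memoryless control case.

Draws are truncated to positive times, optionally right-censored (each
censored subject gets a uniform censoring time before its death), recorded
on an integer-day grid like a real lifespan scoring schedule, and aggregated
into grouped :class:`~lifespans.datasets.SurvivalDataset` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SurvivalDataset

__all__ = ["SimulationSpec", "simulate_lifespans", "make_variance_triplet"]


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one simulated experiment."""

    family: str  # gaussian | gompertz | exponential
    params: dict = field(default_factory=dict)
    n: int = 100
    censor_rate: float = 0.0
    round_to_days: bool = True
    label: str = "sim"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "gompertz", "exponential"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.family == "gaussian":
            if self.params.get("sd", 0) <= 0:
                raise ValueError("gaussian sd must be positive")
        elif self.family == "gompertz":
            if self.params.get("a", 0) <= 0 or self.params.get("b", 0) <= 0:
                raise ValueError("gompertz a and b must be positive")
        else:
            if self.params.get("rate", 0) <= 0:
                raise ValueError("exponential rate must be positive")


def _draw_death_times(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n
    out = np.empty(0)
    while out.size < n:  # redraw non-positive times (truncation at 0)
        need = n - out.size
        if spec.family == "gaussian":
            t = rng.normal(spec.params["mean"], spec.params["sd"], size=2 * need)
        elif spec.family == "exponential":
            t = rng.exponential(1.0 / spec.params["rate"], size=2 * need)
        else:  # gompertz via inverse transform of H(t) = a/b (e^{bt} - 1)
            a, b = spec.params["a"], spec.params["b"]
            u = rng.random(2 * need)
            t = np.log1p(-b * np.log(u) / a) / b
        out = np.concatenate([out, t[t > 0][:need]])
    return out[:n]


def simulate_lifespans(spec: SimulationSpec, seed: int | None = None) -> SurvivalDataset:
    """Draw one grouped lifespan experiment according to ``spec``.

    Censored subjects are chosen uniformly at random (a fraction
    ``censor_rate`` of the cohort) and receive a censoring time drawn
    uniformly on ``(0, death time)`` — censoring carries no information about
    frailty.  With ``round_to_days`` every recorded time is rounded to the
    nearest positive integer day.  Identical ``(spec, seed)`` pairs produce
    identical datasets.
    """
    rng = np.random.default_rng(seed)
    times = _draw_death_times(spec, rng)
    status = np.ones(spec.n, dtype=np.int8)
    n_cens = int(round(spec.censor_rate * spec.n))
    if n_cens:
        who = rng.choice(spec.n, size=n_cens, replace=False)
        status[who] = 0
        times[who] = rng.uniform(0.0, times[who])
    if spec.round_to_days:
        times = np.maximum(np.round(times), 1.0)
    return SurvivalDataset.from_subjects(spec.label, times, status)


def make_variance_triplet(
    n: int = 250, seed: int | None = None
) -> tuple[SurvivalDataset, SurvivalDataset, SurvivalDataset]:
    """The three-cohort validation design for the variance tests.

    Cohorts A and B share a mean lifespan of 20 days but differ in spread
    (SD 2 vs 4 days); cohorts B and C share the spread (SD 4 days) but differ
    in mean (20 vs 30 days).  Mean-oriented tests should separate B from C
    but not A from B; variance tests should do the opposite.  Integer-day
    recording, no censoring; each cohort gets its own seed stream derived
    from ``seed``.
    """
    if n < 30:
        raise ValueError("n must be at least 30 per cohort")
    ss = np.random.SeedSequence(seed).spawn(3)
    specs = [
        SimulationSpec("gaussian", {"mean": 20.0, "sd": 2.0}, n=n, label="A"),
        SimulationSpec("gaussian", {"mean": 20.0, "sd": 4.0}, n=n, label="B"),
        SimulationSpec("gaussian", {"mean": 30.0, "sd": 4.0}, n=n, label="C"),
    ]
    a, b, c = (
        simulate_lifespans(spec, seed=np.random.default_rng(s).integers(2**31))
        for spec, s in zip(specs, ss)
    )
    return a, b, c
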