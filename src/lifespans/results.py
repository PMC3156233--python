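"""Uniform container for hypothesis-test outcomes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["TestResult"]


@dataclass
class TestResult:
    """Outcome of one statistical test.

    ``extras`` carries method-specific detail (Fleming-Harrington rho/gamma,
    the mortality time point and 2x2 table, the selected smooth dimension...)
    so every test can be rendered as one row of a report.
    """

    method: str
    statistic: float
    p_value: float
    df: Any = None
    warnings: list[str] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or self.p_value != self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_row(self) -> dict[str, Any]:
        row = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.df is not None:
            row["df"] = self.df
        if self.warnings:
            row["warnings"] = "; ".join(self.warnings)
        row.update({k: v for k, v in self.extras.items() if not k.startswith("_")})
        return row
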