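"""Readers and writers for the "%"-header tab-separated survival formats.

Two plain-text formats are supported:

* grouped survival tables — a ``%`` line carrying the experiment label,
  followed by rows of ``time<TAB>deaths<TAB>censored``; several experiments
  may be stacked in one file, and
* subject-level tables for Cox regression — a ``%`` line naming the fields,
  followed by rows of ``time<TAB>status<TAB>covariate...``.

Lines starting with ``#`` are comments (an additive extension, ignored on
write); blank lines and trailing whitespace are ignored.  A fourth or later
column in a grouped survival row is ignored with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datasets import CoxDataset, LifespanWarning, SurvivalDataset

__all__ = [
    "FormatError",
    "parse_survival_table",
    "parse_cox_table",
    "write_survival_table",
    "write_cox_table",
    "read_survival_file",
]


class FormatError(ValueError):
    """Malformed input table (missing header, ragged rows...)."""


def _lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def _parse_cell(cell: str, lineno: int, what: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"line {lineno}: non-numeric {what} {cell!r}") from None


def parse_survival_table(text: str) -> list[SurvivalDataset]:
    """Parse one or more grouped survival experiments from ``text``.

    Each ``%``-prefixed line starts a new experiment; the remainder of that
    line is the label.  Data rows need at least three tab-separated columns:
    observation time, number of deaths, number censored.  Duplicate times
    within an experiment are merged by summing counts (with a warning).

    Raises
    ------
    FormatError
        If the first data row precedes any ``%`` header, a row has fewer than
        three columns, or a header has no data rows.
    ValueError
        On non-numeric or negative cells (the message names the line number).
    """
    blocks: list[tuple[str, list[tuple[float, int, int]]]] = []
    extra_cols_warned = False
    for lineno, line in _lines(text):
        if line.startswith("%"):
            blocks.append((line[1:].strip(), []))
            continue
        if not blocks:
            raise FormatError(
                f"line {lineno}: data row before any '%' experiment header"
            )
        cells = line.split("\t")
        if len(cells) < 3:
            raise FormatError(
                f"line {lineno}: expected >=3 tab-separated columns, got {len(cells)}"
            )
        if len(cells) > 3 and any(c.strip() for c in cells[3:]) and not extra_cols_warned:
            warnings.warn(
                f"line {lineno}: ignoring columns beyond the third",
                LifespanWarning,
                stacklevel=2,
            )
            extra_cols_warned = True
        t = _parse_cell(cells[0], lineno, "time")
        d = _parse_cell(cells[1], lineno, "death count")
        c = _parse_cell(cells[2], lineno, "censored count")
        if t < 0:
            raise ValueError(f"line {lineno}: negative time {t}")
        if d < 0 or c < 0:
            raise ValueError(f"line {lineno}: negative count")
        if d != int(d) or c != int(c):
            raise ValueError(f"line {lineno}: non-integer death/censored count")
        blocks[-1][1].append((t, int(d), int(c)))
    if not blocks:
        raise FormatError("no '%' experiment header found")
    datasets = []
    for label, records in blocks:
        if not records:
            raise FormatError(f"experiment {label!r} has no data rows")
        datasets.append(SurvivalDataset.from_records(label, records))
    return datasets


def write_survival_table(datasets: list[SurvivalDataset] | SurvivalDataset) -> str:
    """Serialize experiments back to the grouped text format."""
    if isinstance(datasets, SurvivalDataset):
        datasets = [datasets]
    out: list[str] = []
    for ds in datasets:
        out.append(f"% {ds.label}")
        for t, d, c in zip(ds.times, ds.deaths, ds.censored):
            ts = f"{t:g}"
            out.append(f"{ts}\t{d}\t{c}")
    return "\n".join(out) + "\n"


def parse_cox_table(text: str) -> CoxDataset:
    """Parse a subject-level table: ``% field names`` then rows of
    ``time<TAB>status<TAB>covariates...``.

    All rows must have exactly as many cells as the header has names (or,
    if the header and rows disagree but all rows agree with each other and
    have >=3 cells, the row width wins and names are padded).
    """
    header: list[str] | None = None
    rows: list[list[float]] = []
    width: int | None = None
    for lineno, line in _lines(text):
        if line.startswith("%"):
            if header is not None:
                raise FormatError(f"line {lineno}: second '%' header in Cox table")
            header = [c.strip() for c in line[1:].strip().split("\t") if c.strip()]
            continue
        if header is None:
            raise FormatError(f"line {lineno}: data row before the '%' field-name header")
        cells = line.split("\t")
        if len(cells) < 3:
            raise FormatError(
                f"line {lineno}: expected >=3 columns (time, status, risk factors)"
            )
        if width is None:
            width = len(cells)
            if len(header) > 1 and len(header) != width:
                raise FormatError(
                    f"line {lineno}: header names {len(header)} fields "
                    f"but row has {width} cells"
                )
        elif len(cells) != width:
            raise FormatError(
                f"line {lineno}: ragged row ({len(cells)} cells, expected {width})"
            )
        vals = [_parse_cell(c, lineno, "value") for c in cells]
        if vals[0] <= 0:
            raise ValueError(f"line {lineno}: observed time must be positive")
        if vals[1] not in (0.0, 1.0):
            raise ValueError(
                f"line {lineno}: status must be 0 (censored) or 1 (dead), got {cells[1]}"
            )
        rows.append(vals)
    if header is None:
        raise FormatError("no '%' field-name header found")
    if not rows:
        raise FormatError("Cox table has no data rows")
    arr = np.asarray(rows, dtype=float)
    names = header if len(header) == arr.shape[1] else (
        ["time", "status"] + [f"x{j + 1}" for j in range(arr.shape[1] - 2)]
    )
    return CoxDataset(
        field_names=names,
        time=arr[:, 0],
        status=arr[:, 1].astype(np.int64),
        covariates=arr[:, 2:],
    )


def write_cox_table(data: CoxDataset) -> str:
    """Serialize a subject-level table back to text."""
    names = data.field_names
    if len(names) != 2 + data.n_covariates:
        names = ["time", "status"] + data.covariate_names
    out = ["% " + "\t".join(names)]
    for i in range(data.n_subjects):
        cells = [f"{data.time[i]:g}", str(int(data.status[i]))]
        cells += [f"{v:g}" for v in data.covariates[i]]
        out.append("\t".join(cells))
    return "\n".join(out) + "\n"


def read_survival_file(path) -> list[SurvivalDataset]:
    """Read grouped survival experiments from a file path."""
    with open(path, encoding="utf-8") as fh:
        return parse_survival_table(fh.read())
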