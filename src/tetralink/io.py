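"""Counts-table reading and writing.

The on-disk format is a CSV or TSV with header columns
``population_id, model, n_yellow, n_green, n_red, n_grey``
(case-insensitive).  The same format is emitted by the simulator, so
simulated data round-trip through the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .inference import PhenotypeCounts

__all__ = ["CountsTableRow", "read_counts_table", "write_counts_table", "COLUMNS"]

logger = logging.getLogger("tetralink")

COLUMNS = ("population_id", "model", "n_yellow", "n_green", "n_red", "n_grey")
_MODELS = {"disomic", "tetrasomic"}


@dataclass(frozen=True)
class CountsTableRow:
    population_id: str
    model: str
    n_yellow: int
    n_green: int
    n_red: int
    n_grey: int

    def counts(self) -> PhenotypeCounts:
        return PhenotypeCounts(self.n_yellow, self.n_green, self.n_red, self.n_grey)


def _dialect_sep(path: Path, dialect: Optional[str]) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    return "\t" if dialect == "tsv" else ","


def read_counts_table(path: str | Path, dialect: Optional[str] = None) -> list[CountsTableRow]:
    """Read and validate a counts table.

    Raises ``ValueError`` naming the offending row and column for
    missing/negative/non-integer counts, unknown model labels, and
    duplicated population ids.  A header-only file yields an empty list
    with a warning.
    """
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("%s: counts table contains a header but no rows", path)
        return []

    rows: list[CountsTableRow] = []
    seen: set[str] = set()
    for idx, rec in df.iterrows():
        rowno = int(idx) + 2  # 1-based, after the header line
        pop = str(rec["population_id"]).strip()
        if not pop or pop.lower() == "nan":
            raise ValueError(f"{path} row {rowno}: empty population_id")
        if pop in seen:
            raise ValueError(f"{path} row {rowno}: duplicate population_id {pop!r}")
        seen.add(pop)
        model = str(rec["model"]).strip().lower()
        if model not in _MODELS:
            raise ValueError(
                f"{path} row {rowno}, column 'model': unknown label {model!r} "
                f"(expected disomic or tetrasomic)"
            )
        counts = {}
        for col in COLUMNS[2:]:
            raw = str(rec[col]).strip()
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path} row {rowno}, column {col!r}: {raw!r} is not an integer"
                ) from None
            if val < 0:
                raise ValueError(
                    f"{path} row {rowno}, column {col!r}: negative count {val}"
                )
            counts[col] = val
        rows.append(CountsTableRow(population_id=pop, model=model, **counts))
    return rows


def write_counts_table(
    rows: Iterable[CountsTableRow], path: str | Path, dialect: Optional[str] = None
) -> None:
    """Write rows in the canonical column order; inverse of
    :func:`read_counts_table` for valid tables."""
    path = Path(path)
    sep = _dialect_sep(path, dialect)
    df = pd.DataFrame([r.__dict__ for r in rows], columns=list(COLUMNS))
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")
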