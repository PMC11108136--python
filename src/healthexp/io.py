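"""Readers and writers for individual observation records.

Records are delimited text (CSV by default) with a header row naming the
five fields ``person_id, sex, age, state_t, state_t1``.  Reading is
row-tolerant: malformed rows are rejected with per-row diagnostics and
the remainder is kept; the read fails outright only when a non-empty
file yields zero valid rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .states import LIVING_STATES, N_STATES, RECORD_COLUMNS, SEXES

logger = logging.getLogger(__name__)


@dataclass
class ReadReport:
    """Per-row diagnostics from :func:`read_records`."""

    n_read: int = 0
    n_valid: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)

    def summary(self) -> str:
        return (f"{self.n_valid}/{self.n_read} rows valid; "
                f"{len(self.rejected)} rejected")


def read_records(path, delimiter: str = ",") -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate an individual-records file.

    Returns the valid rows as a DataFrame plus a :class:`ReadReport`
    listing the 1-based data-row numbers of every reject and why.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file without header")
    missing = set(RECORD_COLUMNS) - set(raw.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    report = ReadReport(n_read=len(raw))
    if len(raw) == 0:
        warnings.warn(f"{path}: no data rows, returning empty record set",
                      stacklevel=2)
        return (pd.DataFrame(columns=list(RECORD_COLUMNS)).astype(
            {"age": int, "state_t": int, "state_t1": int}), report)

    df = raw[list(RECORD_COLUMNS)].copy()
    df["sex"] = df["sex"].str.strip().str.lower()
    age = pd.to_numeric(df["age"], errors="coerce")
    st = pd.to_numeric(df["state_t"], errors="coerce")
    st1 = pd.to_numeric(df["state_t1"], errors="coerce")

    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[~df["sex"].isin(SEXES)] = "sex not in {female, male}"
    reasons[(age.isna() | (age % 1 != 0) | (age < 0)) & (reasons == "")] = \
        "unparseable or negative age"
    reasons[(st.isna() | ~st.isin(LIVING_STATES)) & (reasons == "")] = \
        "baseline state not in 1..6"
    reasons[(st1.isna() | ~st1.isin(range(1, N_STATES + 1))) & (reasons == "")] = \
        "follow-up state not in 1..7"

    bad = reasons != ""
    for i in df.index[bad]:
        report.rejected.append((int(i) + 1, reasons[i]))
        logger.warning("%s row %d rejected: %s", path.name, i + 1, reasons[i])

    good = df.loc[~bad].copy()
    good["age"] = age[~bad].astype(int)
    good["state_t"] = st[~bad].astype(int)
    good["state_t1"] = st1[~bad].astype(int)
    report.n_valid = len(good)
    if report.n_valid == 0:
        raise ValidationError(
            f"{path}: zero valid rows ({len(report.rejected)} rejected; "
            f"first: row {report.rejected[0][0]}: {report.rejected[0][1]})"
        )
    return good.reset_index(drop=True), report


def write_records(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False, columns=list(RECORD_COLUMNS))
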