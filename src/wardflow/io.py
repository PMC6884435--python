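"""Readers and writers for the four tabular text formats.

All tables are comma-delimited text with fixed headers and integer seconds:

* raw RTLS data:        ``tagID,tagRole,time,zID``
* period data:          ``tagID,st,et,zID,tagRole``
* facing-time table:    ``nID,<TYPE>_<lo>-<hi>,...`` (type-major columns)
* cluster assignments:  ``nID,cluster``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .facing import FacingTable, TimeBins
from .periods import PERIOD_COLUMNS, PeriodTable
from .synth_rtls import RAW_COLUMNS, RawRtlsTable

__all__ = [
    "read_raw", "write_raw",
    "read_periods", "write_periods",
    "read_facing", "write_facing",
    "read_assignments", "write_assignments",
]


def _read_csv(path, expected: tuple[str, ...], int_cols: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise InputFormatError(f"{path}: unexpected column(s) {extra}")
    for col in int_cols:
        try:
            df[col] = df[col].astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise InputFormatError(f"{path}: column {col!r} is not integral") from exc
    return df


def read_raw(path) -> RawRtlsTable:
    return RawRtlsTable(_read_csv(path, RAW_COLUMNS, ("time", "zID")))


def write_raw(table: RawRtlsTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_periods(path, role_scope: str | None = None) -> PeriodTable:
    df = _read_csv(path, PERIOD_COLUMNS, ("st", "et", "zID"))
    if role_scope is None:
        kinds = set(df["tagRole"].str.split(":").str[0]) if len(df) else set()
        role_scope = ("nurses_only" if kinds <= {"nurse"} and kinds else
                      "patients_only" if kinds <= {"patient"} and kinds else "mixed")
    return PeriodTable(df, role_scope=role_scope)


def write_periods(table: PeriodTable, path) -> None:
    table.df.to_csv(path, index=False)


def write_facing(table: FacingTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_facing(path) -> FacingTable:
    df = pd.read_csv(path, dtype=str)
    if "nID" not in df.columns:
        raise InputFormatError(f"{path}: missing column(s) ['nID']")
    value_cols = [c for c in df.columns if c != "nID"]
    if not value_cols:
        raise InputFormatError(f"{path}: no count columns present")
    # Recover type labels and bins from the <TYPE>_<lo>-<hi> column layout.
    parsed = []
    for c in value_cols:
        try:
            t, rng = c.rsplit("_", 1)
            lo, hi = rng.split("-", 1)
            parsed.append((t, int(lo), None if hi == "inf" else int(hi)))
        except ValueError as exc:
            raise InputFormatError(f"{path}: malformed count column {c!r}") from exc
    type_labels = list(dict.fromkeys(t for t, _, _ in parsed))
    first_type = [p for p in parsed if p[0] == type_labels[0]]
    boundaries = tuple(hi for _, _, hi in first_type if hi is not None)
    bins = TimeBins(boundaries)
    expected = [f"{t}_{lab}" for t in type_labels for lab in bins.labels()]
    if value_cols != expected:
        raise InputFormatError(f"{path}: column layout {value_cols} is not type-major")
    counts = df[value_cols].astype(np.int64).to_numpy()
    return FacingTable(list(df["nID"]), type_labels, bins, counts)


def write_assignments(nurse_ids: list[str], membership: np.ndarray,
                      converged: int, path) -> None:
    clusters = membership.argmax(axis=1)
    df = pd.DataFrame({"nID": nurse_ids, "cluster": clusters})
    df.to_csv(path, index=False)
    Path(str(path) + ".converged").write_text(f"converged={converged}\n")


def read_assignments(path) -> pd.DataFrame:
    return _read_csv(path, ("nID", "cluster"), ("cluster",))
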