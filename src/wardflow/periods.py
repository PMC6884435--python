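"""Local pre-processing of raw RTLS records into maximal stay-periods.

Each party runs this on its own view before the joint protocol: consecutive
grid observations of one tag in one zone merge into a half-open period
[start, last_observation + sample_interval).  A zone change or a tracking
gap (more than one sampling interval between observations) closes the
period; gaps are never bridged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputFormatError, InvariantViolationError

__all__ = ["Period", "PeriodTable", "extract_periods", "periods_to_grid",
           "PERIOD_COLUMNS"]

PERIOD_COLUMNS = ("tagID", "st", "et", "zID", "tagRole")


@dataclass(frozen=True)
class Period:
    """One continuous stay of one tag in one zone, half-open [start, end)."""

    tag_id: str
    start: int
    end: int
    zone_id: int
    tag_role: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeriodTable:
    """An ordered collection of periods with a role scope.

    The nurse-scoped and patient-scoped instances are the two parties'
    period sets (the labour union's and the hospital's inputs).
    """

    df: pd.DataFrame
    role_scope: str = "mixed"  # nurses_only | patients_only | mixed

    def __post_init__(self) -> None:
        missing = [c for c in PERIOD_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputFormatError(f"period table missing columns {missing}")
        self.df = self.df.loc[:, list(PERIOD_COLUMNS)].reset_index(drop=True)
        if self.role_scope not in ("nurses_only", "patients_only", "mixed"):
            raise InputFormatError(f"unknown role_scope {self.role_scope!r}")

    def __len__(self) -> int:
        return len(self.df)

    def to_periods(self) -> list[Period]:
        return [Period(r.tagID, int(r.st), int(r.et), int(r.zID), r.tagRole)
                for r in self.df.itertuples(index=False)]

    @classmethod
    def from_periods(cls, periods: list[Period], role_scope: str = "mixed"
                     ) -> "PeriodTable":
        df = pd.DataFrame(
            [(p.tag_id, p.start, p.end, p.zone_id, p.tag_role) for p in periods],
            columns=list(PERIOD_COLUMNS),
        )
        return cls(df, role_scope=role_scope)


def _infer_scope(roles: pd.Series) -> str:
    kinds = set(roles.str.split(":").str[0].unique())
    if kinds <= {"nurse"}:
        return "nurses_only"
    if kinds <= {"patient"}:
        return "patients_only"
    return "mixed"


def extract_periods(records, sample_interval: int) -> PeriodTable:
    """Merge per-tag grid records into maximal same-zone periods.

    A period's end is the last observed timestamp plus one sampling
    interval (a tag observed at an instant occupies the zone for the full
    sampling slot), so overlaps count shared slots.
    """
    df = records.df if hasattr(records, "df") else records
    if len(df) == 0:
        return PeriodTable(pd.DataFrame(columns=list(PERIOD_COLUMNS)))
    if (df["time"] % sample_interval != 0).any():
        bad = df.loc[df["time"] % sample_interval != 0, "time"].iloc[0]
        raise InputFormatError(f"timestamp {bad} is off the sampling grid")
    if df.duplicated(["tagID", "time"]).any():
        dup = df.loc[df.duplicated(["tagID", "time"]), ["tagID", "time"]].iloc[0]
        raise InputFormatError(
            f"duplicate record for tag {dup.tagID!r} at time {int(dup.time)}"
        )

    df = df.sort_values(["tagID", "time"], kind="mergesort").reset_index(drop=True)
    new_tag = df["tagID"].ne(df["tagID"].shift())
    new_zone = df["zID"].ne(df["zID"].shift())
    gap = df["time"].diff().ne(sample_interval)
    group = (new_tag | new_zone | gap).cumsum()

    agg = df.groupby(group, sort=False).agg(
        tagID=("tagID", "first"),
        st=("time", "min"),
        et=("time", "max"),
        zID=("zID", "first"),
        tagRole=("tagRole", "first"),
    )
    agg["et"] = agg["et"] + sample_interval
    agg = agg.reset_index(drop=True)
    return PeriodTable(agg, role_scope=_infer_scope(df["tagRole"]))


def periods_to_grid(periods: PeriodTable, sample_interval: int):
    """Re-expand periods to one record per contained grid time.

    Inverse of :func:`extract_periods` on dropout-free input; used as the
    consistency oracle between the two representations.
    """
    from .synth_rtls import RawRtlsTable  # local import to avoid a cycle

    df = periods.df
    if len(df) == 0:
        return RawRtlsTable(pd.DataFrame(columns=["tagID", "tagRole", "time", "zID"]))

    ordered = df.sort_values(["tagID", "st"], kind="mergesort")
    same_tag = ordered["tagID"].eq(ordered["tagID"].shift())
    overlapping = same_tag & ordered["st"].lt(ordered["et"].shift())
    if overlapping.any():
        tag = ordered.loc[overlapping, "tagID"].iloc[0]
        raise InvariantViolationError(f"overlapping periods for tag {tag!r}")

    frames = []
    for row in df.itertuples(index=False):
        times = np.arange(row.st, row.et, sample_interval)
        frames.append(pd.DataFrame({
            "tagID": row.tagID, "tagRole": row.tagRole,
            "time": times, "zID": row.zID,
        }))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["tagID", "time"], kind="mergesort").reset_index(drop=True)
    return RawRtlsTable(out)
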