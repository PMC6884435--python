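"""Plaintext construction of the nurse-patient facing-time table.

Phase 1 of the analysis: every (nurse period, patient period) pair that
shares a zone and overlaps in time contributes one interaction, classified
by the patient's type and the binned overlap duration.  Row i of the
resulting count matrix is the data point y(i) clustered in phase 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputFormatError
from .periods import Period, PeriodTable

__all__ = ["TimeBins", "FacingTable", "overlap", "bin_of", "build_table",
           "DEFAULT_BINS"]


@dataclass(frozen=True)
class TimeBins:
    """Duration classes for overlaps.

    ``boundaries`` are the inner bin edges TB (seconds), strictly
    increasing; bin b covers (TB[b-1], TB[b]] with TB[-1] = 0 and the last
    bin unbounded above.  Boundary values fall in the lower bin (an overlap
    of exactly 10 s is "0-10").
    """

    boundaries: tuple[int, ...] = (10, 30, 60)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) == 0:
            raise ConfigurationError("at least one bin boundary is required")
        if any(x <= 0 for x in b) or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigurationError("boundaries must be strictly increasing positives")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1

    def labels(self) -> list[str]:
        lo = (0,) + self.boundaries
        hi = self.boundaries + ("inf",)
        return [f"{a}-{b}" for a, b in zip(lo, hi)]


DEFAULT_BINS = TimeBins((10, 30, 60))


def overlap(a: Period, b: Period) -> int:
    """Temporal overlap min(et) - max(st), floored at 0; zones not checked."""
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def bin_of(ov: int, bins: TimeBins) -> int | None:
    """Bin index of a positive overlap, or None for ov <= 0."""
    if ov <= 0:
        return None
    idx = int(np.searchsorted(bins.boundaries, ov, side="left"))
    return idx  # == n_bins - 1 when ov exceeds every boundary


@dataclass
class FacingTable:
    """Per-nurse interaction counts by (patient type, overlap bin).

    ``counts`` is an Nn x m non-negative integer matrix with
    m = n_bins * n_types, columns type-major: column (t, b) = t * n_bins + b.
    """

    nurse_ids: list[str]
    type_labels: list[str]
    bins: TimeBins
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = (len(self.nurse_ids), len(self.type_labels) * self.bins.n_bins)
        if self.counts.shape != expected:
            raise ConfigurationError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )
        if (self.counts < 0).any():
            raise ConfigurationError("facing-time counts must be non-negative")

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def column_names(self) -> list[str]:
        return [f"{t}_{lab}" for t in self.type_labels for lab in self.bins.labels()]

    def points(self) -> list[tuple[int, ...]]:
        """Rows as integer tuples: the k-means data points."""
        return [tuple(int(v) for v in row) for row in self.counts]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.column_names())
        df.insert(0, "nID", self.nurse_ids)
        return df


def _patient_types(roles: pd.Series) -> pd.Series:
    split = roles.str.split(":", n=1)
    if (split.str.len() != 2).any() or (split.str[0] != "patient").any():
        bad = roles[(split.str.len() != 2) | (split.str[0] != "patient")].iloc[0]
        raise InputFormatError(f"patient period with non-patient role {bad!r}")
    return split.str[1]


def build_table(
    nurse_periods: PeriodTable,
    patient_periods: PeriodTable,
    bins: TimeBins,
    nurse_ids: list[str],
    type_labels: list[str],
) -> FacingTable:
    """Aggregate co-location overlaps into the facing-time table.

    For each (nurse period, patient period) pair in the same zone with
    positive temporal overlap, the cell (nurse, patient type, overlap bin)
    is incremented by one.  Counting is per period pair: a nurse who leaves
    and re-enters a patient's zone produces two separate interactions.
    """
    if nurse_periods.role_scope == "patients_only":
        raise InputFormatError("nurse_periods has patient scope")
    if patient_periods.role_scope == "nurses_only":
        raise InputFormatError("patient_periods has nurse scope")

    n_bins = bins.n_bins
    m = n_bins * len(type_labels)
    counts = np.zeros((len(nurse_ids), m), dtype=np.int64)
    nd, pdf = nurse_periods.df, patient_periods.df
    if len(nd) == 0 or len(pdf) == 0:
        return FacingTable(nurse_ids, type_labels, bins, counts)

    nurse_index = {t: i for i, t in enumerate(nurse_ids)}
    unknown = set(nd["tagID"]) - set(nurse_ids)
    if unknown:
        raise InputFormatError(f"unknown nurse tag(s) {sorted(unknown)}")
    type_index = {t: i for i, t in enumerate(type_labels)}
    ptypes = _patient_types(pdf["tagRole"])
    unknown_types = set(ptypes) - set(type_labels)
    if unknown_types:
        raise InputFormatError(f"unknown patient type(s) {sorted(unknown_types)}")

    n_st = nd["st"].to_numpy()[:, None]
    n_et = nd["et"].to_numpy()[:, None]
    n_zone = nd["zID"].to_numpy()[:, None]
    n_row = nd["tagID"].map(nurse_index).to_numpy()[:, None]
    p_st = pdf["st"].to_numpy()[None, :]
    p_et = pdf["et"].to_numpy()[None, :]
    p_zone = pdf["zID"].to_numpy()[None, :]
    p_type = ptypes.map(type_index).to_numpy()[None, :]

    ov = np.minimum(n_et, p_et) - np.maximum(n_st, p_st)
    hit = (n_zone == p_zone) & (ov > 0)
    if hit.any():
        ov_hit = ov[hit]
        bin_idx = np.searchsorted(np.asarray(bins.boundaries), ov_hit, side="left")
        col = np.broadcast_to(p_type, ov.shape)[hit] * n_bins + bin_idx
        row = np.broadcast_to(n_row, ov.shape)[hit]
        np.add.at(counts, (row, col), 1)
    return FacingTable(nurse_ids, type_labels, bins, counts)
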