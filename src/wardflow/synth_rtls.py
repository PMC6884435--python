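"""Synthetic real-time locating system (RTLS) data.

Emulates a hospital department in which tagged nurses and patients move
between zones, with tag reads on a fixed sampling grid.  The default
configuration mirrors the simulation conditions the method was evaluated
under: 15 zones, a one-hour study window sampled every 4 seconds, nurses
staying in a zone for at most 120 s, patients for up to the full hour, and
patients partitioned into types of 7 patients each.

Each tag's trajectory is a sequence of maximal stays: the zone is drawn
uniformly (consecutive stays land in distinct zones) and the stay duration
uniformly from the sampling-grid multiples up to the role's maximum.  The
generator returns both the raw grid records and the ground-truth stay
periods, so period extraction can be validated against the truth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .periods import PERIOD_COLUMNS, PeriodTable

__all__ = [
    "SimConfig",
    "RawRtlsTable",
    "generate_tracks",
    "split_views",
    "sample_period_table",
    "RAW_COLUMNS",
]

RAW_COLUMNS = ("tagID", "tagRole", "time", "zID")

NURSE_ROLE = "nurse"
PATIENT_PREFIX = "patient:"


def patient_type_labels(n: int) -> list[str]:
    """Type labels A, B, C, ... (AA, AB, ... past 26)."""
    letters = string.ascii_uppercase
    labels = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(label)
    return labels


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the evaluated study conditions."""

    n_nurses: int = 120
    n_patient_types: int = 5
    patients_per_type: int = 7
    n_zones: int = 15
    study_duration: int = 3600
    sample_interval: int = 4
    nurse_max_stay: int = 120
    patient_max_stay: int = 3600
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_nurses, self.n_patient_types, self.patients_per_type,
                  self.n_zones, self.study_duration, self.sample_interval,
                  self.nurse_max_stay, self.patient_max_stay)
        if any(c < 1 for c in counts):
            raise ConfigurationError("all counts and durations must be >= 1")
        if self.study_duration % self.sample_interval != 0:
            raise ConfigurationError(
                "study_duration must be a positive multiple of sample_interval"
            )
        if self.nurse_max_stay > self.study_duration:
            raise ConfigurationError("nurse_max_stay exceeds study_duration")
        if self.patient_max_stay > self.study_duration:
            raise ConfigurationError("patient_max_stay exceeds study_duration")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")

    @property
    def n_patients(self) -> int:
        return self.n_patient_types * self.patients_per_type

    def type_labels(self) -> list[str]:
        return patient_type_labels(self.n_patient_types)

    def nurse_ids(self) -> list[str]:
        width = len(str(self.n_nurses))
        return [f"N{i + 1:0{width}d}" for i in range(self.n_nurses)]


@dataclass
class RawRtlsTable:
    """Raw RTLS observations: one row per (tag, grid time)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RAW_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"raw RTLS table missing columns {missing}")
        self.df = self.df.loc[:, list(RAW_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def _tag_stays(rng: np.random.Generator, config: SimConfig, max_stay: int
               ) -> list[tuple[int, int, int]]:
    """One tag's trajectory as (start, end, zone) stays covering the study."""
    n_steps = max_stay // config.sample_interval
    stays: list[tuple[int, int, int]] = []
    t = 0
    prev_zone = 0  # zones are 1-based; 0 never collides
    while t < config.study_duration:
        zone = int(rng.integers(1, config.n_zones + 1))
        if config.n_zones > 1:
            while zone == prev_zone:
                zone = int(rng.integers(1, config.n_zones + 1))
        duration = int(rng.integers(1, n_steps + 1)) * config.sample_interval
        end = min(t + duration, config.study_duration)
        stays.append((t, end, zone))
        prev_zone = zone
        t = end
    return stays


def generate_tracks(config: SimConfig) -> tuple[RawRtlsTable, PeriodTable]:
    """Generate raw grid records and the ground-truth stay periods.

    Deterministic given ``config.seed``.  With ``dropout_rate`` > 0 a random
    subset of records is removed (periods are left untouched, so the ground
    truth then over-covers the records).
    """
    rng = np.random.default_rng(config.seed)
    delta = config.sample_interval
    type_labels = config.type_labels()

    tags: list[tuple[str, str, int]] = []  # (tag_id, role, max_stay)
    for nurse_id in config.nurse_ids():
        tags.append((nurse_id, NURSE_ROLE, config.nurse_max_stay))
    width = len(str(config.n_patients))
    i = 0
    for label in type_labels:
        for _ in range(config.patients_per_type):
            i += 1
            tags.append((f"P{i:0{width}d}", PATIENT_PREFIX + label, config.patient_max_stay))

    period_rows = []
    record_frames = []
    for tag_id, role, max_stay in tags:
        stays = _tag_stays(rng, config, max_stay)
        for st, et, zone in stays:
            period_rows.append((tag_id, st, et, zone, role))
        times = np.concatenate([np.arange(st, et, delta) for st, et, _ in stays])
        zones = np.concatenate(
            [np.full((et - st) // delta, zone, dtype=np.int64) for st, et, zone in stays]
        )
        record_frames.append(pd.DataFrame({
            "tagID": tag_id, "tagRole": role, "time": times, "zID": zones,
        }))

    records = pd.concat(record_frames, ignore_index=True)
    if config.dropout_rate > 0.0:
        keep = rng.random(len(records)) >= config.dropout_rate
        records = records.loc[keep].reset_index(drop=True)

    periods = pd.DataFrame(period_rows, columns=list(PERIOD_COLUMNS))
    return RawRtlsTable(records), PeriodTable(periods, role_scope="mixed")


def split_views(raw: RawRtlsTable) -> tuple[RawRtlsTable, RawRtlsTable]:
    """Partition raw records into the hospital (patients) and union (nurses) views."""
    is_nurse = raw.df["tagRole"] == NURSE_ROLE
    hospital = raw.df.loc[~is_nurse].reset_index(drop=True)
    union = raw.df.loc[is_nurse].reset_index(drop=True)
    return RawRtlsTable(hospital), RawRtlsTable(union)


def sample_period_table(
    rng: np.random.Generator,
    *,
    tag_ids: list[str],
    roles: list[str],
    n_periods: int,
    n_zones: int,
    study_duration: int,
    sample_interval: int = 4,
    max_stay: int | None = None,
) -> PeriodTable:
    """Directly sample a small valid period table (protocol-test plumbing).

    Draws ``n_periods`` grid-aligned stays spread over the given tags,
    keeping each tag's periods disjoint by carving them out of a forward
    sweep of its timeline.  ``roles[i]`` is the role label of ``tag_ids[i]``.
    """
    delta = sample_interval
    max_steps = (max_stay or study_duration) // delta
    rows = []
    cursors = {tag: 0 for tag in tag_ids}
    for _ in range(n_periods):
        order = rng.permutation(len(tag_ids))
        for j in order:
            tag = tag_ids[j]
            start_slot = cursors[tag] + int(rng.integers(0, 3))
            n_slots = int(rng.integers(1, max_steps + 1))
            st = start_slot * delta
            et = min(st + n_slots * delta, study_duration)
            if et <= st:
                continue
            zone = int(rng.integers(1, n_zones + 1))
            rows.append((tag, st, et, zone, roles[j]))
            cursors[tag] = et // delta
            break
        else:  # every tag's timeline is exhausted
            break
    df = pd.DataFrame(rows, columns=list(PERIOD_COLUMNS))
    scopes = {role.split(":")[0] for role in roles}
    scope = "nurses_only" if scopes == {"nurse"} else (
        "patients_only" if scopes == {"patient"} else "mixed")
    return PeriodTable(df, role_scope=scope)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: the same configuration with a different seed."""
    return replace(config, seed=seed)
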