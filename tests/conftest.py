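"""Shared fixtures and independent oracles for the wardflow test suite."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from wardflow.facing import TimeBins, bin_of
from wardflow.periods import PeriodTable
from wardflow.shares import Dealer, FieldSpec, TwoPartyEngine
from wardflow.synth_rtls import SimConfig, sample_period_table

# A tiny field for exhaustive gate checks: p=101, kappa=1, l=4 keeps the
# masked comparison opening (2^5 + 2^6 = 96) below p.
SMALL_FIELD = FieldSpec(p=101, stat_sec=1, comparison_bitlen=4)


@pytest.fixture
def small_engine():
    return TwoPartyEngine(SMALL_FIELD, Dealer(SMALL_FIELD, seed=42), share_seed=7)


@pytest.fixture
def prod_engine():
    from wardflow.shares import FIELD_PRESETS
    field = FIELD_PRESETS["p127"]
    return TwoPartyEngine(field, Dealer(field, seed=42), share_seed=7)


@pytest.fixture
def tiny_sim():
    return SimConfig(n_nurses=3, n_patient_types=2, patients_per_type=2,
                     n_zones=4, study_duration=120, sample_interval=4,
                     nurse_max_stay=24, patient_max_stay=120, seed=5)


@pytest.fixture
def default_bins():
    return TimeBins((10, 30, 60))


def exact_sq_distance(y, centroid) -> Fraction:
    """Exact rational squared Euclidean distance to a rational centroid."""
    w = centroid.denominator
    return sum((Fraction(yi) - Fraction(x, w)) ** 2
               for yi, x in zip(y, centroid.numerators))


def facing_table_oracle(nurse_periods: PeriodTable, patient_periods: PeriodTable,
                        bins: TimeBins, nurse_ids, type_labels, sample_interval=4):
    """Independent per-grid-slot co-location oracle for the facing table.

    For each (nurse period, patient period) pair, walks the sampling grid
    and counts the slots where both periods cover the slot in the same
    zone; slots * interval is the overlap, binned and accumulated.  Pure
    double loop, no shared code with the implementation.
    """
    n_bins = bins.n_bins
    counts = np.zeros((len(nurse_ids), n_bins * len(type_labels)), dtype=np.int64)
    nurse_row = {t: i for i, t in enumerate(nurse_ids)}
    type_col = {t: i for i, t in enumerate(type_labels)}
    for np_ in nurse_periods.to_periods():
        for pp in patient_periods.to_periods():
            if np_.zone_id != pp.zone_id:
                continue
            slots = 0
            t = min(np_.start, pp.start)
            while t < max(np_.end, pp.end):
                if np_.start <= t < np_.end and pp.start <= t < pp.end:
                    slots += 1
                t += sample_interval
            ov = slots * sample_interval
            b = bin_of(ov, bins)
            if b is not None:
                ptype = pp.tag_role.split(":", 1)[1]
                counts[nurse_row[np_.tag_id], type_col[ptype] * n_bins + b] += 1
    return counts


def random_instance(rng: np.random.Generator, *, n_nurses, n_types,
                    max_periods=8, n_zones=4, study_duration=240):
    """A random small two-party instance (nurse and patient period tables)."""
    nurse_ids = [f"N{i}" for i in range(n_nurses)]
    type_labels = [chr(ord("A") + i) for i in range(n_types)]
    patient_ids = [f"P{i}" for i in range(n_types * 2)]
    patient_roles = [f"patient:{type_labels[i % n_types]}"
                     for i in range(len(patient_ids))]
    nurse_tab = sample_period_table(
        rng, tag_ids=nurse_ids, roles=["nurse"] * n_nurses,
        n_periods=int(rng.integers(1, max_periods + 1)), n_zones=n_zones,
        study_duration=study_duration, max_stay=60,
    )
    patient_tab = sample_period_table(
        rng, tag_ids=patient_ids, roles=patient_roles,
        n_periods=int(rng.integers(1, max_periods + 1)), n_zones=n_zones,
        study_duration=study_duration,
    )
    return nurse_ids, type_labels, nurse_tab, patient_tab
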