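"""Secure protocol: plaintext equivalence, obliviousness, budget planning."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_instance
from wardflow.cluster import KMeansConfig, kmeans, sample_centroid_indices
from wardflow.errors import BudgetError, ConfigurationError
from wardflow.facing import FacingTable, TimeBins, build_table
from wardflow.periods import PeriodTable
from wardflow.secure_flow import (
    CircuitShape,
    plan_budget,
    secure_build_table,
    secure_kmeans,
    share_period_table,
)
from wardflow.shares import FIELD_PRESETS, Dealer, TwoPartyEngine

BINS = TimeBins((10, 30, 60))


def _engine(seed=0, **kw):
    field = FIELD_PRESETS["p127"]
    return TwoPartyEngine(field, Dealer(field, seed=seed + 1), share_seed=seed, **kw)


def _pt(rows, scope):
    df = pd.DataFrame(rows, columns=["tagID", "st", "et", "zID", "tagRole"])
    return PeriodTable(df, role_scope=scope)


def _reveal_table(engine, shared):
    return np.array([[engine.field.signed((c.share_0 + c.share_1) % engine.field.p)
                      for c in row] for row in shared.cells])


def test_secure_table_single_pair_matches_plaintext():
    nurses = _pt([("n1", 100, 140, 3, "nurse")], "nurses_only")
    patients = _pt([("p1", 120, 200, 3, "patient:A")], "patients_only")
    plain = build_table(nurses, patients, BINS, ["n1"], ["A", "B"])
    e = _engine(1)
    sn = share_period_table(e, nurses, nurse_ids=["n1"])
    sp = share_period_table(e, patients, type_labels=["A", "B"])
    shared = secure_build_table(e, sn, sp, BINS, ["n1"], ["A", "B"], time_bound=3600)
    assert np.array_equal(_reveal_table(e, shared), plain.counts)


def test_secure_table_empty_side_is_zero():
    nurses = _pt([("n1", 0, 40, 1, "nurse")], "nurses_only")
    patients = _pt([], "patients_only")
    e = _engine(2)
    sn = share_period_table(e, nurses, nurse_ids=["n1"])
    sp = share_period_table(e, patients, type_labels=["A"])
    shared = secure_build_table(e, sn, sp, BINS, ["n1"], ["A"], time_bound=240)
    assert _reveal_table(e, shared).sum() == 0


@pytest.mark.parametrize("mode", ["public", "oblivious"])
def test_secure_table_random_instances_match_plaintext(mode):
    rng = np.random.default_rng(31)
    reps = 6 if mode == "public" else 2
    for _ in range(reps):
        nurse_ids, type_labels, ntab, ptab = random_instance(
            rng, n_nurses=int(rng.integers(2, 4)), n_types=2, max_periods=5)
        plain = build_table(ntab, ptab, BINS, nurse_ids, type_labels)
        e = _engine(int(rng.integers(0, 1000)))
        sn = share_period_table(e, ntab, nurse_ids=nurse_ids, mode=mode)
        sp = share_period_table(e, ptab, type_labels=type_labels, mode=mode)
        shared = secure_build_table(e, sn, sp, BINS, nurse_ids, type_labels,
                                    time_bound=240)
        assert np.array_equal(_reveal_table(e, shared), plain.counts)


def _shared_facing(engine, counts, nurse_ids, type_labels, y_bound):
    cells = [[engine.share(int(v)) for v in row] for row in counts]
    from wardflow.secure_flow import SharedFacingTable
    return SharedFacingTable(cells, nurse_ids, type_labels, BINS, y_bound=y_bound)


def test_secure_kmeans_four_point_fixture():
    counts = np.zeros((4, 8), dtype=np.int64)
    counts[:, :2] = [(0, 0), (0, 2), (10, 10), (10, 12)]
    points = [tuple(int(v) for v in row) for row in counts]
    seed = next(s for s in range(2000)
                if sample_centroid_indices(4, 2, s) == (0, 2))
    cfg = KMeansConfig(k=2, iterations=2, seed=seed)
    plain = kmeans(points, cfg)
    e = _engine(4)
    table = _shared_facing(e, counts, [f"n{i}" for i in range(4)], ["A", "B"], 12)
    M, conv = secure_kmeans(e, table, cfg)
    assert M.tolist() == [[1, 0], [1, 0], [0, 1], [0, 1]]
    assert conv == 1 == plain.converged
    assert np.array_equal(M, plain.membership)


def test_secure_kmeans_k1_all_ones():
    counts = np.arange(8, dtype=np.int64).reshape(1, 8).repeat(3, axis=0)
    e = _engine(5)
    table = _shared_facing(e, counts, ["a", "b", "c"], ["A", "B"], 8)
    M, conv = secure_kmeans(e, table, KMeansConfig(k=1, iterations=2, seed=0))
    assert M.tolist() == [[1], [1], [1]]
    assert conv == 1


def test_secure_kmeans_random_instances_match_plaintext():
    rng = np.random.default_rng(17)
    for trial in range(8):
        n = int(rng.integers(3, 8))
        k = int(rng.integers(1, 4))
        if k > n:
            k = n
        counts = rng.integers(0, 6, size=(n, 8)).astype(np.int64)
        points = [tuple(int(v) for v in row) for row in counts]
        cfg = KMeansConfig(k=k, iterations=2, seed=int(rng.integers(0, 500)))
        plain = kmeans(points, cfg)
        e = _engine(100 + trial)
        table = _shared_facing(e, counts, [f"n{i}" for i in range(n)],
                               ["A", "B"], y_bound=6)
        M, conv = secure_kmeans(e, table, cfg)
        assert np.array_equal(M, plain.membership)
        assert conv == plain.converged


def test_secure_kmeans_rejects_k_above_n():
    e = _engine(6)
    table = _shared_facing(e, np.zeros((2, 8), dtype=np.int64), ["a", "b"],
                           ["A", "B"], 1)
    with pytest.raises(ConfigurationError):
        secure_kmeans(e, table, KMeansConfig(k=3, iterations=1, seed=0))


def test_budget_denominator_growth_bound():
    shape = CircuitShape(Nn=4, Nptype=2, Ntimebins=4, nP=1, pP=1, k=2,
                         iterations=2)
    budget = plan_budget(shape, y_bound=1)
    # After two rounds the shared denominator is bounded by (Nn + 1)^2 = 25.
    assert budget.max_score_operand >= 1
    x_b, w_b = 1, 1
    for _ in range(2):
        x_b, w_b = w_b * 4 * 1 + x_b, w_b * 5
    assert w_b == 25


def test_budget_counts_match_runtime_consumption():
    rng = np.random.default_rng(23)
    nurse_ids, type_labels, ntab, ptab = random_instance(
        rng, n_nurses=3, n_types=2, max_periods=4)
    shape = CircuitShape(Nn=3, Nptype=2, Ntimebins=4, nP=len(ntab),
                         pP=len(ptab), k=2, iterations=2)
    budget = plan_budget(shape, time_bound=240)
    e = _engine(9)
    sn = share_period_table(e, ntab, nurse_ids=nurse_ids)
    sp = share_period_table(e, ptab, type_labels=type_labels)
    shared = secure_build_table(e, sn, sp, BINS, nurse_ids, type_labels,
                                time_bound=240)
    shared.y_bound = budget.y_bound
    secure_kmeans(e, shared, KMeansConfig(k=2, iterations=2, seed=1))
    got = e.dealer.counters()
    assert got["triples"] == budget.triples
    assert got["random_bits"] == budget.random_bits
    assert got["bounded_masks"] == budget.bounded_masks
    assert got["nonzero_masks"] == budget.nonzero_masks


def test_64bit_field_rejected_at_full_scale():
    # 64-bit field, 5 iterations, 120 nurses: worst-case score comparisons
    # cannot fit the ~21-bit comparison headroom.
    shape = CircuitShape(Nn=120, Nptype=5, Ntimebins=4, nP=7000, pP=100,
                         k=5, iterations=5)
    budget = plan_budget(shape)
    with pytest.raises(BudgetError):
        budget.check(FIELD_PRESETS["p64"])


def test_obliviousness_traces_and_reveals():
    """Gate traces depend only on shape; reveals are outputs only."""
    traces, reveal_labels = [], []
    for variant in range(2):
        # Same shape (2 nurse periods, 2 patient periods), different secrets.
        if variant == 0:
            ntab = _pt([("n1", 0, 40, 1, "nurse"), ("n2", 48, 120, 2, "nurse")],
                       "nurses_only")
            ptab = _pt([("p1", 0, 20, 1, "patient:A"),
                        ("p2", 40, 104, 2, "patient:B")], "patients_only")
        else:
            ntab = _pt([("n1", 80, 200, 3, "nurse"), ("n2", 0, 16, 1, "nurse")],
                       "nurses_only")
            ptab = _pt([("p1", 100, 240, 3, "patient:B"),
                        ("p2", 0, 240, 1, "patient:A")], "patients_only")
        e = _engine(40 + variant, record_gates=True)
        sn = share_period_table(e, ntab, nurse_ids=["n1", "n2"])
        sp = share_period_table(e, ptab, type_labels=["A", "B"])
        shared = secure_build_table(e, sn, sp, BINS, ["n1", "n2"], ["A", "B"],
                                    time_bound=240)
        secure_kmeans(e, shared, KMeansConfig(k=2, iterations=2, seed=3))
        traces.append(e.gate_trace)
        reveal_labels.append([label for label, _ in e.reveals])
    assert traces[0] == traces[1]
    assert set(reveal_labels[0]) == {"membership", "converged"}
    assert reveal_labels[0] == reveal_labels[1]
    # Exactly Nn*k membership reveals plus one convergence bit.
    assert reveal_labels[0].count("membership") == 4
    assert reveal_labels[0].count("converged") == 1
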