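"""The joint two-party protocol: secure table construction and secure k-means.

Mirrors :mod:`wardflow.facing` and :mod:`wardflow.cluster` gate for gate in
the secret-shared domain.  The central guarantee, enforced by the test
suite, is exact equivalence: revealing the secure pipeline's output yields
bit-for-bit the plaintext pipeline's output for the same inputs and seed.

Control flow is oblivious: the sequence of gate invocations depends only on
public shape parameters (period counts, Nn, number of types and bins, k,
iteration count), never on secret values.  The only values ever revealed
are the final membership matrix, the convergence bit, and the statistically
masked openings inside multiplication and comparison gates.

Because shares cannot be reduced by a gcd, centroid denominators grow by a
factor n_j + 1 <= Nn + 1 every iteration; :func:`plan_budget` bounds the
worst-case bit growth of every wire class up front and the entry points
refuse to run a circuit whose comparisons could overflow the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import KMeansConfig, sample_centroid_indices
from .errors import BudgetError, ConfigurationError, InputFormatError
from .facing import TimeBins
from .periods import PeriodTable
from .shares import SharedValue, TwoPartyEngine

__all__ = [
    "SharedPeriodRow",
    "SharedPeriodTable",
    "SharedFacingTable",
    "CircuitShape",
    "CircuitBudget",
    "share_period_table",
    "secure_build_table",
    "secure_kmeans",
    "plan_budget",
]


@dataclass(frozen=True)
class SharedPeriodRow:
    """One secret-shared period: times and zone shared, addressing public.

    In the default addressing mode the nurse's pseudonymous row index (for
    nurse periods) or the patient's type index (for patient periods) is
    public metadata; in oblivious mode it is replaced by a shared one-hot
    vector and ``index`` is None.
    """

    st: SharedValue
    et: SharedValue
    zid: SharedValue
    owner: str  # "hospital" | "union"
    index: int | None  # nurse row index or patient type index
    onehot: tuple[SharedValue, ...] | None = None


@dataclass
class SharedPeriodTable:
    rows: list[SharedPeriodRow]
    scope: str  # nurses_only | patients_only
    mode: str = "public"  # public | oblivious
    n_slots: int = 0  # Nn (nurse scope) or Nptype (patient scope)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SharedFacingTable:
    """Nn x m matrix of shared counts; layout and ordering are public."""

    cells: list[list[SharedValue]]
    nurse_ids: list[str]
    type_labels: list[str]
    bins: TimeBins
    y_bound: int  # public worst-case bound on any cell value

    @property
    def m(self) -> int:
        return self.bins.n_bins * len(self.type_labels)


@dataclass(frozen=True)
class CircuitShape:
    """The public quantities that determine the circuit."""

    Nn: int
    Nptype: int
    Ntimebins: int
    nP: int
    pP: int
    k: int
    iterations: int


@dataclass
class CircuitBudget:
    """Worst-case wire bounds and exact preprocessing counts for a circuit."""

    time_bitlen: int  # comparison class: times, overlaps, bin boundaries
    score_bitlen: int  # comparison class: w~^2 s - w^2 s~ operands
    y_bound: int
    max_score_operand: int
    triples: int
    random_bits: int
    bounded_masks: int
    nonzero_masks: int

    def required_bitlen(self) -> int:
        return max(self.time_bitlen, self.score_bitlen)

    def check(self, field) -> None:
        """Raise BudgetError unless every comparison fits the field."""
        for name, bits in (("time", self.time_bitlen), ("score", self.score_bitlen)):
            if 2 ** (bits + 1) + 2 ** (bits + 1 + field.stat_sec) >= field.p:
                raise BudgetError(
                    f"{name}-comparison class needs {bits} bits; field of "
                    f"{field.p.bit_length()} bits with kappa={field.stat_sec} "
                    "has insufficient headroom"
                )


def _lt_cost(bitlen: int) -> tuple[int, int, int]:
    c = TwoPartyEngine.lt_cost(bitlen)
    return c["triples"], c["random_bits"], c["bounded_masks"]


def plan_budget(shape: CircuitShape, *, time_bound: int = 3600,
                y_bound: int | None = None) -> CircuitBudget:
    """Worst-case bit bounds and exact dealer-tape counts for the pipeline.

    ``y_bound`` is the public bound on any facing-table cell; by default the
    total pair count nP*pP (every pair could land in one cell).  Returns the
    budget; callers compare it against a FieldSpec via :meth:`CircuitBudget.check`.
    """
    nb = shape.Ntimebins
    m = nb * shape.Nptype
    if y_bound is None:
        y_bound = max(1, shape.nP * shape.pP)
    time_bitlen = (2 * time_bound).bit_length() + 1

    # Centroid growth across iterations (no gcd reduction on shares).
    x_b, w_b = y_bound, 1
    cmp_bound = 1
    for _ in range(shape.iterations):
        s_b = m * (x_b * x_b + 2 * w_b * x_b * y_bound)
        cmp_bound = max(cmp_bound, w_b * w_b * s_b)
        x_b = w_b * shape.Nn * y_bound + x_b
        w_b = w_b * (shape.Nn + 1)
    score_bitlen = cmp_bound.bit_length() + 2

    # Phase 1 per pair: eq(2 lt + 1 mul) + smin(lt + 2) + smax(lt + 2)
    # + bin indicators (2 lt + 1 mul per inner bin, 1 lt for the last)
    # + z*indicator (nb muls).
    lt_t, lt_b, lt_m = _lt_cost(time_bitlen)
    pair_lt = 2 + 1 + 1 + (2 * (nb - 1) + 1)
    pair_mul = 1 + 2 + 2 + (nb - 1) + nb
    pairs = shape.nP * shape.pP
    triples = pairs * (pair_mul + pair_lt * lt_t)
    bits = pairs * pair_lt * lt_b
    bounded = pairs * pair_lt * lt_m
    nonzero = 0

    # Phase 2 per iteration.
    s_lt_t, s_lt_b, s_lt_m = _lt_cost(score_bitlen)
    Nn, k = shape.Nn, shape.k
    per_iter_mul = (
        2 * k * m            # x^2 and w*x per centroid component
        + k                  # w^2
        + Nn * k * m         # t * y score terms
        + Nn * k * (k - 1) * 2   # xi operand products
        + Nn * k * max(k - 2, 0)  # raw membership products
        + 2 * Nn * k         # uniqueness pass
        + Nn * k * m         # cluster sums M*y
        + k * m              # w * sum
        + k                  # w' = w * (n_j + 1)
    )
    per_iter_lt = Nn * k * (k - 1)
    triples += shape.iterations * (per_iter_mul + per_iter_lt * s_lt_t)
    bits += shape.iterations * per_iter_lt * s_lt_b
    bounded += shape.iterations * per_iter_lt * s_lt_m
    if shape.iterations >= 2:
        triples += Nn * k + 1  # convergence squares + the zero-test masking
        nonzero += 1

    return CircuitBudget(
        time_bitlen=time_bitlen,
        score_bitlen=score_bitlen,
        y_bound=y_bound,
        max_score_operand=cmp_bound,
        triples=triples,
        random_bits=bits,
        bounded_masks=bounded,
        nonzero_masks=nonzero,
    )


def secure_pipeline_from_periods(
    nurse_tab: PeriodTable,
    patient_tab: PeriodTable,
    bins: TimeBins,
    nurse_ids: list[str],
    type_labels: list[str],
    km_config: KMeansConfig,
    *,
    time_bound: int,
    share_seed: int = 0,
    addressing: str = "public",
    field=None,
    record_gates: bool = False,
):
    """Run both secure phases on plaintext period tables (shared on entry).

    Plans the circuit budget, picks the smallest adequate field preset when
    ``field`` is None, and returns (membership, converged, engine).
    """
    from .shares import field_for_budget

    shape = CircuitShape(Nn=len(nurse_ids), Nptype=len(type_labels),
                         Ntimebins=bins.n_bins, nP=len(nurse_tab),
                         pP=len(patient_tab), k=km_config.k,
                         iterations=km_config.iterations)
    budget = plan_budget(shape, time_bound=time_bound)
    if field is None:
        field = field_for_budget(budget.required_bitlen())
    budget.check(field)
    engine = TwoPartyEngine(field, share_seed=share_seed,
                            record_gates=record_gates)
    shared_nurse = share_period_table(engine, nurse_tab, nurse_ids=nurse_ids,
                                      mode=addressing)
    shared_patient = share_period_table(engine, patient_tab,
                                        type_labels=type_labels, mode=addressing)
    shared_table = secure_build_table(engine, shared_nurse, shared_patient,
                                      bins, nurse_ids, type_labels,
                                      time_bound=time_bound)
    membership, converged = secure_kmeans(engine, shared_table, km_config)
    return membership, converged, engine


def share_period_table(
    engine: TwoPartyEngine,
    periods: PeriodTable,
    *,
    nurse_ids: list[str] | None = None,
    type_labels: list[str] | None = None,
    mode: str = "public",
) -> SharedPeriodTable:
    """Secret-share a party's period table, keeping addressing metadata public."""
    if periods.role_scope == "nurses_only":
        if nurse_ids is None:
            raise InputFormatError("nurse periods need the public nurse ordering")
        lookup = {t: i for i, t in enumerate(nurse_ids)}
        owner, n_slots = "union", len(nurse_ids)
    elif periods.role_scope == "patients_only":
        if type_labels is None:
            raise InputFormatError("patient periods need the public type labels")
        lookup = {t: i for i, t in enumerate(type_labels)}
        owner, n_slots = "hospital", len(type_labels)
    else:
        raise InputFormatError("shared period tables must be single-scope")

    rows = []
    for p in periods.to_periods():
        key = p.tag_id if owner == "union" else p.tag_role.split(":", 1)[1]
        if key not in lookup:
            raise InputFormatError(f"unlisted identifier {key!r} in period table")
        idx = lookup[key]
        onehot = None
        public_idx: int | None = idx
        if mode == "oblivious":
            onehot = tuple(engine.share(1 if i == idx else 0) for i in range(n_slots))
            public_idx = None
        rows.append(SharedPeriodRow(
            st=engine.share(p.start), et=engine.share(p.end),
            zid=engine.share(p.zone_id), owner=owner, index=public_idx,
            onehot=onehot,
        ))
    return SharedPeriodTable(rows, scope=periods.role_scope, mode=mode,
                             n_slots=n_slots)


def secure_build_table(
    engine: TwoPartyEngine,
    nurse: SharedPeriodTable,
    patient: SharedPeriodTable,
    bins: TimeBins,
    nurse_ids: list[str],
    type_labels: list[str],
    *,
    time_bound: int = 3600,
) -> SharedFacingTable:
    """Secure phase 1: shared facing-time table from shared period tables.

    For every (patient period, nurse period) pair the circuit evaluates
    zone equality, the shared overlap min(et) - max(st), and one shared
    indicator per time bin; the product is accumulated into the cell
    addressed by the (public or one-hot shared) nurse index and patient
    type.  Revealing the result equals the plaintext ``build_table``.
    """
    if nurse.scope != "nurses_only" or patient.scope != "patients_only":
        raise InputFormatError("scope mismatch between shared period tables")
    bitlen = (2 * time_bound).bit_length() + 1
    if 2 ** (bitlen + 1) + 2 ** (bitlen + 1 + engine.field.stat_sec) >= engine.field.p:
        raise BudgetError("time comparisons do not fit the chosen field")

    n_bins = bins.n_bins
    m = n_bins * len(type_labels)
    zero = engine.share_public(0)
    cells = [[zero for _ in range(m)] for _ in range(len(nurse_ids))]
    tb = bins.boundaries

    for prow in patient.rows:
        for nrow in nurse.rows:
            z = engine.eq(prow.zid, nrow.zid, bitlen)
            ov = engine.sub(
                engine.smin(prow.et, nrow.et, bitlen),
                engine.smax(prow.st, nrow.st, bitlen),
            )
            indicators = []
            for b in range(n_bins):
                if b < n_bins - 1:
                    lo = 0 if b == 0 else tb[b - 1]
                    above = engine.ge(ov, engine.share_public(lo + 1), bitlen)
                    below = engine.ge(engine.share_public(tb[b]), ov, bitlen)
                    indicators.append(engine.mul(above, below))
                else:
                    indicators.append(
                        engine.ge(ov, engine.share_public(tb[-1] + 1), bitlen)
                    )
            contributions = [engine.mul(z, ind) for ind in indicators]
            for b, contrib in enumerate(contributions):
                if nurse.mode == "public" and patient.mode == "public":
                    col = prow.index * n_bins + b
                    cells[nrow.index][col] = engine.add(cells[nrow.index][col], contrib)
                else:
                    for ni in range(len(nurse_ids)):
                        n_sel = (nrow.onehot[ni] if nrow.onehot is not None
                                 else engine.share_public(1 if ni == nrow.index else 0))
                        picked = engine.mul(contrib, n_sel)
                        for ti in range(len(type_labels)):
                            t_sel = (prow.onehot[ti] if prow.onehot is not None
                                     else engine.share_public(
                                         1 if ti == prow.index else 0))
                            cell = engine.mul(picked, t_sel)
                            col = ti * n_bins + b
                            cells[ni][col] = engine.add(cells[ni][col], cell)

    return SharedFacingTable(cells, nurse_ids, type_labels, bins,
                             y_bound=max(1, len(nurse.rows) * len(patient.rows)))


def secure_kmeans(
    engine: TwoPartyEngine,
    table: SharedFacingTable,
    config: KMeansConfig,
) -> tuple[np.ndarray, int]:
    """Secure phase 2: k-means over the shared facing table.

    Initial centroid indices are chosen publicly (by the hospital) from the
    seed; scores, comparison bits, membership entries, cluster sizes and
    centroid numerators/denominators all remain shared throughout.  Only
    the final tie-broken membership matrix and a one-bit convergence flag
    (a masked zero-test of the squared difference of the last two
    membership matrices) are revealed.
    """
    Nn, m, k = len(table.cells), table.m, config.k
    if k > Nn:
        raise ConfigurationError(f"k={k} exceeds Nn={Nn}")
    shape = CircuitShape(Nn=Nn, Nptype=len(table.type_labels),
                         Ntimebins=table.bins.n_bins, nP=1, pP=1,
                         k=k, iterations=config.iterations)
    budget = plan_budget(shape, y_bound=table.y_bound)
    if 2 ** (budget.score_bitlen + 1) + \
            2 ** (budget.score_bitlen + 1 + engine.field.stat_sec) >= engine.field.p:
        raise BudgetError(
            f"score comparisons need {budget.score_bitlen} bits; "
            "choose a wider field or fewer iterations"
        )
    bitlen = budget.score_bitlen

    points = table.cells
    indices = sample_centroid_indices(Nn, k, config.seed)
    cent_x = [[points[i][l] for l in range(m)] for i in indices]
    cent_w = [engine.share_public(1) for _ in range(k)]

    one = engine.share_public(1)
    members_prev: list[list[SharedValue]] | None = None
    members: list[list[SharedValue]] | None = None
    for _ in range(config.iterations):
        # Scores s(y_i, c_j) = sum_l (x^2 - 2 (w x) y): shared throughout.
        x_sq = [[engine.mul(cent_x[j][l], cent_x[j][l]) for l in range(m)]
                for j in range(k)]
        wx = [[engine.mul(cent_w[j], cent_x[j][l]) for l in range(m)]
              for j in range(k)]
        w_sq = [engine.mul(cent_w[j], cent_w[j]) for j in range(k)]
        scores = []
        for i in range(Nn):
            row = []
            for j in range(k):
                acc = engine.share_public(0)
                for l in range(m):
                    term = engine.sub(
                        x_sq[j][l],
                        engine.mul_const(engine.mul(wx[j][l], points[i][l]), 2),
                    )
                    acc = engine.add(acc, term)
                row.append(acc)
            scores.append(row)

        # xi(i, j, j') = [ w_{j'}^2 s_ij <= w_j^2 s_ij' ], lowest-index ties.
        members_prev = members
        members = []
        for i in range(Nn):
            raw = []
            for j in range(k):
                xis = []
                for j2 in range(k):
                    if j2 == j:
                        continue
                    lhs = engine.mul(w_sq[j2], scores[i][j])
                    rhs = engine.mul(w_sq[j], scores[i][j2])
                    xis.append(engine.ge(rhs, lhs, bitlen))
                bit = one if not xis else xis[0]
                for xi in xis[1:]:
                    bit = engine.mul(bit, xi)
                raw.append(bit)
            row = []
            none_before = one
            for j in range(k):
                m_ij = engine.mul(raw[j], none_before)
                row.append(m_ij)
                none_before = engine.mul(none_before, engine.sub(one, m_ij))
            members.append(row)

        # Division-free centroid update on shares.
        new_x = []
        new_w = []
        for j in range(k):
            n_j = engine.share_public(0)
            for i in range(Nn):
                n_j = engine.add(n_j, members[i][j])
            sums = []
            for l in range(m):
                acc = engine.share_public(0)
                for i in range(Nn):
                    acc = engine.add(acc, engine.mul(members[i][j], points[i][l]))
                sums.append(acc)
            new_x.append([
                engine.add(engine.mul(cent_w[j], sums[l]), cent_x[j][l])
                for l in range(m)
            ])
            new_w.append(engine.mul(cent_w[j], engine.add_const(n_j, 1)))
        cent_x, cent_w = new_x, new_w

    # Convergence: masked zero-test of sum (M_T - M_{T-1})^2; one bit leaks.
    if members_prev is not None:
        diff_sq = engine.share_public(0)
        for i in range(Nn):
            for j in range(k):
                d = engine.sub(members[i][j], members_prev[i][j])
                diff_sq = engine.add(diff_sq, engine.mul(d, d))
        mask = engine.dealer.random_nonzero()
        opened = engine.reveal(engine.mul(diff_sq, mask), label="converged")
        converged = int(opened == 0)
    else:
        converged = 0

    revealed = np.zeros((Nn, k), dtype=np.int64)
    for i in range(Nn):
        for j in range(k):
            revealed[i, j] = engine.reveal(members[i][j], label="membership")
    return revealed, converged
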