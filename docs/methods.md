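# Methods

This note documents the models, conventions and design choices behind
`wardflow`, in the order the pipeline runs.

## Synthetic RTLS data

The generator emulates an instrumented hospital department: every tagged
person (nurse or patient) reports a `(tagID, tagRole, time, zID)` record at
every tick of a fixed sampling grid. Default parameters are the study
conditions the method was evaluated under:

| parameter | default | meaning |
|---|---|---|
| `n_zones` | 15 | zones (rooms/areas) of the department |
| `study_duration` | 3600 s | one-hour observation window |
| `sample_interval` (Δ) | 4 s | RTLS reporting period |
| `n_nurses` | 120 | nurses (the clustered individuals) |
| `n_patient_types` × `patients_per_type` | 5 × 7 | patients, typed by condition |
| `nurse_max_stay` | 120 s | longest stay of a nurse in one zone |
| `patient_max_stay` | 3600 s | patients may stay put for the whole hour |

A trajectory is a sequence of stays: each stay's zone is uniform over the
zones (consecutive stays forced distinct, so stays are maximal), and its
duration is uniform over the grid multiples {Δ, 2Δ, …, max_stay}, truncated
at the end of the study. Only the maxima are externally constrained; the
uniform duration law is this package's choice — the simplest distribution
satisfying them. The generator returns ground-truth stay periods alongside
the records, which the tests use to validate period extraction. An optional
`dropout_rate` deletes records at random to exercise gap handling.

What this emulates — realistic zone-stay durations, role asymmetry between
nurses and patients, dense pairwise co-location — is what the analysis is
sensitive to. What it does not emulate: spatial topology (zone transitions
are uniform, not adjacency-constrained), correlated movement (nurses do not
seek out patients), RTLS signal noise. Passing tests therefore show the
*computation* is correct on data of realistic shape and scale, not that the
clustering is clinically meaningful.

## Periods

`extract_periods` merges consecutive same-zone records at grid distance Δ
into half-open periods `[first, last + Δ)`. Two conventions are ours:

* **End time = last observation + Δ.** A tag observed at an instant is
  taken to occupy the zone for that full sampling slot. This makes overlap
  equal to (shared slots) × Δ and avoids zero-length periods.
* **Gaps close periods.** A missing sample splits the stay rather than
  bridging it: absence of evidence of presence is treated conservatively.

`periods_to_grid` is the exact inverse on dropout-free data and serves as
the round-trip oracle.

## Facing-time table

The interaction unit is the *period pair*: each (nurse period, patient
period) with equal zone and positive overlap counts once, in the column
given by the patient's type and the overlap's duration bin. A nurse who
leaves and re-enters a patient's zone thus logs two shorter interactions,
which is the intended reading of frequency-and-length profiling.

Bins are left-open right-closed, `(TB[b-1], TB[b]]`, with the last bin
unbounded: an overlap of exactly 10 s falls in the 0–10 bin. Overlaps of
exactly 0 (touching half-open intervals) are not interactions.

## k-means variant

Data points are non-negative integer vectors, which enables an all-integer
algorithm:

* **Rational centroids** `c = x/w`. Initial centroids are k data points
  drawn uniformly without replacement (seeded; the draw is public — in the
  two-party setting the hospital makes it). Sampling *without* replacement
  avoids coincident initial centroids; with k ≤ Nn it is always possible.
* **Score-based comparison.** `s(y,c) = Σ(xₗ² − 2w xₗ yₗ)` satisfies
  `d² = Σyₗ² + s/w²`, so `d²(y,c) ≤ d²(y,c̃) ⟺ w̃²s(y,c) ≤ w²s(y,c̃)` —
  an exact integer test, no division or floats anywhere.
* **Assignment** is the product form `M_ij = Π_j′ ξ(i,j,j′)` with
  ξ the pairwise comparison bit, followed by the uniqueness pass
  `M_ij ← M_ij · Π_{j′<j}(1 − M_ij′)`. This realises "ties go to the lowest
  index" as pure arithmetic on bits, which is what makes it portable to the
  share domain unchanged.
* **Update** `x′ = w·Σᵢ M_ij y⁽ⁱ⁾ + x`, `w′ = w(n_j + 1)`: the new centroid
  is the mean of the cluster's members *plus its own previous centroid*.
  This removes the division and simultaneously makes empty clusters benign
  (n_j = 0 leaves the centroid exactly unchanged), at the cost of a mild
  drag toward the previous centroid. A `strict_lloyd` mode with plain means
  (empty clusters frozen) exists as a testing aid; its within-cluster sum
  of squares is provably non-increasing and tested as such.
* **Fixed iterations, one convergence check.** The iteration count is a
  parameter (5 in the evaluated setting); convergence is checked only once,
  after the last iteration, by comparing the final two membership matrices.
  With a single iteration there is nothing to compare and the flag is 0.
* **Outputs**: membership matrix and convergence bit only. Centroids are
  never returned — in the secure setting they are aggregates that could
  identify individuals.

The plaintext path reduces each centroid fraction by its gcd after every
update. This is pure representation hygiene (the value x/w is unchanged, so
assignments are unchanged); the secure path cannot do it, which is why
denominators there grow and a budget planner is needed.

## Secret-sharing engine

Integers in `[-M, M]` are embedded in 𝔽_p (2M < p) and additively shared
between the two simulated parties. Linear gates are local. Multiplication
uses Beaver triples from a trusted dealer. Comparison `lt(u, v)` for
secrets bounded by 2^(ℓ−1) in magnitude opens `z + 2^ℓ + r` where
`z = u − v` and `r` is a dealer-supplied random mask of ℓ + κ + 1 bits
whose low ℓ bits are also shared bit by bit; a public/shared bitwise
comparison then recovers the sign bit of z. The opening is within
statistical distance 2^(−κ) of uniform (κ = 40 by default). `ge`, `eq`,
`smin`, `smax` are composed from `lt` exactly as
min(a,b) = a·ε + b·(1−ε), ε = (a<b).

Field presets: `p64` (2⁶⁴ − 59, ℓ = 21) matching the evaluated deployment's
field size, the default `p127` (2¹²⁷ − 1, ℓ = 84) and `p255` (2²⁵⁵ − 19,
ℓ = 212) for deep circuits. One `lt` at bit length ℓ consumes exactly
2ℓ − 1 triples, ℓ shared random bits and one bounded mask; these closed
forms are tested against the runtime dealer counters.

**Trust model.** Semi-honest, two parties, trusted dealer. A deployment
claiming malicious security would layer MAC-checked shares and verified
preprocessing (as SPDZ-style frameworks do) over the same gate semantics;
that machinery is deliberately out of scope here, and this engine must be
read as a protocol simulator, not a hardened implementation. What *is*
faithfully reproduced and tested: the share/compute/reveal semantics of
every gate, which values cross the wire, and that those values carry
(statistically) no information about the secrets.

## Secure pipeline

Phase 1 evaluates, for every period pair, zone equality, the shared overlap
`smin(et) − smax(st)`, and one shared indicator per duration bin (comparisons
against the public bin boundaries); the product is accumulated into the
target cell. In the default *public addressing* mode the nurse's
pseudonymous row index and the patient's type are public per period — they
key the revealed output anyway, and the residual leakage (how many periods
each pseudonym has) buys a per-pair cost independent of Nn, matching linear
scaling in the number of periods. A *fully oblivious* mode replaces both
indices with shared one-hot vectors at ×(Nn·Nptype) cost for callers who
cannot accept that leakage.

Phase 2 runs the k-means variant entirely on shares. Because gcd reduction
is impossible on shares, denominators grow by a factor ≤ Nn + 1 per
iteration, scores by roughly the square of the numerators. `plan_budget`
computes worst-case bit bounds per wire class (time-valued wires get a
small comparison bit length, score-valued wires a large one) plus exact
preprocessing counts, and the entry points refuse — before any gate runs —
any configuration whose comparisons could overflow the field. The evaluated
64-bit field leaves ≈ 21 comparison bits after the κ = 40 statistical mask,
which worst-case bounds exceed after even one iteration at realistic sizes;
how the original deployment kept five iterations inside a 64-bit field is
not reconstructable from the available description, so the package instead
selects the smallest adequate preset (typically `p127`) when no field is
pinned. A pinned field that cannot fit raises a configuration error.

The convergence check computes Σ_ij (M_T − M_{T−1})² on shares, multiplies
by a dealer-supplied uniform nonzero field element and reveals the product:
zero iff converged, uniform nonzero otherwise, so exactly one bit leaks.

Obliviousness holds by construction — the gate sequence is a function of
public shape only — and is asserted by comparing recorded gate traces of
equal-shape runs with different secrets. The engine tags every reveal; the
secure pipeline's only output reveals are the membership entries and the
convergence bit.

## Problem sizes in tests and the acceptance script

Equivalence is exercised on randomized instances of 4–12 nurses, up to 8
periods per side, k ∈ {2,3} and 2–3 iterations, plus one end-to-end secure
run of the reduced study preset (7 nurses, 21 patients, a full hour of
data, ≈ 28 000 period pairs, k = 2, 2 iterations — a few minutes of pure
Python). The full 120-nurse configuration runs in plaintext mode in
seconds; its secure execution would take hours in this simulator and adds
no information beyond the equivalence already established at smaller sizes,
so it is not part of the default runs. Gate-level checks are exhaustive
over a p = 101 toy field (κ = 1, ℓ = 4, the largest comparison range that
field admits) and randomized at production parameters.

## Known limitations

* Semi-honest security only; no MACs, no networking — a simulator.
* The synthetic data has no spatial or behavioural correlation structure.
* The fully oblivious addressing mode is exponential in table size relative
  to public addressing and is practical only for small instances.
* `division_free` k-means biases centroids slightly toward their previous
  positions by construction; use `strict_lloyd` for textbook behaviour in
  plaintext analyses.
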