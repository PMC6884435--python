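# wardflow

Privacy-preserving analysis of hospital workflow from indoor location data.

A hospital wants to know whether its nurses interact with the patient types
they are assigned to, using a real-time locating system (RTLS) that records
which zone every tagged person is in every few seconds. Privacy regulation
prevents the hospital from seeing staff location data, so the data is split:
the hospital holds the patient records, a labour union holds the nurse
records. `wardflow` implements the joint analysis the two parties can run
without either side revealing its data:

1. **Facing-time table.** Each party locally condenses its raw records into
   *periods* — maximal stays of one tag in one zone. Jointly, every
   (nurse period *j*, patient period *i*) pair with equal zone and positive
   temporal overlap `ov = min(etᵢ, etⱼ) − max(stᵢ, stⱼ)` contributes one
   interaction, classified by patient type and binned duration (0–10 s,
   10–30 s, 30–60 s, >60 s by default). Row *i* of the resulting per-nurse
   count matrix is the data point **y**⁽ⁱ⁾ ∈ ℕᵐ, m = (#bins)·(#types).
2. **k-means clustering of nurses.** A fixed-iteration Lloyd variant with
   rational centroids **c** = **x**/w (integer numerators, one integer
   denominator). Distances are never materialised: with the integer score
   s(**y**,**c**) = Σₗ(xₗ² − 2w xₗ yₗ), the comparison
   d²(**y**,**c**) ≤ d²(**y**,**c̃**) holds iff w̃²·s(**y**,**c**) ≤ w²·s(**y**,**c̃**),
   so the whole algorithm runs in integer arithmetic. The centroid update is
   division-free — the new centroid is the mean of the cluster's points plus
   its own previous centroid (x′ = w·Σ M·y + x, w′ = w(n+1)) — which also
   keeps empty clusters well-defined. Ties assign to the lowest-indexed
   cluster. Only the binary membership matrix **M** and a one-bit
   convergence flag are ever output; centroids stay hidden.

Both phases exist twice: a plaintext reference, and a secure two-party
execution over additive secret shares in a prime field (Beaver-triple
multiplication, statistically masked comparison gates, trusted-dealer
preprocessing, semi-honest model). The package's central guarantee, enforced
by its test suite, is **exact equivalence**: revealing the secure execution's
output gives bit-for-bit the plaintext result.

> **Security caveat.** The secret-sharing engine simulates both parties in
> one process and uses a trusted dealer with passive security. It
> demonstrates and tests the protocol's functional semantics and leakage
> profile; it is not hardened for protecting real data.

## Worked example

```python
from wardflow import (SimConfig, generate_tracks, split_views, extract_periods,
                      TimeBins, build_table, KMeansConfig, kmeans)

sim = SimConfig(n_nurses=7, n_patient_types=3, patients_per_type=7, seed=5)
raw, _ = generate_tracks(sim)              # 1 h of 4 s samples, 15 zones
hospital_view, union_view = split_views(raw)

nurse_periods = extract_periods(union_view, sim.sample_interval)
patient_periods = extract_periods(hospital_view, sim.sample_interval)
table = build_table(nurse_periods, patient_periods, TimeBins((10, 30, 60)),
                    sim.nurse_ids(), sim.type_labels())
print(table.counts.shape, int(table.counts.sum()))

result = kmeans(table.points(), KMeansConfig(k=2, iterations=2, seed=5))
print(result.membership.sum(axis=0), result.converged)
```

prints

```
(7, 12) 633
[5 2] 1
```

i.e. the 7 nurses produced 633 nurse–patient interactions across the
12 (type × duration-bin) columns, and the clustering split them 5/2 and had
already stabilised (`converged = 1`). The same analysis in secure mode, from
the shell:

```sh
wardflow -v run-all --mode secure --seed 5 --out-dir out/
```

writes the raw tables, both parties' period tables, the cluster assignment
file `clusters.csv` (identical to the plaintext run with the same seed) and
a gate-count transcript. `generate`, `preprocess`, `build-table` and
`cluster` run the individual stages; configurations can be given as a YAML
file (`--config`).

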