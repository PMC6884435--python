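"""End-to-end orchestration: generate -> split -> extract -> table -> cluster.

``run_pipeline`` executes the whole analysis in either plaintext or secure
mode from a single :class:`RunConfig`, writing every intermediate table to
the output directory.  Every artifact is reproducible from config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import io as wio
from .cluster import KMeansConfig, kmeans
from .errors import ConfigurationError
from .facing import TimeBins, build_table
from .periods import extract_periods
from .secure_flow import (
    CircuitShape,
    plan_budget,
    secure_build_table,
    secure_kmeans,
    share_period_table,
)
from .shares import FIELD_PRESETS, FieldSpec, TwoPartyEngine, field_for_budget
from .synth_rtls import SimConfig, generate_tracks, split_views

log = logging.getLogger("wardflow")

__all__ = ["RunConfig", "run_pipeline", "load_config", "PipelineResult"]


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    bins: TimeBins = field(default_factory=TimeBins)
    kmeans: KMeansConfig = field(default_factory=lambda: KMeansConfig(k=5))
    field_preset: str | None = None  # None: budget-driven choice in secure mode
    mode: str = "plaintext"  # plaintext | secure
    addressing: str = "public"  # public | oblivious

    def __post_init__(self) -> None:
        if self.mode not in ("plaintext", "secure"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.addressing not in ("public", "oblivious"):
            raise ConfigurationError(f"unknown addressing {self.addressing!r}")
        if self.kmeans.k > self.sim.n_nurses:
            raise ConfigurationError("k exceeds the number of nurses")
        if self.field_preset is not None and self.field_preset not in FIELD_PRESETS:
            raise ConfigurationError(f"unknown field preset {self.field_preset!r}")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; missing sections use defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimConfig(**data.get("sim", {}))
    bins = TimeBins(tuple(data.get("bins", (10, 30, 60))))
    km = KMeansConfig(**data.get("kmeans", {"k": 5}))
    return RunConfig(
        sim=sim, bins=bins, kmeans=km,
        field_preset=data.get("field"),
        mode=data.get("mode", "plaintext"),
        addressing=data.get("addressing", "public"),
    )


@dataclass
class PipelineResult:
    nurse_ids: list[str]
    membership: "object"
    converged: int
    facing_counts: "object"
    gate_counts: dict | None = None
    dealer_counters: dict | None = None
    field_bits: int | None = None


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None
                 ) -> PipelineResult:
    """Run the full analysis and write all artifacts under ``out_dir``.

    ``seed`` overrides both the simulation and clustering seeds at once.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim if seed is None else replace(config.sim, seed=seed)
    km = config.kmeans if seed is None else replace(config.kmeans, seed=seed)

    log.info("generate: %d nurses, %d patients, %d zones, %ds at %ds sampling",
             sim.n_nurses, sim.n_patients, sim.n_zones, sim.study_duration,
             sim.sample_interval)
    raw, truth = generate_tracks(sim)
    wio.write_raw(raw, out / "raw.csv")
    wio.write_periods(truth, out / "ground_truth_periods.csv")

    hospital, union = split_views(raw)
    wio.write_raw(hospital, out / "raw_hospital.csv")
    wio.write_raw(union, out / "raw_union.csv")

    patient_periods = extract_periods(hospital, sim.sample_interval)
    nurse_periods = extract_periods(union, sim.sample_interval)
    wio.write_periods(patient_periods, out / "periods_hospital.csv")
    wio.write_periods(nurse_periods, out / "periods_union.csv")
    log.info("periods: %d nurse, %d patient", len(nurse_periods), len(patient_periods))

    nurse_ids = sim.nurse_ids()
    type_labels = sim.type_labels()

    plain = build_table(nurse_periods, patient_periods, config.bins,
                        nurse_ids, type_labels)

    if config.mode == "plaintext":
        wio.write_facing(plain, out / "facing.csv")
        result = kmeans(plain.points(), km)
        wio.write_assignments(nurse_ids, result.membership, result.converged,
                              out / "clusters.csv")
        log.info("plaintext clustering done; converged=%d", result.converged)
        return PipelineResult(nurse_ids, result.membership, result.converged,
                              plain.counts)

    shape = CircuitShape(
        Nn=sim.n_nurses, Nptype=sim.n_patient_types,
        Ntimebins=config.bins.n_bins,
        nP=len(nurse_periods), pP=len(patient_periods),
        k=km.k, iterations=km.iterations,
    )
    budget = plan_budget(shape, time_bound=sim.study_duration)
    if config.field_preset is not None:
        field_spec: FieldSpec = FIELD_PRESETS[config.field_preset]
        budget.check(field_spec)
    else:
        field_spec = field_for_budget(budget.required_bitlen())
    log.info("secure mode: field %d bits, budget %d triples / %d bit-masks",
             field_spec.p.bit_length(), budget.triples, budget.random_bits)

    engine = TwoPartyEngine(field_spec, share_seed=sim.seed)
    shared_nurse = share_period_table(engine, nurse_periods,
                                      nurse_ids=nurse_ids, mode=config.addressing)
    shared_patient = share_period_table(engine, patient_periods,
                                        type_labels=type_labels,
                                        mode=config.addressing)
    shared_table = secure_build_table(
        engine, shared_nurse, shared_patient, config.bins,
        nurse_ids, type_labels, time_bound=sim.study_duration,
    )
    membership, converged = secure_kmeans(engine, shared_table, km)
    wio.write_assignments(nurse_ids, membership, converged, out / "clusters.csv")

    transcript = {
        "gate_counts": dict(engine.gate_counts),
        "dealer": engine.dealer.counters(),
        "reveal_labels": sorted({label for label, _ in engine.reveals}),
        "field_bits": field_spec.p.bit_length(),
    }
    (out / "transcript.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in transcript.items()) + "\n")
    log.info("secure clustering done; converged=%d; %d muls, %d comparisons",
             converged, engine.gate_counts.get("mul", 0),
             engine.gate_counts.get("lt", 0))
    # The shared facing table stays shared: it is not an output of the
    # protocol and is deliberately not reconstructed here.
    return PipelineResult(nurse_ids, membership, converged, None,
                          gate_counts=dict(engine.gate_counts),
                          dealer_counters=engine.dealer.counters(),
                          field_bits=field_spec.p.bit_length())
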