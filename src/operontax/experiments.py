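"""Canned benchmark experiments: mock-community composition recovery.

These drive the whole toolkit end to end on synthetic data: build a panel of
operon-bearing genomes for a community's species, curate it into a reference
database, simulate error-prone reads at the community's theoretical
composition, map them with minimap2, profile, and compare the recovered
relative abundances with the truth.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

from .community_sim import CommunitySpec, ErrorModel, SyntheticPanel, simulate_reads, synth_panel, write_reads_fastq
from .db_curation import ReferenceDB, build_database
from .io import Config
from .metrics_eval import AbundanceVector, AssignmentEvaluation, evaluate_assignments, l2_distance
from .profiler import QCTable, run_pipeline

__all__ = ["RecoveryResult", "panel_database", "run_recovery"]


@dataclass
class RecoveryResult:
    """Outcome of one simulated community recovery run."""

    spec: CommunitySpec
    recovered_percent: dict[str, float]  # species (no rank prefix) -> % of assigned reads
    expected_percent: dict[str, float]
    qc: QCTable
    evaluation: AssignmentEvaluation
    l2: float

    def error_for(self, species: str) -> float:
        return self.recovered_percent.get(species, 0.0) - self.expected_percent[species]


def panel_database(
    panel: SyntheticPanel, workdir: Path, config: Config | None = None
) -> tuple[ReferenceDB, Path]:
    """Curate a panel's genomes into a reference DB; returns (db, db FASTA)."""
    gdir, tax = panel.write_database_inputs(workdir)
    dbdir = workdir / "db"
    db = build_database(gdir, tax, config, outdir=dbdir)
    return db, dbdir / "reference.fasta"


def run_recovery(
    spec: CommunitySpec,
    n_reads: int = 5000,
    error: ErrorModel | None = None,
    panel_seed: int = 1,
    between_species_divergence: float = 0.10,
    within_species_divergence: float = 0.005,
    workdir: str | Path | None = None,
    config: Config | None = None,
    per_species: int | None = None,
) -> RecoveryResult:
    """Simulate a community and measure how well its composition is recovered.

    Reads are drawn multinomially at the spec proportions (or exactly
    ``per_species`` reads per member), corrupted by the error model, mapped
    against the panel's own curated database and profiled at species rank
    with the default filters.
    """
    error = error or ErrorModel()
    config = config or Config()
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    workdir = Path(ctx.name) if ctx else Path(workdir)
    try:
        panel = synth_panel(
            species_names=spec.species,
            between_species_divergence=between_species_divergence,
            within_species_divergence=within_species_divergence,
            seed=panel_seed,
        )
        db, db_fasta = panel_database(panel, workdir, config)
        records, truth = simulate_reads(
            panel, spec, n_reads=n_reads, error=error, per_species=per_species
        )
        fastq = workdir / "reads.fastq"
        write_reads_fastq(records, truth, fastq, workdir / "truth.tsv")
        profiles, qc, assignments = run_pipeline(
            fastq, db, config=config, db_fasta=db_fasta
        )
        prof = profiles["species"]
        recovered = {
            t.removeprefix("s__"): 100.0 * r for t, r in prof.relative.items()
        }
        expected = {sp: 100.0 * p for sp, p in spec.members}
        evaluation = evaluate_assignments(truth, assignments)
        l2 = l2_distance(
            AbundanceVector.from_mapping(recovered),
            AbundanceVector.from_mapping(expected),
        )
        return RecoveryResult(spec, recovered, expected, qc, evaluation, l2)
    finally:
        if ctx:
            ctx.cleanup()
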