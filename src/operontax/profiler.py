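"""Taxonomic profiling of long operon reads by filtered best alignment.

Reads are length-filtered to the sequencable amplicon window (3,500-5,000 bp
by default), aligned to a curated reference (externally in PAF, or via
minimap2 in map-ont mode with secondaries disabled), and each read is
assigned the lineage of its best primary alignment that clears the residue
matches (>=2,500 bp) and alignment block length (>=3,500 bp) thresholds.
Secondary alignments are never considered: with error-prone long reads they
mostly add false positives. Counts are aggregated per taxonomic rank into
relative abundances, optionally divided by per-species mean operon copy
number so abundance reflects organisms rather than gene copies.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from .db_curation import ReferenceDB
from .io import RANKS, Config, Lineage, log, read_reads

__all__ = [
    "AlignmentRecord",
    "ReadAssignment",
    "AbundanceProfile",
    "QCTable",
    "length_filter_reads",
    "parse_paf",
    "filter_alignments",
    "assign_reads",
    "profile",
    "run_pipeline",
    "run_minimap2",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """The PAF fields the filter contract needs."""

    read_id: str
    read_length: int
    target_record_id: str
    residue_matches: int
    alignment_block_length: int
    mapping_quality: int
    is_primary: bool


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # assigned | unassigned_no_hit | unassigned_filtered | removed_length
    target_record_id: str | None = None
    lineage: Lineage | None = None


@dataclass
class AbundanceProfile:
    """Per-rank taxon counts and relative abundances."""

    rank: str
    counts: dict[str, int] = field(default_factory=dict)
    relative: dict[str, float] = field(default_factory=dict)
    normalized_relative: dict[str, float] | None = None
    empty: bool = False

    def write_tsv(self, fh: TextIO) -> None:
        fh.write("taxon\tcount\trelative\tnormalized_relative\n")
        for taxon in sorted(self.counts, key=lambda t: (-self.counts[t], t)):
            norm = (
                f"{self.normalized_relative[taxon]:.6g}"
                if self.normalized_relative is not None
                else "NA"
            )
            fh.write(f"{taxon}\t{self.counts[taxon]}\t{self.relative[taxon]:.6g}\t{norm}\n")


@dataclass
class QCTable:
    """Read accounting: every input read lands in exactly one bin."""

    reads_in: int = 0
    removed_length: int = 0
    unassigned_no_hit: int = 0
    unassigned_filtered: int = 0
    assigned: int = 0

    def write_tsv(self, fh: TextIO) -> None:
        fh.write("metric\tcount\n")
        for k in ("reads_in", "removed_length", "unassigned_no_hit", "unassigned_filtered", "assigned"):
            fh.write(f"{k}\t{getattr(self, k)}\n")


def length_filter_reads(
    reads: Iterable[tuple[str, str]], min_len: int = 3500, max_len: int = 5000
) -> tuple[list[tuple[str, str]], list[str]]:
    """Split reads into (kept, removed ids) by the sequence-length window."""
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    kept, removed = [], []
    for rid, seq in reads:
        if min_len <= len(seq) <= max_len:
            kept.append((rid, seq))
        else:
            removed.append(rid)
    return kept, removed


def parse_paf(stream: Iterable[str] | str | Path) -> list[AlignmentRecord]:
    """Parse PAF lines into AlignmentRecords.

    Column 10 is the number of residue matches, column 11 the alignment
    block length (1-based column numbers). Primary/secondary status comes
    from the ``tp:A:`` tag; a missing tag means primary.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return parse_paf(fh)
    out: list[AlignmentRecord] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields_ = line.split("\t")
        if len(fields_) < 12:
            raise ValueError(
                f"PAF line {lineno}: expected >=12 tab-separated fields, got {len(fields_)}"
            )
        try:
            read_id = fields_[0]
            read_length = int(fields_[1])
            target = fields_[5]
            matches = int(fields_[9])
            block = int(fields_[10])
            mapq = int(fields_[11])
        except ValueError as e:
            raise ValueError(f"PAF line {lineno}: {e}") from None
        is_primary = True
        for tag in fields_[12:]:
            if tag.startswith("tp:A:"):
                is_primary = tag[5:] == "P"
                break
        out.append(
            AlignmentRecord(read_id, read_length, target, matches, block, mapq, is_primary)
        )
    return out


def filter_alignments(
    alignments: Iterable[AlignmentRecord],
    min_matches: int = 2500,
    min_block: int = 3500,
    min_mapq: int | None = None,
) -> list[AlignmentRecord]:
    """Keep primary alignments clearing both thresholds.

    ``min_mapq`` is an optional extra gate, off by default.
    """
    return [
        a
        for a in alignments
        if a.is_primary
        and a.residue_matches >= min_matches
        and a.alignment_block_length >= min_block
        and (min_mapq is None or a.mapping_quality >= min_mapq)
    ]


def assign_reads(
    passing: Iterable[AlignmentRecord],
    db: ReferenceDB,
    all_read_ids: Iterable[str],
    reads_with_hits: set[str] | None = None,
) -> list[ReadAssignment]:
    """One assignment per read: the best passing alignment wins.

    Best = max residue matches, ties broken by max block length, then by
    lexicographically smallest target record id. Reads without any passing
    alignment are ``unassigned_filtered`` when they had alignments at all,
    ``unassigned_no_hit`` otherwise.
    """
    best: dict[str, AlignmentRecord] = {}
    for a in passing:
        cur = best.get(a.read_id)
        if cur is None or (
            (-a.residue_matches, -a.alignment_block_length, a.target_record_id)
            < (-cur.residue_matches, -cur.alignment_block_length, cur.target_record_id)
        ):
            best[a.read_id] = a
    if reads_with_hits is None:
        reads_with_hits = set(best)
    out: list[ReadAssignment] = []
    for rid in all_read_ids:
        a = best.get(rid)
        if a is not None:
            lineage = db.lineage_of(a.target_record_id)
            out.append(ReadAssignment(rid, "assigned", a.target_record_id, lineage))
        elif rid in reads_with_hits:
            out.append(ReadAssignment(rid, "unassigned_filtered"))
        else:
            out.append(ReadAssignment(rid, "unassigned_no_hit"))
    return out


def profile(
    assignments: Iterable[ReadAssignment],
    db: ReferenceDB,
    rank: str = "species",
    normalize: bool = False,
) -> AbundanceProfile:
    """Aggregate assigned reads into a per-rank abundance profile.

    Unassigned reads are excluded from relative-abundance denominators.
    Copy-number normalization divides species-level counts by each species'
    mean operon copies per genome and renormalizes; higher ranks aggregate
    the normalized species values.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, int] = defaultdict(int)
    species_counts: dict[str, int] = defaultdict(int)
    species_to_taxon: dict[str, str] = {}
    for a in assignments:
        if a.status != "assigned":
            continue
        taxon = a.lineage.at_rank(rank)
        counts[taxon] += 1
        sp = a.lineage.species_base
        species_counts[sp] += 1
        species_to_taxon[sp] = taxon
    total = sum(counts.values())
    if total == 0:
        return AbundanceProfile(rank, {}, {}, None, empty=True)
    relative = {t: c / total for t, c in counts.items()}
    normalized = None
    if normalize:
        weighted: dict[str, float] = defaultdict(float)
        for sp, c in species_counts.items():
            cn = db.copy_number.get(sp, 1.0)
            weighted[species_to_taxon[sp]] += c / cn
        wtot = sum(weighted.values())
        normalized = {t: w / wtot for t, w in weighted.items()}
    return AbundanceProfile(rank, dict(counts), relative, normalized)


def run_minimap2(
    reference_fasta: str | Path,
    reads: list[tuple[str, str]],
    paf_out: str | Path,
    threads: int = 1,
) -> None:
    """Map reads with minimap2 (map-ont preset, secondaries disabled)."""
    if shutil.which("minimap2") is None:
        raise RuntimeError(
            "minimap2 not found on PATH; supply a precomputed PAF file instead"
        )
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as tmp:
        for rid, seq in reads:
            tmp.write(f">{rid}\n{seq}\n")
        reads_path = tmp.name
    try:
        cmd = [
            # -c: base-level alignment so PAF col 10/11 are true residue
            # matches and block length, which the filter contract needs
            "minimap2", "-cx", "map-ont", "--secondary=no", "-t", str(threads),
            "-o", str(paf_out), str(reference_fasta), reads_path,
        ]
        res = subprocess.run(cmd, capture_output=True, text=True)
        if res.returncode != 0:
            raise RuntimeError(f"minimap2 failed: {res.stderr.strip()}")
    finally:
        Path(reads_path).unlink(missing_ok=True)


def run_pipeline(
    reads_path: str | Path,
    db: ReferenceDB,
    paf_path: str | Path | None = None,
    config: Config | None = None,
    db_fasta: str | Path | None = None,
    ranks: tuple[str, ...] = RANKS,
) -> tuple[dict[str, AbundanceProfile], QCTable, list[ReadAssignment]]:
    """Length filter -> align/ingest -> filter -> assign -> profile.

    Either ``paf_path`` (precomputed alignments) or ``db_fasta`` (reference
    FASTA to map against with minimap2) must be provided.
    """
    config = config or Config()
    reads = list(read_reads(reads_path))
    kept, removed = length_filter_reads(reads, config.read_min_len, config.read_max_len)
    kept_ids = [rid for rid, _ in kept]
    qc = QCTable(reads_in=len(reads), removed_length=len(removed))

    if paf_path is None:
        if db_fasta is None:
            raise ValueError(
                "no alignments available: pass paf_path (precomputed PAF) or "
                "db_fasta (reference FASTA for the built-in minimap2 runner)"
            )
        with tempfile.NamedTemporaryFile(suffix=".paf", delete=False) as tmp:
            paf_tmp = tmp.name
        try:
            run_minimap2(db_fasta, kept, paf_tmp)
            alignments = parse_paf(paf_tmp)
        finally:
            Path(paf_tmp).unlink(missing_ok=True)
    else:
        alignments = parse_paf(paf_path)

    kept_set = set(kept_ids)
    alignments = [a for a in alignments if a.read_id in kept_set]
    reads_with_hits = {a.read_id for a in alignments}
    passing = filter_alignments(alignments, config.min_matches, config.min_block)
    assignments = assign_reads(passing, db, kept_ids, reads_with_hits)

    for a in assignments:
        if a.status == "assigned":
            qc.assigned += 1
        elif a.status == "unassigned_filtered":
            qc.unassigned_filtered += 1
        else:
            qc.unassigned_no_hit += 1

    profiles = {
        rank: profile(assignments, db, rank, config.normalize) for rank in ranks
    }
    return profiles, qc, assignments
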