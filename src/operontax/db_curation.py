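"""Reference-database curation.

Turns raw in silico PCR amplicons from a set of genome assemblies into a
curated 16S-ITS-23S rRNA operon reference database through a fixed cascade:

1. extract amplicons within the product-size window (done upstream);
2. drop every assembly whose amplicons contain an ambiguous base;
3. attach taxonomy and drop assemblies without a species-level assignment
   (GTDB alphabetic species suffixes are ignored when comparing species);
4. compute per-species mean operon copy number on this (pre-dedup) set;
5. remove duplicate sequences within a species;
6. cluster at 99% identity and screen mixed clusters for cross-species
   contamination; every record of a contaminated assembly is removed.

Each stage's removal counts are tallied in a CurationReport that reconciles
exactly (in - removed = out at every stage).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import edlib

from .insilico_pcr import AmpliconHit, IUPACPrimer, extract_from_records
from .io import Config, Lineage, log, read_fasta, read_taxonomy_tsv, write_fasta

__all__ = [
    "OperonRecord",
    "ReferenceDB",
    "CurationReport",
    "Cluster",
    "filter_ambiguous",
    "attach_taxonomy",
    "dedup_within_species",
    "cluster_sequences",
    "detect_cross_species",
    "remove_contaminated",
    "compute_copy_number",
    "build_database",
    "alignment_identity",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class OperonRecord:
    """One curated operon sequence with provenance and lineage."""

    record_id: str
    assembly_id: str
    lineage: Lineage
    sequence: str
    fwd_mismatches: int = 0
    rev_mismatches: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> str:
        return self.lineage.species_base


@dataclass
class CurationReport:
    """Per-stage genome/sequence counts of the curation cascade."""

    genomes_in: int = 0
    genomes_with_amplicons: int = 0
    genomes_ambiguity_removed: int = 0
    genomes_unassigned_removed: int = 0
    duplicate_sequences_removed: int = 0
    genomes_contamination_removed: int = 0
    final_genomes: int = 0
    final_sequences: int = 0
    final_species: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class Cluster:
    cluster_id: int
    members: list[str]  # record_ids, centroid first
    representative: str


@dataclass
class ReferenceDB:
    """Curated record set plus per-species mean operon copy number."""

    records: list[OperonRecord]
    copy_number: dict[str, float]
    report: CurationReport = field(default_factory=CurationReport)

    def lineage_of(self, record_id: str) -> Lineage:
        try:
            return self._by_id[record_id].lineage
        except AttributeError:
            self._by_id = {r.record_id: r for r in self.records}
            return self.lineage_of(record_id)
        except KeyError:
            raise KeyError(f"record {record_id!r} not in reference database") from None

    def save(self, outdir: str | Path) -> None:
        """Write FASTA + metadata/copy-number/report sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([(r.record_id, r.sequence) for r in self.records], outdir / "reference.fasta")
        with open(outdir / "metadata.tsv", "w") as fh:
            fh.write("record_id\tassembly_id\tlineage\tlength\tfwd_mm\trev_mm\n")
            for r in self.records:
                fh.write(
                    f"{r.record_id}\t{r.assembly_id}\t{r.lineage.to_string()}\t"
                    f"{r.length}\t{r.fwd_mismatches}\t{r.rev_mismatches}\n"
                )
        with open(outdir / "copy_number.tsv", "w") as fh:
            fh.write("species\tmean_copies\n")
            for sp in sorted(self.copy_number):
                fh.write(f"{sp}\t{self.copy_number[sp]:.6g}\n")
        with open(outdir / "report.json", "w") as fh:
            fh.write(self.report.to_json() + "\n")

    @classmethod
    def load(cls, dbdir: str | Path) -> "ReferenceDB":
        dbdir = Path(dbdir)
        seqs = dict(read_fasta(dbdir / "reference.fasta"))
        records = []
        with open(dbdir / "metadata.tsv") as fh:
            header = fh.readline()
            for line in fh:
                rid, aid, lin, _length, fmm, rmm = line.rstrip("\n").split("\t")
                records.append(
                    OperonRecord(rid, aid, Lineage.from_string(lin), seqs[rid], int(fmm), int(rmm))
                )
        copy_number = {}
        cn_path = dbdir / "copy_number.tsv"
        if cn_path.exists():
            with open(cn_path) as fh:
                fh.readline()
                for line in fh:
                    sp, val = line.rstrip("\n").split("\t")
                    copy_number[sp] = float(val)
        report = CurationReport()
        rp = dbdir / "report.json"
        if rp.exists():
            report = CurationReport(**json.loads(rp.read_text()))
        return cls(records, copy_number, report)


def filter_ambiguous(
    amplicons_by_assembly: dict[str, list[AmpliconHit]],
) -> tuple[dict[str, list[AmpliconHit]], list[str]]:
    """Drop any assembly with a non-ACGT character in ANY of its amplicons.

    The whole genome is distrusted once one of its operons is ambiguous.
    """
    kept: dict[str, list[AmpliconHit]] = {}
    removed: list[str] = []
    for asm in sorted(amplicons_by_assembly):
        hits = amplicons_by_assembly[asm]
        if any(set(h.sequence) - _ACGT for h in hits):
            removed.append(asm)
        else:
            kept[asm] = hits
    return kept, removed


def attach_taxonomy(
    amplicons_by_assembly: dict[str, list[AmpliconHit]],
    taxonomy: dict[str, Lineage],
) -> tuple[list[OperonRecord], list[str]]:
    """Attach lineages; drop assemblies with no species-level assignment.

    Returns (records, dropped assembly ids). Records are ordered by
    (assembly_id, record_id); record ids are ``<assembly>|<contig>|<start>-<end>|<strand>``.
    """
    records: list[OperonRecord] = []
    dropped: list[str] = []
    for asm in sorted(amplicons_by_assembly):
        lineage = taxonomy.get(asm)
        if lineage is None:
            log(f"assembly {asm}: absent from taxonomy table; dropped")
            dropped.append(asm)
            continue
        if not lineage.species or lineage.species == "s__":
            log(f"assembly {asm}: no species-level assignment; dropped")
            dropped.append(asm)
            continue
        for h in sorted(amplicons_by_assembly[asm], key=lambda h: (h.contig_id, h.start)):
            rid = f"{asm}|{h.contig_id}|{h.start}-{h.end}|{h.strand}"
            records.append(
                OperonRecord(rid, asm, lineage, h.sequence, h.fwd_mismatches, h.rev_mismatches)
            )
    return records, dropped


def dedup_within_species(records: list[OperonRecord]) -> tuple[list[OperonRecord], int]:
    """Keep one record per distinct sequence within each species.

    The representative is the first by sorted (assembly_id, record_id).
    Identical sequences in *different* species are both retained here; the
    contamination screen decides their fate.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[OperonRecord] = []
    n_removed = 0
    for rec in sorted(records, key=lambda r: (r.assembly_id, r.record_id)):
        key = (rec.species, rec.sequence)
        if key in seen:
            n_removed += 1
        else:
            seen.add(key)
            kept.append(rec)
    return kept, n_removed


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns (incl. gaps)."""
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches / columns


def cluster_sequences(
    records: list[OperonRecord], identity_threshold: float = 0.99
) -> list[Cluster]:
    """Greedy centroid clustering in length-descending order (cd-hit style).

    Each record joins the first existing centroid whose global-alignment
    identity with it is >= the threshold, else founds a new cluster. Ties in
    length are broken by record_id for determinism.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-r.length, r.record_id))
    clusters: list[Cluster] = []
    centroids: list[OperonRecord] = []
    for rec in order:
        for cl, cen in zip(clusters, centroids):
            # identity upper bound from length difference prunes most pairs
            if cen.length and 1 - (cen.length - rec.length) / cen.length < identity_threshold:
                continue
            if alignment_identity(rec.sequence, cen.sequence) >= identity_threshold:
                cl.members.append(rec.record_id)
                break
        else:
            clusters.append(Cluster(len(clusters), [rec.record_id], rec.record_id))
            centroids.append(rec)
    return clusters


def detect_cross_species(
    clusters: list[Cluster],
    records: list[OperonRecord],
    minor_genome_threshold: int = 2,
) -> list[str]:
    """Flag assemblies whose operons look copied from another species.

    Within each mixed-species cluster, the minor taxa are the species backed
    by at most ``minor_genome_threshold`` genomes in that cluster. A
    minor-taxon record is contaminated when its best-identity match among all
    other records (its own assembly excluded) belongs to a different species
    and beats (or is unopposed by) its best same-species match. The whole
    assembly is flagged.
    """
    by_id = {r.record_id: r for r in records}
    flagged: set[str] = set()
    for cl in clusters:
        members = [by_id[rid] for rid in cl.members]
        species_in_cluster = {m.species for m in members}
        if len(species_in_cluster) < 2:
            continue
        genomes_per_species: dict[str, set[str]] = defaultdict(set)
        for m in members:
            genomes_per_species[m.species].add(m.assembly_id)
        minor = {
            sp for sp, asms in genomes_per_species.items()
            if len(asms) <= minor_genome_threshold
        }
        for m in members:
            if m.species not in minor or m.assembly_id in flagged:
                continue
            best_same = None
            best_other = None
            for other in records:
                if other.assembly_id == m.assembly_id:
                    continue
                ident = alignment_identity(m.sequence, other.sequence)
                if other.species == m.species:
                    if best_same is None or ident > best_same:
                        best_same = ident
                else:
                    if best_other is None or ident > best_other:
                        best_other = ident
            if best_other is not None and (best_same is None or best_other > best_same):
                flagged.add(m.assembly_id)
    return sorted(flagged)


def remove_contaminated(
    records: list[OperonRecord], flagged_assemblies: list[str]
) -> list[OperonRecord]:
    """Drop ALL records of every flagged assembly (clean copies included)."""
    flagged = set(flagged_assemblies)
    return [r for r in records if r.assembly_id not in flagged]


def compute_copy_number(records: list[OperonRecord]) -> dict[str, float]:
    """Mean operon copies per genome for each species.

    The mean is over a species' assemblies of the number of extracted
    amplicons in each assembly; values are >= 1 by construction.
    """
    per_assembly: dict[str, int] = defaultdict(int)
    species_of: dict[str, str] = {}
    for r in records:
        per_assembly[r.assembly_id] += 1
        species_of[r.assembly_id] = r.species
    per_species: dict[str, list[int]] = defaultdict(list)
    for asm, count in per_assembly.items():
        per_species[species_of[asm]].append(count)
    return {sp: sum(c) / len(c) for sp, c in sorted(per_species.items())}


def build_database(
    genome_dir: str | Path,
    taxonomy_tsv: str | Path,
    config: Config | None = None,
    outdir: str | Path | None = None,
) -> ReferenceDB:
    """Run the full curation cascade over a directory of genome FASTA files.

    Every ``*.fa``/``*.fasta``/``*.fna`` file is one assembly (the stem is
    its accession). Writes FASTA + TSV sidecars when ``outdir`` is given.
    """
    config = config or Config()
    genome_dir = Path(genome_dir)
    if not genome_dir.is_dir():
        raise FileNotFoundError(f"genome directory not found: {genome_dir}")
    fasta_paths = sorted(
        p for p in genome_dir.iterdir() if p.suffix.lower() in (".fa", ".fasta", ".fna")
    )
    report = CurationReport(genomes_in=len(fasta_paths))

    amplicons: dict[str, list[AmpliconHit]] = {}
    for path in fasta_paths:
        try:
            hits = extract_from_records(
                read_fasta(path),
                config.fwd_primer,
                config.rev_primer,
                config.max_mismatch,
                config.amplicon_min_len,
                config.amplicon_max_len,
            )
        except (OSError, ValueError) as e:
            raise RuntimeError(f"failed reading genome {path}: {e}") from e
        if hits:
            amplicons[path.stem] = hits
    report.genomes_with_amplicons = len(amplicons)

    kept, ambiguous = filter_ambiguous(amplicons)
    report.genomes_ambiguity_removed = len(ambiguous)

    taxonomy = read_taxonomy_tsv(taxonomy_tsv) if fasta_paths else {}
    records, unassigned = attach_taxonomy(kept, taxonomy)
    report.genomes_unassigned_removed = len(unassigned)

    copy_number = compute_copy_number(records)

    records, n_dups = dedup_within_species(records)
    report.duplicate_sequences_removed = n_dups

    clusters = cluster_sequences(records, config.identity_threshold)
    flagged = detect_cross_species(clusters, records, config.minor_genome_threshold)
    records = remove_contaminated(records, flagged)
    report.genomes_contamination_removed = len(flagged)

    if config.copy_number_post_dedup:
        copy_number = compute_copy_number(records)
    surviving_species = {r.species for r in records}
    copy_number = {sp: cn for sp, cn in copy_number.items() if sp in surviving_species}

    report.final_genomes = len({r.assembly_id for r in records})
    report.final_sequences = len(records)
    report.final_species = len({r.species for r in records})

    db = ReferenceDB(records, copy_number, report)
    if outdir is not None:
        db.save(outdir)
    return db
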