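"""Readers, writers and shared configuration.

Sequence I/O goes through Biopython's SeqIO; sequences are uppercased on
ingest. Taxonomy arrives as a two-column TSV mapping assembly accession to a
GTDB-style seven-rank lineage string (``d__...;p__...;...;s__...``).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, TextIO

from Bio import SeqIO

from .insilico_pcr import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER, IUPACPrimer

RANKS = ("domain", "phylum", "class_", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class Lineage:
    """A GTDB-style seven-rank lineage; rank values keep their prefixes."""

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    @classmethod
    def from_string(cls, lineage: str) -> "Lineage":
        """Parse ``d__A;p__B;...;s__G``; missing trailing ranks become empty."""
        parts = [p.strip() for p in lineage.strip().split(";")]
        if len(parts) > 7:
            raise ValueError(f"lineage has {len(parts)} fields (max 7): {lineage!r}")
        values = []
        for i, prefix in enumerate(_RANK_PREFIXES):
            if i < len(parts) and parts[i]:
                if not parts[i].startswith(prefix):
                    raise ValueError(
                        f"rank {i} should start with {prefix!r}: {parts[i]!r}"
                    )
                values.append(parts[i])
            else:
                values.append("")
        return cls(*values)

    def to_string(self) -> str:
        return ";".join(
            getattr(self, r) or p for r, p in zip(RANKS, _RANK_PREFIXES)
        )

    def at_rank(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, rank)

    @property
    def species_base(self) -> str:
        """Species with any GTDB alphabetic suffix (``_A`` etc.) stripped."""
        return strip_gtdb_suffix(self.species)


def strip_gtdb_suffix(name: str) -> str:
    """Drop a trailing GTDB placeholder suffix like ``_A`` from a taxon name.

    ``s__Bacillus subtilis_A`` and ``s__Bacillus subtilis`` compare equal
    after stripping. Only a final ``_`` + uppercase-letters token is removed.
    """
    head, sep, tail = name.rpartition("_")
    if sep and head and not head.endswith("_") and tail.isalpha() and tail.isupper():
        return head
    return name


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record_id, uppercase sequence) from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (record_id, uppercase sequence, quality string) from FASTQ."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq).upper(), qual


def read_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTA or FASTQ, sniffed by first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        yield from read_fasta(path)
    elif first == "@":
        for rid, seq, _ in read_fastq(path):
            yield rid, seq
    elif first == "":
        return
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_taxonomy_tsv(path: str | Path) -> dict[str, Lineage]:
    """Read ``assembly_id<TAB>lineage-string`` into a dict of Lineage."""
    table: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                table[parts[0]] = Lineage.from_string(parts[1])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return table


def write_krona(profile: "AbundanceProfile", db, path: str | Path) -> int:
    """Write Krona-compatible text: ``count<TAB>rank1<TAB>rank2...``.

    One line per distinct full lineage with a nonzero read count; counts are
    aggregated at the profile's rank, lineages resolved through the reference
    database. Returns the number of lines written.
    """
    lineage_of: dict[str, Lineage] = {}
    for rec in db.records:
        taxon = rec.lineage.at_rank(profile.rank)
        lineage_of.setdefault(taxon, rec.lineage)
    n = 0
    with open(path, "w") as fh:
        for taxon in sorted(profile.counts):
            count = profile.counts[taxon]
            if count <= 0:
                continue
            lin = lineage_of.get(taxon)
            ranks = []
            for r in RANKS:
                v = lin.at_rank(r) if lin is not None else ""
                ranks.append(v)
                if r == profile.rank:
                    break
            fh.write(str(count) + "\t" + "\t".join(ranks) + "\n")
            n += 1
    return n


@dataclass
class Config:
    """All tunables, defaulting to the method's published operating point."""

    fwd_primer: IUPACPrimer = DEFAULT_FWD_PRIMER
    rev_primer: IUPACPrimer = DEFAULT_REV_PRIMER
    max_mismatch: int = 2
    amplicon_min_len: int = 3500
    amplicon_max_len: int = 7000
    read_min_len: int = 3500
    read_max_len: int = 5000
    min_matches: int = 2500
    min_block: int = 3500
    identity_threshold: float = 0.99
    minor_genome_threshold: int = 2
    normalize: bool = False
    copy_number_post_dedup: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Key-value config file (``key = value`` or ``key: value`` lines)."""
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                for sep in ("=", ":"):
                    if sep in line:
                        key, _, val = line.partition(sep)
                        break
                else:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = key.strip(), val.strip()
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
                cur = getattr(cls, key, None)
                if key in ("fwd_primer", "rev_primer"):
                    role = "forward" if key == "fwd_primer" else "reverse"
                    kwargs[key] = IUPACPrimer(key, val, role)
                elif isinstance(cur, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes", "on")
                elif isinstance(cur, int):
                    kwargs[key] = int(val)
                elif isinstance(cur, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)


def log(msg: str, file: TextIO = sys.stderr) -> None:
    """Diagnostics go to stderr; data goes to files/stdout."""
    print(f"[operontax] {msg}", file=file)
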