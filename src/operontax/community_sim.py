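"""Synthetic communities: operon panels, mock compositions and noisy reads.

The generator emulates what the rest of the toolkit consumes without any
download: multi-copy rRNA-operon-bearing genomes with species-level
divergence, defined mock-community compositions, and Nanopore-like
error-prone full-length amplicon reads.

A panel starts from a single ~4,300 bp ancestral operon whose termini are
concrete realizations of the universal primer pair; each species mutates the
interior at a between-species rate (default 10% - comfortably above the 99%
curation clustering threshold), and each operon copy within a genome mutates
further at a within-species rate (default 0.5%, mimicking intragenomic
operon heterogeneity). Primer binding sites are held fixed so in silico PCR
recovers every planted copy. Reads are full-length operon copies with i.i.d.
substitution/insertion/deletion errors (defaults 3%/2%/3%, ~8% total,
Nanopore-like) and randomized strand; true species labels travel in the
FASTQ headers and a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .insilico_pcr import (
    DEFAULT_FWD_PRIMER,
    DEFAULT_REV_PRIMER,
    IUPAC_SETS,
    IUPACPrimer,
    reverse_complement,
)

__all__ = [
    "CommunitySpec",
    "ErrorModel",
    "SyntheticPanel",
    "synth_panel",
    "simulate_reads",
    "mock_spec",
    "write_reads_fastq",
    "MOCK1_COMPOSITION",
    "MOCK2_COMPOSITION",
]

_BASES = "ACGT"

# ZymoBIOMICS theoretical operon-level compositions (%), bacterial members
# only, GTDB species names. MOCK1 is the 8-species microbial community
# standard; MOCK2 the 14-bacteria gut microbiome standard (archaeal and
# fungal members carry no 16S-ITS-23S operon and are excluded).
MOCK1_COMPOSITION: dict[str, float] = {
    "Bacillus marinus": 17.4,
    "Enterococcus faecalis": 9.9,
    "Escherichia flexneri": 10.1,
    "Lactobacillus fermentum": 18.4,
    "Listeria monocytogenes": 14.1,
    "Pseudomonas aeruginosa": 4.2,
    "Salmonella enterica": 10.4,
    "Staphylococcus aureus": 15.5,
}

MOCK2_COMPOSITION: dict[str, float] = {
    "Akkermansia muciniphila": 0.97,
    "Bacteroides fragilis": 9.94,
    "Bifidobacterium adolescentis": 8.78,
    "Clostridioides difficile": 2.62,
    "Clostridium perfringens": 0.0002,
    "Enterococcus faecalis": 0.0009,
    "Escherichia flexneri": 12.12,
    "Faecalibacterium prausnitzii": 17.63,
    "Fusobacterium animalis": 7.49,
    "Lactobacillus fermentum": 9.63,
    "Prevotella corporis": 4.98,
    "Roseburia hominis": 9.89,
    "Salmonella enterica": 0.009,
    "Veillonella rogosae": 15.87,
}


@dataclass(frozen=True)
class CommunitySpec:
    """Taxon -> proportion ground truth for a community."""

    members: tuple[tuple[str, float], ...]
    name: str = "community"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community has no members")
        total = sum(p for _, p in self.members)
        if any(p <= 0 for _, p in self.members):
            raise ValueError("proportions must be > 0")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")

    @classmethod
    def from_percentages(cls, percents: dict[str, float], name: str) -> "CommunitySpec":
        total = sum(percents.values())
        members = tuple((sp, p / total) for sp, p in sorted(percents.items()))
        return cls(members, name)

    @property
    def species(self) -> list[str]:
        return [sp for sp, _ in self.members]

    @property
    def proportions(self) -> dict[str, float]:
        return dict(self.members)


def mock_spec(name: str) -> CommunitySpec:
    """The bacterial members of the two standard mock communities,
    proportions renormalized over bacteria."""
    table = {"MOCK1": MOCK1_COMPOSITION, "MOCK2": MOCK2_COMPOSITION}
    try:
        return CommunitySpec.from_percentages(table[name.upper()], name.upper())
    except KeyError:
        raise ValueError(f"unknown mock community {name!r}; expected MOCK1 or MOCK2") from None


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. substitution/insertion/deletion error rates."""

    substitution_rate: float = 0.03
    insertion_rate: float = 0.02
    deletion_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("error rates must lie in [0, 1)")
        if sum(rates) >= 0.5:
            raise ValueError("total error rate must be < 0.5")

    @property
    def total(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


@dataclass
class SyntheticPanel:
    """Operon-bearing synthetic genomes with planted ground truth."""

    species: list[str]
    operons: dict[str, list[str]]  # species -> operon copies (amplicon orientation)
    genomes: dict[str, str]  # species -> full genome sequence
    assembly_ids: dict[str, str] = field(default_factory=dict)

    def copy_counts(self) -> dict[str, int]:
        return {sp: len(ops) for sp, ops in self.operons.items()}

    def lineage_string(self, species: str) -> str:
        genus = species.split()[0]
        return (
            f"d__Bacteria;p__{genus}_phy;c__{genus}_cls;o__{genus}_ord;"
            f"f__{genus}_fam;g__{genus};s__{species}"
        )

    def write_database_inputs(self, outdir: str | Path) -> tuple[Path, Path]:
        """Write per-assembly genome FASTAs and the taxonomy TSV.

        Returns (genome_dir, taxonomy_tsv), ready for build_database.
        """
        outdir = Path(outdir)
        genome_dir = outdir / "genomes"
        genome_dir.mkdir(parents=True, exist_ok=True)
        tax_path = outdir / "taxonomy.tsv"
        with open(tax_path, "w") as tax:
            for sp in self.species:
                asm = self.assembly_ids[sp]
                with open(genome_dir / f"{asm}.fasta", "w") as fh:
                    fh.write(f">{asm}_contig1\n")
                    seq = self.genomes[sp]
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
                tax.write(f"{asm}\t{self.lineage_string(sp)}\n")
        return genome_dir, tax_path


def _realize_primer(primer: IUPACPrimer, rng: np.random.Generator) -> str:
    """Pick one concrete ACGT realization of a degenerate primer."""
    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in primer.sequence
    )


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def _mutate_interior(operon: str, rate: float, fixed_5p: int, fixed_3p: int,
                     rng: np.random.Generator) -> str:
    """Substitute interior bases at the given per-base rate; primer-site
    termini are never touched."""
    if rate <= 0:
        return operon
    arr = np.frombuffer(operon.encode(), dtype=np.uint8).copy()
    lo, hi = fixed_5p, len(arr) - fixed_3p
    mask = np.zeros(len(arr), dtype=bool)
    mask[lo:hi] = rng.random(hi - lo) < rate
    idx = np.flatnonzero(mask)
    if idx.size:
        lut = {ord(b): i for i, b in enumerate(_BASES)}
        codes = np.array([lut[v] for v in arr[idx]])
        codes = (codes + rng.integers(1, 4, idx.size)) % 4
        arr[idx] = np.frombuffer(_BASES.encode(), dtype=np.uint8)[codes]
    return arr.tobytes().decode()


def synth_panel(
    n_species: int = 8,
    copies_per_genome: tuple[int, int] = (1, 5),
    between_species_divergence: float = 0.10,
    within_species_divergence: float = 0.005,
    seed: int = 0,
    species_names: list[str] | None = None,
    operon_length: int = 4300,
    fwd: IUPACPrimer = DEFAULT_FWD_PRIMER,
    rev: IUPACPrimer = DEFAULT_REV_PRIMER,
) -> SyntheticPanel:
    """Build a panel of operon-bearing genomes with planted copy counts.

    Species operons diverge from a common ancestor at the between-species
    rate, copies within a genome at the within-species rate (substitutions
    only, so lengths stay in the amplicon window). Operons are embedded in
    random genomic background with >=1 kb flanks and ~3 kb spacers (so
    cross-copy primer pairings fall outside the 7 kb product window), each
    copy on a random strand.
    """
    if not 0 <= within_species_divergence <= 0.3 or not 0 <= between_species_divergence <= 0.3:
        raise ValueError("divergences must lie in [0, 0.3]")
    if between_species_divergence < within_species_divergence:
        raise ValueError("between-species divergence must be >= within-species")
    lo, hi = copies_per_genome
    if not 1 <= lo <= hi:
        raise ValueError("copies_per_genome must be a range with 1 <= lo <= hi")
    if species_names is not None:
        names = list(species_names)
    else:
        names = [f"Synthsp species{i + 1:03d}" for i in range(n_species)]
    if len(set(names)) != len(names):
        raise ValueError("species names must be unique")

    rng = np.random.default_rng(seed)
    fwd_site = _realize_primer(fwd, rng)
    rev_site = reverse_complement(_realize_primer(rev, rng))
    interior_len = operon_length - len(fwd_site) - len(rev_site)
    ancestor = fwd_site + _random_seq(interior_len, rng) + rev_site

    operons: dict[str, list[str]] = {}
    genomes: dict[str, str] = {}
    assembly_ids: dict[str, str] = {}
    for i, sp in enumerate(names):
        sp_operon = _mutate_interior(
            ancestor, between_species_divergence, len(fwd_site), len(rev_site), rng
        )
        n_copies = int(rng.integers(lo, hi + 1))
        copies = [
            _mutate_interior(
                sp_operon, within_species_divergence, len(fwd_site), len(rev_site), rng
            )
            for _ in range(n_copies)
        ]
        parts = [_random_seq(1000 + int(rng.integers(0, 500)), rng)]
        for copy in copies:
            embedded = copy if rng.random() < 0.5 else reverse_complement(copy)
            parts.append(embedded)
            parts.append(_random_seq(3000 + int(rng.integers(0, 500)), rng))
        genome = "".join(parts)
        operons[sp] = copies
        genomes[sp] = genome
        assembly_ids[sp] = f"SYN{i + 1:06d}"
    return SyntheticPanel(names, operons, genomes, assembly_ids)


def _apply_errors(seq: str, error: ErrorModel, rng: np.random.Generator) -> str:
    """Vectorized i.i.d. error process: per base delete/substitute, then at
    most one insertion per gap (adequate for rates well below 1)."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int8)
    u = rng.random(arr.size)
    del_mask = u < error.deletion_rate
    sub_mask = (~del_mask) & (u < error.deletion_rate + error.substitution_rate)
    if sub_mask.any():
        arr[sub_mask] = (arr[sub_mask] + rng.integers(1, 4, int(sub_mask.sum()))) % 4
    arr = arr[~del_mask]
    ins_mask = rng.random(arr.size + 1) < error.insertion_rate
    if ins_mask.any():
        pos = np.flatnonzero(ins_mask)
        bases = rng.integers(0, 4, pos.size).astype(np.int8)
        arr = np.insert(arr, pos, bases)
    back = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    return back[arr].tobytes().decode()


def simulate_reads(
    panel: SyntheticPanel,
    spec: CommunitySpec,
    n_reads: int = 5000,
    error: ErrorModel | None = None,
    length_window: tuple[int, int] | None = None,
    per_species: int | None = None,
) -> tuple[list[tuple[str, str, str]], dict[str, str]]:
    """Simulate full-length error-prone amplicon reads from a panel.

    Species are drawn multinomially at the spec proportions, or exactly
    ``per_species`` reads per member when that mode is set (the fixed
    per-species design used in body-site benchmarks). Each read is a random
    operon copy of its species, error-corrupted and strand-randomized.
    Returns (records, truth): records are (read_id, sequence, quality)
    triples, truth maps read_id -> true species. When ``length_window`` is
    given, reads falling outside it are redrawn (up to 50 attempts each).
    """
    error = error or ErrorModel()
    missing = [sp for sp in spec.species if sp not in panel.operons]
    if missing:
        raise ValueError(f"species not in panel: {missing}")
    rng = np.random.default_rng(error.seed)
    if per_species is not None:
        labels = [sp for sp in spec.species for _ in range(per_species)]
    else:
        props = np.array([p for _, p in spec.members])
        counts = rng.multinomial(n_reads, props / props.sum())
        labels = [sp for (sp, _), c in zip(spec.members, counts) for _ in range(c)]
    records: list[tuple[str, str, str]] = []
    truth: dict[str, str] = {}
    for i, sp in enumerate(labels):
        copies = panel.operons[sp]
        for _ in range(50):
            template = copies[rng.integers(len(copies))]
            read = _apply_errors(template, error, rng)
            if rng.random() < 0.5:
                read = reverse_complement(read)
            if length_window is None or length_window[0] <= len(read) <= length_window[1]:
                break
        rid = f"read_{i + 1:06d}"
        qual = "I" * len(read)  # constant Q40 placeholder; qualities are not modelled
        records.append((rid, read, qual))
        truth[rid] = sp
    return records, truth


def write_reads_fastq(
    records: list[tuple[str, str, str]],
    truth: dict[str, str],
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write simulated reads as FASTQ (species= tag in the description) and
    an optional read_id -> species truth TSV."""
    with open(fastq_path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid} species={truth.get(rid, 'NA')}\n{seq}\n+\n{qual}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tspecies\n")
            for rid, _, _ in records:
                fh.write(f"{rid}\t{truth[rid]}\n")
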