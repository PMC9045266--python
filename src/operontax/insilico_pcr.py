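"""Degenerate-primer in silico PCR.

Locates IUPAC degenerate primer binding sites on both strands of a genome
sequence (allowing a bounded number of mismatches) and pairs forward/reverse
sites into candidate 16S-ITS-23S rRNA operon amplicons within a product-size
window. The default primer pair is the universal operon set 16S-27F
(AGRGTTYGATYHTGGCTCAG) and 23S-2241R (ACCRCCCCAGTHRAACT), with at most two
mismatches per primer and products of 3,500-7,000 bp.

Coordinates are 0-based half-open on the forward strand. Amplicon sequences
are reported 5'->3' in amplicon orientation and include both primer binding
regions, following the EMBOSS-primersearch "amplimer" convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "IUPACPrimer",
    "PrimerSite",
    "AmpliconHit",
    "iupac_mismatches",
    "find_primer_sites",
    "extract_amplicons",
    "reverse_complement",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
]

#: Degeneracy sets for the 15 IUPAC nucleotide codes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# 4-bit encoding: A=1, C=2, G=4, T=8; anything else 0 (never matches).
_BASE_BITS = np.zeros(256, dtype=np.uint8)
for _b, _v in zip("ACGT", (1, 2, 4, 8)):
    _BASE_BITS[ord(_b)] = _v
    _BASE_BITS[ord(_b.lower())] = _v

_CODE_BITS = {
    code: np.uint8(sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases))
    for code, bases in IUPAC_SETS.items()
}


def reverse_complement(seq: str) -> str:
    """Reverse complement, degenerate-code aware (R<->Y, H<->D, ...)."""
    return seq.upper().translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACPrimer:
    """A PCR primer written in IUPAC nucleotide codes."""

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"primer {self.name!r} has an empty sequence")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"primer {self.name!r} contains invalid IUPAC codes: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


DEFAULT_FWD_PRIMER = IUPACPrimer("16S-27F", "AGRGTTYGATYHTGGCTCAG", "forward")
DEFAULT_REV_PRIMER = IUPACPrimer("23S-2241R", "ACCRCCCCAGTHRAACT", "reverse")


@dataclass(frozen=True)
class PrimerSite:
    """One primer binding window on the forward strand of a contig.

    ``strand`` is '+' when the primer itself matches the forward strand and
    '-' when its reverse complement does (i.e. the primer anneals to the
    forward strand and extends leftward).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    """A full in silico PCR product, spanning both primer regions."""

    contig_id: str
    start: int
    end: int
    strand: str
    product_length: int
    fwd_mismatches: int
    rev_mismatches: int
    sequence: str


def iupac_mismatches(primer_seq: str, window: str) -> int:
    """Count mismatches between a degenerate primer and a genome window.

    A position matches when the window base belongs to the degeneracy set of
    the primer code at that position. N (or any non-ACGT character) in the
    genome window always counts as a mismatch: ambiguity is never given the
    benefit of the doubt.

    Raises ``ValueError`` on length mismatch or an invalid primer code.
    """
    if len(primer_seq) != len(window):
        raise ValueError(
            f"primer length {len(primer_seq)} != window length {len(window)}"
        )
    n = 0
    for code, base in zip(primer_seq.upper(), window.upper()):
        try:
            allowed = IUPAC_SETS[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code in primer: {code!r}") from None
        if base not in allowed:
            n += 1
    return n


def _scan(seq_bits: np.ndarray, primer: str) -> np.ndarray:
    """Per-offset mismatch counts for a primer against an encoded sequence.

    Returns an int array of length ``len(seq) - len(primer) + 1`` (empty when
    the sequence is shorter than the primer).
    """
    L = len(primer)
    n_win = seq_bits.size - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    mm = np.zeros(n_win, dtype=np.int64)
    for j, code in enumerate(primer):
        mm += (seq_bits[j : j + n_win] & _CODE_BITS[code]) == 0
    return mm


def find_primer_sites(
    contig: str,
    primer: IUPACPrimer,
    max_mismatch: int = 2,
    contig_id: str = "",
) -> list[PrimerSite]:
    """All binding sites of ``primer`` on both strands of ``contig``.

    Forward-strand matches are reported with strand '+', matches of the
    primer's reverse complement with strand '-'. Coordinates always refer to
    the forward strand. Sites are sorted by start (then strand).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if not contig:
        return []
    seq_bits = _BASE_BITS[np.frombuffer(contig.encode("ascii"), dtype=np.uint8)]
    sites: list[PrimerSite] = []
    L = len(primer)
    for strand, pseq in (("+", primer.sequence), ("-", reverse_complement(primer.sequence))):
        mm = _scan(seq_bits, pseq)
        for start in np.flatnonzero(mm <= max_mismatch):
            sites.append(
                PrimerSite(contig_id, int(start), int(start) + L, strand, int(mm[start]))
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _pair_sites(
    left: list[PrimerSite], right: list[PrimerSite], min_len: int, max_len: int
) -> list[tuple[PrimerSite, PrimerSite]]:
    """Greedy leftmost pairing: each left site takes the nearest unconsumed
    downstream right site; the pair is emitted only if the spanned product
    falls inside the size window. Either way both sites are spent for that
    pairing attempt only when a product is emitted."""
    pairs = []
    used: set[int] = set()
    right_sorted = sorted(right, key=lambda s: s.start)
    for ls in sorted(left, key=lambda s: s.start):
        for i, rs in enumerate(right_sorted):
            if i in used or rs.start < ls.end:
                continue
            if min_len <= rs.end - ls.start <= max_len:
                pairs.append((ls, rs))
                used.add(i)
            break  # nearest downstream site only
    return pairs


def extract_amplicons(
    contig: str,
    fwd: IUPACPrimer = DEFAULT_FWD_PRIMER,
    rev: IUPACPrimer = DEFAULT_REV_PRIMER,
    max_mismatch: int = 2,
    min_len: int = 3500,
    max_len: int = 7000,
    contig_id: str = "",
) -> list[AmpliconHit]:
    """In silico PCR products of a primer pair on both strands of a contig.

    A plus-strand product runs from a forward-primer site to the nearest
    downstream site of the reverse primer's reverse complement; minus-strand
    products are the mirror case. Products outside [min_len, max_len] are
    discarded. Output is sorted by (contig_id, start).
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    contig = contig.upper()
    f_sites = find_primer_sites(contig, fwd, max_mismatch, contig_id)
    r_sites = find_primer_sites(contig, rev, max_mismatch, contig_id)

    hits: list[AmpliconHit] = []
    # Plus strand: fwd(+) ... revcomp(rev)(-).
    for fs, rs in _pair_sites(
        [s for s in f_sites if s.strand == "+"],
        [s for s in r_sites if s.strand == "-"],
        min_len,
        max_len,
    ):
        seq = contig[fs.start : rs.end]
        hits.append(
            AmpliconHit(
                contig_id, fs.start, rs.end, "+", rs.end - fs.start,
                fs.mismatches, rs.mismatches, seq,
            )
        )
    # Minus strand: rev(+) ... revcomp(fwd)(-); mirror the greedy order so the
    # pairing is leftmost in amplicon (minus) orientation.
    minus_fwd = [s for s in f_sites if s.strand == "-"]
    minus_rev = [s for s in r_sites if s.strand == "+"]
    used: set[int] = set()
    rev_sorted = sorted(minus_rev, key=lambda s: -s.start)
    for fs in sorted(minus_fwd, key=lambda s: -s.start):
        for i, rs in enumerate(rev_sorted):
            if i in used or rs.end > fs.start:
                continue
            if min_len <= fs.end - rs.start <= max_len:
                seq = reverse_complement(contig[rs.start : fs.end])
                hits.append(
                    AmpliconHit(
                        contig_id, rs.start, fs.end, "-", fs.end - rs.start,
                        fs.mismatches, rs.mismatches, seq,
                    )
                )
                used.add(i)
            break
    hits.sort(key=lambda h: (h.contig_id, h.start))
    return hits


def extract_from_records(
    records: Iterable[tuple[str, str]],
    fwd: IUPACPrimer = DEFAULT_FWD_PRIMER,
    rev: IUPACPrimer = DEFAULT_REV_PRIMER,
    max_mismatch: int = 2,
    min_len: int = 3500,
    max_len: int = 7000,
) -> list[AmpliconHit]:
    """Run extract_amplicons over (contig_id, sequence) records."""
    hits: list[AmpliconHit] = []
    for contig_id, seq in records:
        hits.extend(
            extract_amplicons(
                seq, fwd, rev, max_mismatch, min_len, max_len, contig_id=contig_id
            )
        )
    return hits
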