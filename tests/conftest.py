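"""Shared fixtures: synthetic panels and a curation fixture with planted defects."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from operontax import mock_spec, synth_panel
from operontax.community_sim import _random_seq


@pytest.fixture(scope="session")
def mock1_panel():
    """Synthetic 8-species panel named after the MOCK1 community."""
    return synth_panel(species_names=mock_spec("MOCK1").species, seed=1)


def embed_operons(copies: list[str], rng: np.random.Generator) -> str:
    """Plant operon copies in random genomic background, >=1 kb flanks and
    ~3 kb spacers so cross-copy primer pairings exceed the product window."""
    parts = [_random_seq(1000, rng)]
    for c in copies:
        parts.append(c)
        parts.append(_random_seq(3000, rng))
    return "".join(parts)


@pytest.fixture(scope="session")
def curation_fixture(tmp_path_factory) -> dict:
    """Twelve genome assemblies with known planted curation defects.

    Planted ground truth: one genome whose operon contains an N (ambiguity
    removal), one genome whose two operon copies byte-duplicate another
    genome of the same species (2 within-species duplicates), and one
    single-genome species whose operon is copied verbatim from a
    three-genome species (cross-species contaminant). Everything else is
    clean and must survive.
    """
    base = synth_panel(
        n_species=7,
        copies_per_genome=(2, 2),
        between_species_divergence=0.10,
        within_species_divergence=0.002,
        seed=42,
    )
    rng = np.random.default_rng(77)
    sp = base.species  # generic labels "Synthsp species001" ...
    ops = base.operons

    def mutate(seq: str, rate: float) -> str:
        from operontax.community_sim import _mutate_interior
        return _mutate_interior(seq, rate, 20, 17, rng)

    genomes: dict[str, tuple[str, str]] = {}  # asm -> (species, genome seq)
    # sp[0]: asm1 clean, asm9 duplicates asm1's two copies exactly
    genomes["ASM001"] = (sp[0], embed_operons(ops[sp[0]], rng))
    genomes["ASM009"] = (sp[0], embed_operons(ops[sp[0]], rng))
    # sp[1]: asm2 clean, asm10 carries an N inside its operon
    genomes["ASM002"] = (sp[1], embed_operons(ops[sp[1]], rng))
    ambiguous = ops[sp[1]][0]
    ambiguous = ambiguous[:2000] + "N" + ambiguous[2001:]
    genomes["ASM010"] = (sp[1], embed_operons([ambiguous], rng))
    # sp[2]: three clean assemblies (non-minor), plus a contaminant species
    # whose single operon is an exact copy of ASM003's first operon
    genomes["ASM003"] = (sp[2], embed_operons(ops[sp[2]], rng))
    genomes["ASM004"] = (sp[2], embed_operons([mutate(o, 0.002) for o in ops[sp[2]]], rng))
    genomes["ASM005"] = (sp[2], embed_operons([mutate(o, 0.002) for o in ops[sp[2]]], rng))
    genomes["ASM011"] = ("Contaminomonas planted", embed_operons([ops[sp[2]][0]], rng))
    # four more clean single-assembly species
    genomes["ASM006"] = (sp[3], embed_operons(ops[sp[3]], rng))
    genomes["ASM007"] = (sp[4], embed_operons(ops[sp[4]], rng))
    genomes["ASM008"] = (sp[5], embed_operons(ops[sp[5]], rng))
    genomes["ASM012"] = (sp[6], embed_operons(ops[sp[6]], rng))

    root = tmp_path_factory.mktemp("curation_fixture")
    gdir = root / "genomes"
    gdir.mkdir()
    tax_path = root / "taxonomy.tsv"
    with open(tax_path, "w") as tax:
        for asm, (species, genome) in sorted(genomes.items()):
            genus = species.split()[0]
            (gdir / f"{asm}.fasta").write_text(f">{asm}_c1\n{genome}\n")
            tax.write(
                f"{asm}\td__Bacteria;p__{genus}_p;c__{genus}_c;o__{genus}_o;"
                f"f__{genus}_f;g__{genus};s__{species}\n"
            )
    return {
        "genome_dir": gdir,
        "taxonomy_tsv": tax_path,
        "contaminant_assembly": "ASM011",
        "ambiguous_assembly": "ASM010",
        "duplicate_assembly": "ASM009",
        "n_genomes": 12,
        "clean_assemblies": sorted(
            set(genomes) - {"ASM009", "ASM010", "ASM011"}
        ),
    }
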