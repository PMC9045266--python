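"""Curate a reference database from genome assemblies.

Writes a synthetic 8-genome panel to disk (FASTA per assembly + taxonomy
TSV), runs the curation cascade (ambiguity filter, species-level taxonomy,
copy-number calculation, within-species dedup, 99%-identity clustering with
a cross-species contamination screen) and prints the per-stage report.
"""

import tempfile
from pathlib import Path

from operontax import build_database, synth_panel

with tempfile.TemporaryDirectory() as td:
    panel = synth_panel(n_species=8, copies_per_genome=(1, 5), seed=11)
    genome_dir, taxonomy_tsv = panel.write_database_inputs(td)
    db = build_database(genome_dir, taxonomy_tsv, outdir=Path(td) / "db")

    r = db.report
    print("curation report:")
    print(f"  genomes in                {r.genomes_in}")
    print(f"  with amplicons            {r.genomes_with_amplicons}")
    print(f"  removed: ambiguity        {r.genomes_ambiguity_removed}")
    print(f"  removed: no species       {r.genomes_unassigned_removed}")
    print(f"  removed: duplicates       {r.duplicate_sequences_removed} sequences")
    print(f"  removed: contamination    {r.genomes_contamination_removed} genomes")
    print(f"  final: {r.final_sequences} sequences / {r.final_species} species / {r.final_genomes} genomes")
    print("mean operon copies per genome:")
    for sp, cn in sorted(db.copy_number.items()):
        print(f"  {sp}: {cn:g}")
# The copy numbers are computed before deduplication, so they reflect how
# many operons each genome actually carries - the divisor used for
# copy-number-normalized abundance profiles.
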