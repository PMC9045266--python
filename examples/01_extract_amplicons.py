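"""In silico PCR: pull 16S-ITS-23S operon amplicons out of a genome.

Builds a small synthetic genome with three planted operon copies, scans it
with the universal degenerate primer pair (16S-27F / 23S-2241R, up to two
mismatches per primer) and prints every product in the 3,500-7,000 bp
window.
"""

from operontax import extract_amplicons, synth_panel

panel = synth_panel(n_species=1, copies_per_genome=(3, 3), seed=4)
species = panel.species[0]
genome = panel.genomes[species]

hits = extract_amplicons(genome, contig_id="contig1")
print(f"genome of {len(genome):,} bp -> {len(hits)} amplicons")
for h in hits:
    print(
        f"  {h.contig_id}:{h.start}-{h.end} ({h.strand})  "
        f"{h.product_length} bp, primer mismatches fwd={h.fwd_mismatches} rev={h.rev_mismatches}"
    )
# Each line is one PCR product: its forward-strand coordinates, the strand
# the amplicon reads 5'->3' on, its length, and how many bases in each
# primer binding site deviated from the degenerate primer.
assert len(hits) == len(panel.operons[species])
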