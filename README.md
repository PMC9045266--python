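# operontax

Reference curation and taxonomic profiling for **long-read 16S-ITS-23S rRNA
operon metataxonomics**.

Short-read 16S surveys target a few hundred bases of the 16S rRNA gene and
often cannot resolve communities below genus level. Long-read platforms can
sequence the full ~4,300 bp span from the 16S gene across the internal
transcribed spacer (ITS) into the 23S gene, which carries enough variation
to separate species — but only if a curated operon reference exists and the
classifier is built for reads with several percent error. `operontax` is a
toolkit for both sides of that problem, aimed at microbiome researchers
working with Nanopore (or similar) amplicon data:

- **In silico PCR** — locate binding sites of the universal degenerate
  primer pair 16S-27F (`AGRGTTYGATYHTGGCTCAG`) / 23S-2241R
  (`ACCRCCCCAGTHRAACT`) on both strands of genome assemblies, allowing up to
  2 mismatches per primer, and extract products of 3,500–7,000 bp.
- **Database curation** — a fixed cascade over the extracted amplicons:
  drop genomes with ambiguous bases in any operon; require a species-level
  GTDB-style taxonomy (alphabetic suffixes such as `_A` are ignored);
  compute per-species mean operon copy number; deduplicate identical
  sequences within a species; cluster at 99 % global-alignment identity and
  remove genomes whose operons look copied from another species
  (a minor taxon in a mixed cluster whose best hit is foreign).
- **Profiling** — length-filter reads to 3,500–5,000 bp, ingest PAF
  alignments (or run `minimap2 -cx map-ont --secondary=no` directly), keep
  only primary alignments with residue matches ≥ 2,500 bp and alignment
  block length ≥ 3,500 bp, assign each read to its best remaining hit, and
  aggregate per-rank relative abundances, optionally divided by operon copy
  number. Outputs include per-rank TSV, a QC table and Krona-compatible
  text.
- **Simulation** — synthetic multi-copy operon-bearing genomes with
  controlled between/within-species divergence, the two ZymoBIOMICS mock
  community compositions (8 and 14 bacterial species), and an i.i.d.
  substitution/insertion/deletion read-error model, so every pipeline stage
  is testable without downloading genomes.
- **Evaluation** — L2 distance between estimated and expected abundance
  vectors (Σ(estᵢ−expᵢ)², reported by default as its square root on
  percent-scale vectors), Bray-Curtis dissimilarity Σ|p−q|/Σ(p+q),
  rarefaction of species richness, Shannon taxonomic entropy −Σ f ln f, and
  correctly/mis/not-assigned read accounting.

## Worked example

```python
from operontax import mock_spec
from operontax.community_sim import ErrorModel
from operontax.experiments import run_recovery

spec = mock_spec("MOCK1")           # 8 species, theoretical operon-level %
res = run_recovery(spec, n_reads=2000,
                   error=ErrorModel(0.03, 0.02, 0.03, seed=1), panel_seed=1)
for sp in sorted(res.expected_percent, key=res.expected_percent.get, reverse=True):
    print(f"{sp:30s} est {res.recovered_percent.get(sp, 0):6.2f}%  "
          f"exp {res.expected_percent[sp]:6.2f}%")
print(f"L2 = {res.l2:.2f}")
```

prints (seeds as above):

```
Lactobacillus fermentum        est  18.90%  exp  18.40%
Bacillus marinus               est  17.10%  exp  17.40%
Staphylococcus aureus          est  15.30%  exp  15.50%
Listeria monocytogenes         est  15.35%  exp  14.10%
Salmonella enterica            est   9.75%  exp  10.40%
Escherichia flexneri           est  10.35%  exp  10.10%
Enterococcus faecalis          est   9.00%  exp   9.90%
Pseudomonas aeruginosa         est   4.25%  exp   4.20%
L2 = 1.80
```

Each line compares the relative abundance recovered from 2,000 simulated
~8 %-error reads with the community's theoretical composition; the residual
differences are multinomial sampling noise. `examples/` contains narrative
scripts for each capability; the same workflow is available from the shell
via the `operontax` command (`extract`, `build-db`, `profile`, `simulate`,
`evaluate`).

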