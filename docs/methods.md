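# Methods

This note records how `operontax` models the 16S-ITS-23S rRNA operon
workflow, the defaults it ships with and why, what the synthetic data does
and does not emulate, and the numerical choices a maintainer would want
written down.

## In silico PCR

Primer binding sites are found by exhaustive window scanning on both
strands. A window position matches a primer position when the genome base
lies in the IUPAC degeneracy set of the primer code; an `N` (or any
non-ACGT character) in the genome always counts as a mismatch — ambiguity
is never allowed to satisfy a primer, which keeps this stage consistent
with the later ambiguity filter. The scan is vectorized as a 4-bit
base-mask convolution (O(genome × primer length) with numpy), and its
results are checked in the tests against a per-window set-membership
oracle.

Amplicons follow the EMBOSS-primersearch "amplimer" convention: the product
spans from the 5′ end of the forward-primer site to the far end of the
reverse-primer site, so both primer regions are included — which is why
typical products are ~4,300 bp rather than ~4,260. Pairing is greedy and
leftmost in amplicon orientation: each forward site takes the nearest
downstream reverse-complemented reverse-primer site and the pair is emitted
only if the product lies in the size window; a site is consumed by at most
one product. Nested or overlapping alternative pairings are deliberately
not enumerated — the output must be a deterministic function of the
sequence. The minus strand is handled by the mirror-image procedure, which
makes amplicon extraction exactly strand-symmetric (a tested invariant).

Mismatch budgets apply **per primer** (2 each by default), not jointly;
whether the original extraction tool budgeted jointly is not documentable,
and per-primer is the more permissive, simpler contract.

Defaults: primers 16S-27F / 23S-2241R, `max_mismatch=2`, product window
3,500–7,000 bp. All are configurable.

## Curation cascade

Order is fixed: extraction → ambiguity filter → taxonomy attachment →
copy-number calculation → within-species dedup → clustering/contamination
screen. Each stage's removals are disjoint from later stages' inputs and
the report reconciles exactly; a genome whose sequences are all duplicates
survives as a genome with zero sequences (its first-seen twin carries the
sequence).

Choices worth recording:

- **Ambiguity** removes the whole genome, not the offending amplicon: one
  ambiguous operon is taken as evidence of low assembly quality.
- **Taxonomy** arrives as a TSV of GTDB-style lineages; whole-genome
  taxonomic reassignment is an external concern. Alphabetic species
  suffixes (`_A`) are stripped before any species comparison. The stripper
  only removes a final `_` + uppercase-letters token when what remains is
  not itself a rank prefix.
- **Dedup** keeps, per species, one record per distinct sequence — the
  lexicographically first (assembly, record) — a deterministic tie-break.
  Identical sequences in *different* species are both kept here; deciding
  which one is wrong is the contamination screen's job.
- **Clustering** is greedy centroid clustering in length-descending order
  (cd-hit style), identity defined as matches / alignment columns of a
  global (Needleman-Wunsch) alignment computed with edlib; a length-ratio
  bound prunes pairs that cannot reach the threshold. Default threshold
  0.99. The tests replay the same greedy order with an independent
  Biopython aligner as the oracle.
- **Contamination screen**: in a mixed-species cluster, a *minor taxon* is
  a species backed by ≤ 2 genomes in that cluster (`minor_genome_threshold`,
  configurable — the natural-language definition "derived from less than
  two genomes" is ambiguous between <2 and ≤2, so the threshold is
  exposed). A minor-taxon record is contaminated when its best-identity
  match over all other records (own assembly excluded) is foreign and
  strictly beats its best same-species match, or it has no same-species
  record at all. The flagged genome is removed entirely, clean copies
  included. This replaces manual BLAST/phylogeny adjudication with a
  deterministic best-hit rule — a tool that runs unattended cannot ask a
  curator.
- **Copy number** is the per-species mean of amplicons-per-assembly,
  computed on the post-taxonomy, **pre-dedup** set (dedup would bias copies
  downward for species with identical intragenomic copies); a post-dedup
  mode exists for sensitivity analysis.

## Profiling

The classifier is deliberately thin: alignment is delegated to a long-read
mapper (any PAF source; the built-in runner calls
`minimap2 -cx map-ont --secondary=no -t 1`). The `-c` flag matters: without
base-level alignment PAF column 10 holds anchor counts, not residue
matches, and the ≥ 2,500 bp filter would reject everything. The bespoke
contract is the filter and assignment: primary alignments only, residue
matches ≥ 2,500 bp (PAF col 10) and block length ≥ 3,500 bp (col 11); the
read's best passing alignment wins, ties broken by block length then
lexicographic target id, making assignment deterministic even when the
mapper emits duplicates. Mapping quality is parsed but unused by default.

Reads outside 3,500–5,000 bp are removed before alignment (full-length
amplicon products; anything shorter/longer is truncated, chimeric or
concatemeric). Relative abundances are computed over **assigned** reads
only. Copy-number normalization (divide species counts by mean copies,
renormalize, aggregate upward) is **off** by default: raw and normalized
profiles answer different questions (gene copies vs organisms) and the
published convention for mock profiles is not stated, so both are exposed.

## Synthetic data

The generator emulates exactly what the pipeline consumes: one ancestral
~4,300 bp operon whose termini are concrete realizations of the primer
pair; species mutate the interior i.i.d. at a between-species rate (default
0.10 — far below 99 % identity, so species never co-cluster), copies within
a genome at a within-species rate (default 0.005, mimicking intragenomic
operon heterogeneity; two copies are then ~1 % apart, straddling the 0.99
clustering threshold, which is harmless because single-species clusters are
never screened). Copies are embedded on random strands in random background
with ≥ 1 kb flanks and ~3 kb spacers, so cross-copy primer pairings exceed
the 7 kb product window and extraction recovers exactly the planted copies
(a tested invariant). Mutations are substitutions only, keeping operon
lengths inside the read window.

Read errors are i.i.d. per base — deletion, else substitution, by one
uniform draw; then at most one insertion per gap — with defaults
3 %/2 %/3 % (~8 % total), a Nanopore-like overall rate. This parametric
model reproduces the *rate* of errors but none of the structure of real
basecalls: no homopolymer bias, no quality scores, no chimeras, no
truncated reads. Passing the recovery benchmarks therefore shows the
filter/assignment logic is sound at realistic error loads, not that any
particular flow-cell chemistry will behave identically. Mock compositions
are the two ZymoBIOMICS standards' theoretical operon-level percentages,
bacteria only, renormalized to 1 (the 8-species set sums to 100.0 exactly;
the 14-bacteria gut set to 99.93 before renormalization).

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical panels and
FASTQ.

## Benchmark problem sizes

The recovery experiments use 5,000 multinomially sampled reads per mock
community (multinomial σ ≈ 0.5 percentage points for a 18 % member, an
order of magnitude inside the ±2-point acceptance band) and 1,000 reads for
the zero-error round trip; the fixed-design mode reproduces the
27 species × 100 reads = 2,700-read gut panel arithmetic. These sizes give
stable estimates while keeping a full end-to-end run under a minute on one
CPU.

## Known limitations

- Identity is edit-distance-based (unit costs); a scoring-matrix aligner
  would place gaps slightly differently near the 99 % boundary.
- The contamination screen is all-pairs within the record set; fine at
  desk scale, quadratic in general (the cluster structure would bound it
  for large databases).
- Unlinked rRNA operons (16S and 23S on different contigs/loci) yield no
  amplicon and are invisible to this marker, as for any operon-spanning
  approach; fragmented assemblies likewise drop out.
- The error model ignores homopolymer structure, so length-dependent
  deletion artifacts of real basecallers are not represented.
- Archaea are out of scope (the default primer pair is bacterial).
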