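"""Curation cascade: ambiguity, taxonomy, dedup, clustering, contamination."""

import numpy as np
import pytest
from Bio import Align

from operontax.db_curation import (
    OperonRecord,
    alignment_identity,
    build_database,
    cluster_sequences,
    compute_copy_number,
    dedup_within_species,
    detect_cross_species,
    filter_ambiguous,
    remove_contaminated,
)
from operontax.insilico_pcr import AmpliconHit
from operontax.io import Lineage, strip_gtdb_suffix


def hit(seq, contig="c", start=0):
    return AmpliconHit(contig, start, start + len(seq), "+", len(seq), 0, 0, seq)


def rec(rid, asm, species, seq):
    lin = Lineage("d__Bacteria", "p__P", "c__C", "o__O", "f__F", "g__G", f"s__{species}")
    return OperonRecord(rid, asm, lin, seq)


class TestAmbiguityFilter:
    def test_assembly_with_any_ambiguous_amplicon_removed(self):
        kept, removed = filter_ambiguous(
            {"a1": [hit("ACGTACGT"), hit("ACNTACGT")], "a2": [hit("ACGTACGT")]}
        )
        assert removed == ["a1"]
        assert list(kept) == ["a2"]

    def test_empty_input(self):
        assert filter_ambiguous({}) == ({}, [])


class TestTaxonomy:
    def test_species_suffix_stripping(self):
        assert strip_gtdb_suffix("s__Bacillus subtilis_A") == "s__Bacillus subtilis"
        assert strip_gtdb_suffix("s__Bacillus subtilis") == "s__Bacillus subtilis"
        a = rec("r1", "a1", "Bacillus subtilis_A", "ACGT")
        b = rec("r2", "a2", "Bacillus subtilis", "ACGT")
        assert a.species == b.species

    def test_blank_species_dropped(self):
        from operontax.db_curation import attach_taxonomy

        tax = {
            "a1": Lineage.from_string("d__B;p__P;c__C;o__O;f__F;g__G;s__Escherichia flexneri"),
            "a2": Lineage.from_string("d__B;p__P;c__C;o__O;f__F;g__G;s__"),
        }
        records, dropped = attach_taxonomy(
            {"a1": [hit("ACGT")], "a2": [hit("ACGT")], "a3": [hit("ACGT")]}, tax
        )
        assert [r.assembly_id for r in records] == ["a1"]
        assert records[0].lineage.species == "s__Escherichia flexneri"
        assert sorted(dropped) == ["a2", "a3"]  # blank species + absent from table


class TestDedup:
    def test_within_species_duplicates_collapse(self):
        records = [
            rec("r1", "a1", "X", "ACGTACGT"),
            rec("r2", "a2", "X", "ACGTACGT"),
            rec("r3", "a1", "X", "ACGTACGA"),
        ]
        kept, n = dedup_within_species(records)
        assert n == 1
        assert {r.record_id for r in kept} == {"r1", "r3"}  # first by (assembly, record)

    def test_cross_species_identical_sequences_both_kept(self):
        records = [rec("r1", "a1", "X", "ACGT"), rec("r2", "a2", "Y", "ACGT")]
        kept, n = dedup_within_species(records)
        assert n == 0 and len(kept) == 2

    def test_idempotent(self):
        records = [rec("r1", "a1", "X", "AC"), rec("r2", "a2", "X", "AC")]
        once, n1 = dedup_within_species(records)
        twice, n2 = dedup_within_species(once)
        assert n1 == 1 and n2 == 0 and twice == once


def _oracle_identity(a: str, b: str) -> float:
    """Independent global-alignment identity via Biopython PairwiseAligner."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y for x, y in zip(sa, sb))
    return matches / len(sa)


class TestClustering:
    def test_identical_sequences_share_a_cluster(self):
        records = [rec("r1", "a1", "X", "ACGT" * 300), rec("r2", "a2", "X", "ACGT" * 300)]
        clusters = cluster_sequences(records)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_divergent_sequences_split(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=1000))
        mutated = list(base)
        for i in rng.choice(1000, size=50, replace=False):  # ~95% identity
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        records = [rec("r1", "a1", "X", base), rec("r2", "a2", "X", "".join(mutated))]
        assert len(cluster_sequences(records, 0.99)) == 2

    def test_memberships_match_all_pairs_oracle(self):
        """Greedy clustering agrees with an all-pairs-identity oracle applied
        in the same length-descending greedy order."""
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), size=800))
        seqs = []
        for fam in range(4):
            fam_seq = list(base)
            for i in rng.choice(800, size=40 * (fam + 1), replace=False):
                fam_seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fam_seq[i]]
            fam_seq = "".join(fam_seq)
            seqs.append(fam_seq)
            for _ in range(3):
                near = list(fam_seq)
                for i in rng.choice(800, size=2, replace=False):
                    near[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[i]]
                seqs.append("".join(near))
        records = [rec(f"r{i:02d}", f"a{i:02d}", "X", s) for i, s in enumerate(seqs)]
        got = cluster_sequences(records, 0.99)

        order = sorted(records, key=lambda r: (-r.length, r.record_id))
        oracle_clusters: list[list[str]] = []
        centroids: list[str] = []
        for r in order:
            for ci, cen in enumerate(centroids):
                if _oracle_identity(r.sequence, cen) >= 0.99:
                    oracle_clusters[ci].append(r.record_id)
                    break
            else:
                oracle_clusters.append([r.record_id])
                centroids.append(r.sequence)
        assert [sorted(c.members) for c in got] == [sorted(c) for c in oracle_clusters]

    def test_identity_definition(self):
        assert alignment_identity("ACGT", "ACGT") == 1.0
        assert alignment_identity("ACGT", "ACTT") == pytest.approx(0.75)
        # one gap: 4 matches over 5 alignment columns
        assert alignment_identity("ACGT", "ACGTT") == pytest.approx(4 / 5)


class TestContaminationScreen:
    def _mixed_cluster_records(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), size=1000))
        records = [rec(f"rX{i}", f"aX{i}", "X", base) for i in range(5)]
        records.append(rec("rY0", "aY0", "Y", base))  # identical to X, no other Y
        return records

    def test_minor_taxon_with_foreign_best_hit_flagged(self):
        records = self._mixed_cluster_records()
        clusters = cluster_sequences(records)
        assert detect_cross_species(clusters, records) == ["aY0"]

    def test_single_species_cluster_never_flagged(self):
        records = [rec(f"r{i}", f"a{i}", "X", "ACGT" * 250) for i in range(3)]
        clusters = cluster_sequences(records)
        assert detect_cross_species(clusters, records) == []

    def test_minor_taxon_closer_to_own_species_not_flagged(self):
        """Best-hit rule verified against an exhaustive identity comparison."""
        rng = np.random.default_rng(3)
        base = list("".join(rng.choice(list("ACGT"), size=1000)))
        far = list(base)
        for i in rng.choice(1000, size=8, replace=False):
            far[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[far[i]]
        positions = rng.choice(1000, size=3, replace=False)
        near = list(base)
        for i in positions[:2]:
            near[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[i]]
        near2 = list(near)
        i = positions[2]
        near2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near2[i]]
        far2 = list(base)
        for i in rng.choice(1000, size=5, replace=False):
            far2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[far2[i]]
        records = [
            rec("rX0", "aX0", "X", "".join(base)),
            rec("rX1", "aX1", "X", "".join(far)),
            rec("rX2", "aX2", "X", "".join(far2)),  # X: 3 genomes, non-minor
            rec("rY0", "aY0", "Y", "".join(near)),
            rec("rY1", "aY1", "Y", "".join(near2)),  # Y's own species holds the best hit
        ]
        # exhaustive best-hit oracle: each Y record's best same-species
        # identity strictly beats its best cross-species identity
        for yi, other_y in ((3, 4), (4, 3)):
            same = _oracle_identity(records[yi].sequence, records[other_y].sequence)
            cross = max(
                _oracle_identity(records[yi].sequence, records[xi].sequence)
                for xi in (0, 1, 2)
            )
            assert same > cross
        clusters = cluster_sequences(records)
        assert detect_cross_species(clusters, records) == []

    def test_remove_contaminated_drops_whole_assembly(self):
        records = [
            rec("r1", "a1", "X", "AAAA"),
            rec("r2", "a1", "X", "CCCC"),
            rec("r3", "a1", "X", "GGGG"),
            rec("r4", "a1", "X", "TTTT"),
            rec("r5", "a2", "Y", "ACGT"),
        ]
        out = remove_contaminated(records, ["a1"])
        assert [r.record_id for r in out] == ["r5"]
        assert remove_contaminated(records, []) == records


class TestCopyNumber:
    def test_mean_over_assemblies(self):
        records = [rec(f"r{i}", "a1", "X", f"A{i}") for i in range(4)]
        records += [rec(f"s{i}", "a2", "X", f"C{i}") for i in range(2)]
        assert compute_copy_number(records) == {"s__X": 3.0}

    def test_single_assembly(self):
        records = [rec(f"r{i}", "a1", "X", f"A{i}") for i in range(7)]
        assert compute_copy_number(records) == {"s__X": 7.0}

    def test_weighted_sum_conserves_total(self):
        rng = np.random.default_rng(4)
        records = []
        for s in range(5):
            for a in range(int(rng.integers(1, 4))):
                for c in range(int(rng.integers(1, 6))):
                    records.append(rec(f"r{s}{a}{c}", f"a{s}{a}", f"S{s}", f"{s}{a}{c}"))
        cn = compute_copy_number(records)
        n_asm = {
            sp: len({r.assembly_id for r in records if r.species == sp}) for sp in cn
        }
        assert sum(cn[sp] * n_asm[sp] for sp in cn) == pytest.approx(len(records))

    def test_invariant_under_reordering(self):
        records = [rec(f"r{i}", f"a{i % 3}", "X", f"A{i}") for i in range(6)]
        assert compute_copy_number(records) == compute_copy_number(records[::-1])


class TestBuildDatabase:
    def test_planted_defects_detected_and_report_reconciles(self, curation_fixture):
        db = build_database(curation_fixture["genome_dir"], curation_fixture["taxonomy_tsv"])
        rep = db.report
        assert rep.genomes_in == 12
        assert rep.genomes_with_amplicons == 12
        assert rep.genomes_ambiguity_removed == 1
        assert rep.genomes_unassigned_removed == 0
        assert rep.duplicate_sequences_removed == 2
        assert rep.genomes_contamination_removed == 1
        surviving = {r.assembly_id for r in db.records}
        assert curation_fixture["contaminant_assembly"] not in surviving
        assert curation_fixture["ambiguous_assembly"] not in surviving
        for asm in curation_fixture["clean_assemblies"]:
            assert asm in surviving
        assert rep.final_genomes == len(surviving)
        assert rep.final_sequences == len(db.records)
        assert rep.final_species == len({r.species for r in db.records})
        # no within-species duplicates in the final set
        assert len({(r.species, r.sequence) for r in db.records}) == len(db.records)
        # every surviving species has a copy number >= 1
        for r in db.records:
            assert db.copy_number[r.species] >= 1

    def test_deterministic_rerun(self, curation_fixture):
        a = build_database(curation_fixture["genome_dir"], curation_fixture["taxonomy_tsv"])
        b = build_database(curation_fixture["genome_dir"], curation_fixture["taxonomy_tsv"])
        assert a.report == b.report
        assert [r.record_id for r in a.records] == [r.record_id for r in b.records]

    def test_empty_genome_dir(self, tmp_path):
        empty = tmp_path / "genomes"
        empty.mkdir()
        tax = tmp_path / "tax.tsv"
        tax.write_text("")
        db = build_database(empty, tax)
        assert db.records == [] and db.report.genomes_in == 0

    def test_save_load_roundtrip(self, curation_fixture, tmp_path):
        db = build_database(
            curation_fixture["genome_dir"], curation_fixture["taxonomy_tsv"],
            outdir=tmp_path / "db",
        )
        from operontax.db_curation import ReferenceDB

        loaded = ReferenceDB.load(tmp_path / "db")
        assert [r.record_id for r in loaded.records] == [r.record_id for r in db.records]
        assert loaded.copy_number == db.copy_number
        assert loaded.report == db.report
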