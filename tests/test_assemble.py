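import itertools

import numpy as np
import pytest

from conftest import make_read
from radphylo.assemble import (
    ClusterAlignment,
    EmptyAlignmentListError,
    Supermatrix,
    align_cluster,
    concatenate,
    filter_min_taxa,
    filter_paralogs,
    matrix_stats,
)
from radphylo.cluster import Cluster


def _cluster(cid, *taxon_seq_pairs):
    members = [
        make_read(seq, taxon=taxon, read_id=f"{cid}:{i}")
        for i, (taxon, seq) in enumerate(taxon_seq_pairs)
    ]
    return Cluster(cluster_id=cid, seed_read_id=members[0].read_id, members=members)


class TestFilters:
    def test_paralog_filter_examples(self):
        keep = _cluster("k", ("A", "ACGT"), ("B", "ACGT"))
        drop = _cluster("d", ("A", "ACGT"), ("A", "ACGA"), ("B", "ACGT"))
        assert filter_paralogs([keep, drop]) == [keep]

    def test_all_paralogous_gives_empty_set(self):
        drop = _cluster("d", ("A", "ACGT"), ("A", "ACGA"))
        assert filter_paralogs([drop]) == []

    @pytest.mark.parametrize("n_taxa, k, kept", [(3, 4, False), (4, 4, True), (9, 9, True), (8, 9, False)])
    def test_min_taxa_boundaries(self, n_taxa, k, kept):
        c = _cluster("c", *((f"t{i}", "ACGTACGT") for i in range(n_taxa)))
        assert (filter_min_taxa([c], k) == [c]) is kept

    def test_min_taxa_below_four_warns_but_runs(self):
        c = _cluster("c", ("A", "ACGT"), ("B", "ACGT"), ("C", "ACGT"))
        with pytest.warns(UserWarning, match="unrooted"):
            assert filter_min_taxa([c], 3) == [c]

    def test_filter_order_does_not_change_survivors(self):
        rng = np.random.default_rng(0)
        clusters = []
        for i in range(30):
            n = int(rng.integers(2, 8))
            taxa = [f"t{rng.integers(0, 6)}" for _ in range(n)]
            clusters.append(_cluster(f"c{i}", *((t, "ACGTACGT") for t in taxa)))
        a = filter_min_taxa(filter_paralogs(clusters), 4)
        b = filter_paralogs(filter_min_taxa(clusters, 4))
        assert [c.cluster_id for c in a] == [c.cluster_id for c in b]


class TestAlignCluster:
    def test_identical_reads_align_gapless(self):
        c = _cluster("c", *((f"t{i}", "ACGTACGTAC" * 5) for i in range(5)))
        ca = align_cluster(c)
        assert ca.width == 50
        assert all("-" not in row for row in ca.rows.values())

    def test_substitutions_only_align_gapless(self):
        base = "ACGTACGTAC" * 5
        variants = [base, base[:10] + "A" + base[11:], base[:30] + "C" + base[31:]]
        c = _cluster("c", *((f"t{i}", s) for i, s in enumerate(variants)))
        ca = align_cluster(c)
        assert ca.width == 50
        assert {ca.rows[f"t{i}"] for i in range(3)} == set(variants)

    def test_member_deletion_gets_gap_column(self):
        seed = "ACGTTGCATGCAACGGTTAA"
        member = seed[:8] + seed[9:]  # one base deleted
        c = _cluster("c", ("A", seed), ("B", member))
        ca = align_cluster(c)
        assert ca.width == 20
        assert ca.rows["A"] == seed
        assert ca.rows["B"].count("-") == 1
        assert ca.rows["B"].replace("-", "") == member

    def test_member_insertion_adds_column_for_all(self):
        seed = "ACGTTGCATGCAACGGTTAA"
        member = seed[:10] + "C" + seed[10:]
        c = _cluster("c", ("A", seed), ("B", member), ("C", seed))
        ca = align_cluster(c)
        assert ca.width == 21
        for t, original in (("A", seed), ("B", member), ("C", seed)):
            assert ca.rows[t].replace("-", "") == original

    def test_unfiltered_duplicate_taxa_rejected(self):
        c = _cluster("c", ("A", "ACGT"), ("A", "ACGT"))
        with pytest.raises(ValueError, match="duplicate taxa"):
            align_cluster(c)


def _aln(lid, rows):
    return ClusterAlignment(locus_id=lid, rows=rows)


class TestConcatenate:
    def test_missing_taxon_filled_and_width_conserved(self):
        a1 = _aln("l1", {t: "ACGTACGTAC" * 5 for t in "ABCD"})
        a2 = _aln("l2", {t: "TTGCATGCAT" * 5 for t in "ABC"})
        m = concatenate([a1, a2], list("ABCD"))
        assert m.width == 100
        assert m.rows["D"] == "ACGTACGTAC" * 5 + "?" * 50
        assert m.width == sum(end - start for _, start, end in m.partitions)
        assert not m.incomplete

    def test_taxon_in_no_locus_flags_incomplete(self):
        a1 = _aln("l1", {t: "ACGT" for t in "ABCD"})
        m = concatenate([a1], list("ABCDE"))
        assert m.incomplete

    def test_loci_ordered_by_taxon_count_then_id(self):
        a1 = _aln("b", {t: "AAAA" for t in "ABC"})
        a2 = _aln("a", {t: "CCCC" for t in "ABCD"})
        a3 = _aln("c", {t: "GGGG" for t in "ABC"})
        m = concatenate([a1, a2, a3], list("ABCD"))
        assert [p[0] for p in m.partitions] == ["a", "b", "c"]

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyAlignmentListError):
            concatenate([], list("ABCD"))


class TestMatrixStats:
    def test_identical_rows_have_no_variable_sites(self):
        m = Supermatrix(
            taxa=list("ABCD"),
            rows={t: "ACGTACGT" for t in "ABCD"},
            partitions=[("l", 0, 8)],
        )
        s = matrix_stats(m)
        assert s.variable_sites == 0
        assert s.parsimony_informative_sites == 0
        assert s.missing_fraction == 0.0

    def test_pi_definition_matches_exhaustive_enumeration(self):
        # every 4-taxon column over A,C,G,T: PI iff >= 2 states seen >= 2 times
        taxa = list("ABCD")
        columns = list(itertools.product("ACGT", repeat=4))
        rows = {t: "".join(col[i] for col in columns) for i, t in enumerate(taxa)}
        m = Supermatrix(taxa=taxa, rows=rows, partitions=[("l", 0, len(columns))])
        s = matrix_stats(m)
        expected_var = expected_pi = 0
        for col in columns:
            counts = {b: col.count(b) for b in set(col)}
            if len(counts) >= 2:
                expected_var += 1
                if sum(1 for v in counts.values() if v >= 2) >= 2:
                    expected_pi += 1
        assert s.variable_sites == expected_var
        assert s.parsimony_informative_sites == expected_pi

    def test_specific_columns(self):
        m = Supermatrix(
            taxa=list("ABCD"),
            rows={"A": "AA", "B": "AA", "C": "CC", "D": "CG"},
            partitions=[("l", 0, 2)],
        )
        s = matrix_stats(m)
        # column 0 (AACC): variable and PI; column 1 (AACG): variable, not PI
        assert s.variable_sites == 2
        assert s.parsimony_informative_sites == 1

    def test_missing_fraction_arithmetic(self):
        width = 50
        rows = {t: "A" * width for t in "ABC"}
        rows["D"] = "?" * width
        m = Supermatrix(taxa=list("ABCD"), rows=rows, partitions=[("l", 0, width)])
        s = matrix_stats(m)
        assert s.missing_fraction == pytest.approx(50 / 200)
        assert s.per_taxon_missing["D"] == 1.0
        assert s.per_taxon_missing["A"] == 0.0

    def test_invariant_cluster_fraction(self):
        c_inv = _cluster("i", ("A", "ACGT"), ("B", "ACGT"))
        c_var = _cluster("v", ("A", "ACGT"), ("B", "ACGA"))
        m = Supermatrix(
            taxa=list("AB"),
            rows={"A": "ACGTACGT", "B": "ACGTACGA"},
            partitions=[("i", 0, 4), ("v", 4, 8)],
        )
        s = matrix_stats(m, [c_inv, c_var])
        assert s.invariant_cluster_fraction == 0.5

    def test_per_taxon_pi_representation(self):
        # PI columns where a taxon holds a real base count toward that taxon
        rows = {"A": "AC", "B": "AC", "C": "GT", "D": "G?"}
        m = Supermatrix(taxa=list("ABCD"), rows=rows, partitions=[("l", 0, 2)])
        s = matrix_stats(m)
        assert s.parsimony_informative_sites == 1  # only column 0
        assert s.per_taxon_pi_sites == {"A": 1, "B": 1, "C": 1, "D": 1}
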