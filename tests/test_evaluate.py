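import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from scipy.stats import mannwhitneyu

from conftest import make_read
from oracles import mwu_exact_ref
from radphylo.assemble import ClusterAlignment, Supermatrix, align_cluster
from radphylo.cluster import Cluster
from radphylo.digest import ECORI, LocusTruth
from radphylo.evaluate import (
    LabelGapError,
    LeafSetMismatchError,
    NotOrthologousError,
    UnlabeledReadError,
    alignment_agreement,
    bipartitions,
    classify_topology,
    count_correct_nodes,
    mann_whitney_u,
    orthology_fraction,
    replicate_consistency,
    split_by_orthology,
    split_key,
)
from radphylo.io_formats import ReferenceAlignment, parse_newick

T12 = "(((t0,t1),(t2,t3)),((t4,t5),(t6,t7)),((t8,t9),(t10,t11)));"


class TestBipartitions:
    def test_quartet(self):
        splits = bipartitions(parse_newick("((A,B),(C,D));"))
        assert splits == {frozenset((frozenset("AB"), frozenset("CD")))}

    def test_star_tree_has_none(self):
        assert bipartitions(parse_newick("(A,B,C,D,E);")) == set()

    def test_resolved_12_leaf_tree_has_nine(self):
        assert len(bipartitions(parse_newick(T12))) == 9

    def test_fewer_than_four_leaves_rejected(self):
        with pytest.raises(ValueError):
            bipartitions(parse_newick("(A,B,C);"))


def _random_tree(rng, n):
    taxa = [f"t{i}" for i in range(n)]
    rng.shuffle(taxa)
    nodes = [f"{t}" for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return parse_newick("(" + ",".join(nodes) + ");")


class TestCountCorrectNodes:
    def test_identical_binary_trees_share_all_nodes(self):
        t = parse_newick(T12)
        assert count_correct_nodes(t, parse_newick(T12)) == 9

    def test_single_nni_shares_all_but_one(self):
        ref = parse_newick("(((A,B),(C,D)),(E,F),(G,H));")
        # swap B with (C,D) across the edge above (A,B): one split changes
        nni = parse_newick("(((A,(C,D)),B),(E,F),(G,H));")
        n = len(ref.leaf_nodes())
        assert count_correct_nodes(nni, ref) == n - 4

    def test_consistent_with_robinson_foulds(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 11))
            t1, t2 = _random_tree(rng, n), _random_tree(rng, n)
            tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
            a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
            b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
            a.encode_bipartitions()
            b.encode_bipartitions()
            rf = treecompare.symmetric_difference(a, b)
            assert count_correct_nodes(t1, t2) == (n - 3) - rf // 2

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(LeafSetMismatchError):
            count_correct_nodes(parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));"))


class TestClassifyTopology:
    def test_reference_and_alternative_and_other(self):
        ref = parse_newick("(((A,B),(C,D)),(E,F),(G,H));")
        alt = parse_newick("(((A,B),(C,D)),(E,G),(F,H));")
        other = parse_newick("(((A,C),(B,D)),(E,F),(G,H));")
        assert classify_topology(ref, ref, [alt]) == "reference"
        assert classify_topology(alt, ref, [alt]) == "alternative"
        assert classify_topology(other, ref, [alt]) == "other"

    def test_reference_iff_all_nodes_correct(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = _random_tree(rng, 8)
            ref = _random_tree(rng, 8)
            is_ref = classify_topology(t, ref) == "reference"
            assert is_ref == (count_correct_nodes(t, ref) == 5)


def _labeled_cluster(cid, labels):
    members = [
        make_read("ACGTACGT", taxon=f"t{i}", read_id=f"{cid}:{i}", site_column=col, side=side)
        for i, (col, side) in enumerate(labels)
    ]
    return Cluster(cluster_id=cid, seed_read_id=members[0].read_id, members=members)


class TestOrthologyFraction:
    def test_all_single_locus_is_one(self):
        cl = [_labeled_cluster(f"c{i}", [(5, "upstream")] * 3) for i in range(4)]
        frac, labels = orthology_fraction(cl)
        assert frac == 1.0
        assert all(labels.values())

    def test_three_of_four(self):
        good = [_labeled_cluster(f"c{i}", [(i, "upstream")] * 2) for i in range(3)]
        bad = _labeled_cluster("c3", [(1, "upstream"), (2, "upstream")])
        frac, labels = orthology_fraction(good + [bad])
        assert frac == 0.75
        assert labels["c3"] is False

    def test_side_matters(self):
        mixed = _labeled_cluster("c", [(4, "upstream"), (4, "downstream")])
        frac, _ = orthology_fraction([mixed])
        assert frac == 0.0

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(2)
        clusters = []
        for i in range(40):
            labels = [
                (int(rng.integers(0, 5)), ("upstream", "downstream")[rng.integers(0, 2)])
                for _ in range(rng.integers(1, 5))
            ]
            clusters.append(_labeled_cluster(f"c{i}", labels))
        frac, _ = orthology_fraction(clusters)
        expected = np.mean(
            [len({(r.truth.site_column, r.truth.side) for r in c.members}) == 1 for c in clusters]
        )
        assert frac == pytest.approx(expected)

    def test_unlabeled_read_rejected(self):
        c = Cluster("c", "r", [make_read("ACGT", read_id="r")])
        with pytest.raises(UnlabeledReadError):
            orthology_fraction([c])


class TestSplitByOrthology:
    def _matrix(self):
        return Supermatrix(
            taxa=list("AB"),
            rows={"A": "ACGTACGTTT", "B": "ACGAACGTGG"},
            partitions=[("x", 0, 4), ("y", 4, 8), ("z", 8, 10)],
        )

    def test_widths_and_cells_conserve(self):
        m = self._matrix()
        orth, non = split_by_orthology(m, {"x": True, "y": False, "z": True})
        assert orth.width + non.width == m.width
        assert orth.rows["A"] == "ACGTTT"
        assert non.rows["A"] == "ACGT"
        assert [p[0] for p in orth.partitions] == ["x", "z"]

    def test_all_orthologous_gives_empty_remainder(self):
        m = self._matrix()
        orth, non = split_by_orthology(m, {"x": True, "y": True, "z": True})
        assert orth.rows == m.rows
        assert non.width == 0

    def test_label_gap_rejected(self):
        with pytest.raises(LabelGapError):
            split_by_orthology(self._matrix(), {"x": True})


class TestAlignmentAgreement:
    def _setup(self, disrupt=False):
        rng = np.random.default_rng(4)
        up = "".join(rng.choice(list("ACGT"), 8))
        down = "".join(rng.choice(list("ACGT"), 8))
        row = "ACGT" + up + ECORI.motif + down + "ACGT"
        taxa = ["x", "y", "z"]
        rows = {t: row for t in taxa}
        aln = ReferenceAlignment(taxa=taxa, rows=rows)
        site_col = 12
        reads = [
            make_read(up, taxon=t, read_id=f"{t}:u", site_column=site_col, side="upstream")
            for t in taxa
        ]
        c = Cluster("c", reads[0].read_id, reads)
        ca = align_cluster(c)
        return ca, aln

    def test_substitution_only_cluster_agrees(self):
        ca, aln = self._setup()
        assert alignment_agreement(ca, aln, ECORI, 8) is True

    def test_differently_placed_indel_disagrees(self):
        # reference puts the gap early in the flank; the star aligner,
        # aligning the deleted row against the seed, places it elsewhere
        taxa = ["x", "y"]
        up_x = "AACCGGTTAC"
        row_x = up_x + ECORI.motif + "ACGTACGT"
        row_y = "-" + up_x[1:] + ECORI.motif + "ACGTACGT"
        aln = ReferenceAlignment(taxa=taxa, rows={"x": row_x, "y": row_y})
        site_col = 10
        rx = make_read(up_x, taxon="x", read_id="x:u", site_column=site_col, side="upstream")
        uy = row_y.replace("-", "")[:9]
        ry = make_read(uy, taxon="y", read_id="y:u", site_column=site_col, side="upstream")
        ca = align_cluster(Cluster("c", "x:u", [rx, ry]))
        agree = alignment_agreement(ca, aln, ECORI, 10)
        ref_gap = 0  # reference gap at flank position 0
        own_gap = ca.rows["y"].find("-")
        assert (own_gap == ref_gap) == agree

    def test_requires_fully_orthologous_cluster(self):
        ca = ClusterAlignment("c", {"x": "ACGT"}, truth_keys=frozenset({(1, "upstream"), (2, "upstream")}))
        aln = ReferenceAlignment(taxa=["x"], rows={"x": "ACGT"})
        with pytest.raises(NotOrthologousError):
            alignment_agreement(ca, aln, ECORI, 4)


class TestMannWhitneyU:
    def test_fully_separated_triples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_u_statistics_sum_to_nx_ny(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 10, rng.integers(2, 9)).tolist()
            y = rng.integers(0, 10, rng.integers(2, 9)).tolist()
            ux, _ = mann_whitney_u(x, y)
            uy, _ = mann_whitney_u(y, x)
            assert ux + uy == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("sides", ["two", "greater"])
    def test_matches_enumeration_oracle_with_ties(self, sides):
        rng = np.random.default_rng(1)
        for _ in range(15):
            x = rng.integers(0, 6, 5).tolist()
            y = rng.integers(0, 6, 6).tolist()
            u, p = mann_whitney_u(x, y, sides)
            u_ref, p_ref = mwu_exact_ref(x, y, sides)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_permutation_oracle_on_8_plus_8(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 8).round(2).tolist()
        y = rng.normal(0.8, 1, 8).round(2).tolist()
        _, p = mann_whitney_u(x, y)
        _, p_ref = mwu_exact_ref(x, y)
        assert p == pytest.approx(p_ref, abs=0.01)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(3)
        x = rng.permutation(100)[:7].tolist()
        y = rng.permutation(100)[50:61].tolist()
        u, p = mann_whitney_u(x, y)
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == res.statistic
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40).tolist()
        y = rng.normal(1, 1, 40).tolist()
        _, p = mann_whitney_u(x, y)
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])


class TestReplicateConsistency:
    def test_identical_trees(self):
        trees = [parse_newick(T12) for _ in range(5)]
        rc = replicate_consistency(trees)
        assert rc.all_identical and rc.n_distinct == 1 and rc.modal_count == 5

    def test_four_plus_one_nni(self):
        ref = "(((A,B),(C,D)),(E,F),(G,H));"
        nni = "(((A,C),(B,D)),(E,F),(G,H));"
        trees = [parse_newick(ref) for _ in range(4)] + [parse_newick(nni)]
        rc = replicate_consistency(trees)
        assert not rc.all_identical
        assert rc.n_distinct == 2
        assert rc.modal_count == 4
        assert bipartitions(rc.modal_tree) == bipartitions(parse_newick(ref))

    def test_distinct_count_matches_pairwise_equality_oracle(self):
        rng = np.random.default_rng(5)
        trees = [_random_tree(rng, 6) for _ in range(8)]
        rc = replicate_consistency(trees)
        splits = [frozenset(split_key(s) for s in bipartitions(t)) for t in trees]
        assert rc.n_distinct == len(set(splits))

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(LeafSetMismatchError):
            replicate_consistency([parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));")])
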