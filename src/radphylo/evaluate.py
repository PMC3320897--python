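"""Scoring of orthology estimation and phylogenetic accuracy.

Topological accuracy is bipartition-based: a node of an inferred tree is
correct when it induces a taxon bipartition present in the reference tree.
Orthology is scored against true locus labels carried by reads harvested
from a reference alignment.  Bootstrap support of correct versus incorrect
nodes is compared with Mann-Whitney U tests (the trees sharing nodes are not
independent, so pooled tests are descriptive).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, erfc, sqrt
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.stats import rankdata

from .assemble import ClusterAlignment, Supermatrix
from .cluster import Cluster
from .digest import Enzyme, LocusTruth, _locus_span
from .io_formats import GAP, ReferenceAlignment

SUPPORT_THRESHOLD = 70.0  # strict: "supported" means bootstrap > 70%


class LeafSetMismatchError(ValueError):
    """Two trees being compared do not share a leaf set."""


# A bipartition is a frozenset of the two frozensets of leaf labels.
Bipartition = frozenset


def _leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def _edge_split(node: dendropy.Node, tree: dendropy.Tree) -> Bipartition | None:
    """Bipartition induced by the edge above ``node``, or None if trivial."""
    all_leaves = _leaf_labels(tree)
    below = frozenset(l.taxon.label for l in node.leaf_iter())
    rest = all_leaves - below
    if len(below) < 2 or len(rest) < 2:
        return None
    return frozenset((below, rest))


def split_key(split: Bipartition, taxa: Sequence[str] | None = None) -> frozenset:
    """Canonical hashable key for a bipartition: the side not holding the
    lexicographically smallest leaf."""
    a, b = tuple(split)
    ref = min(min(a), min(b))
    return b if ref in a else a


def bipartitions(tree: dendropy.Tree) -> set:
    """Nontrivial bipartitions of the unrooted tree, one per internal edge."""
    leaves = _leaf_labels(tree)
    if len(leaves) < 4:
        raise ValueError("bipartitions require a tree over >= 4 leaves")
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        split = _edge_split(node, tree)
        if split is not None:
            out.add(split)
    return out


def _check_leafsets(t: dendropy.Tree, ref: dendropy.Tree) -> None:
    lt, lr = _leaf_labels(t), _leaf_labels(ref)
    if lt != lr:
        raise LeafSetMismatchError(
            f"leaf sets differ: only-in-first={sorted(lt - lr)}, only-in-second={sorted(lr - lt)}"
        )


def count_correct_nodes(t: dendropy.Tree, ref: dendropy.Tree) -> int:
    """Number of internal nodes of ``t`` whose bipartition occurs in ``ref``."""
    _check_leafsets(t, ref)
    return len(bipartitions(t) & bipartitions(ref))


def classify_topology(
    t: dendropy.Tree,
    ref: dendropy.Tree,
    alternatives: Sequence[dendropy.Tree] = (),
) -> str:
    """Classify an unrooted topology as reference / alternative / other.

    Exact topology equality (bipartition-set equality) is tested against the
    reference first, then each alternative in order.
    """
    _check_leafsets(t, ref)
    t_splits = bipartitions(t)
    if t_splits == bipartitions(ref):
        return "reference"
    for alt in alternatives:
        _check_leafsets(t, alt)
        if t_splits == bipartitions(alt):
            return "alternative"
    return "other"


class UnlabeledReadError(ValueError):
    """A read lacks the truth label needed for orthology scoring."""


def orthology_fraction(
    clusters: Sequence[Cluster],
    truth: Mapping[str, LocusTruth] | None = None,
) -> tuple[float, dict[str, bool]]:
    """Fraction of clusters consisting entirely of orthologous reads.

    A cluster is fully orthologous when all members carry the same true
    (site column, side) label.  Labels come from the reads themselves or the
    ``truth`` mapping (read_id -> label).  Returns the fraction and the
    per-cluster labels.
    """
    if not clusters:
        raise ValueError("no clusters to score")
    labels: dict[str, bool] = {}
    n_orth = 0
    for c in clusters:
        keys = set()
        for r in c.members:
            lt = r.truth if r.truth is not None else (truth or {}).get(r.read_id)
            if lt is None:
                raise UnlabeledReadError(f"read {r.read_id!r} has no truth label")
            keys.add(lt.locus_key)
        ok = len(keys) == 1
        labels[c.cluster_id] = ok
        n_orth += ok
    return n_orth / len(clusters), labels


class LabelGapError(KeyError):
    """A supermatrix partition has no orthology label."""


def split_by_orthology(
    m: Supermatrix, labels: Mapping[str, bool]
) -> tuple[Supermatrix, Supermatrix]:
    """Partition-wise split into orthologous-only and non-orthologous matrices.

    Every cell of ``m`` lands in exactly one of the two outputs; widths sum
    to the original width.  Either output may be empty (zero partitions), in
    which case it is returned as a zero-width matrix.
    """
    missing = [lid for lid, _, _ in m.partitions if lid not in labels]
    if missing:
        raise LabelGapError(f"partitions without orthology labels: {missing[:5]}")

    def _take(want: bool) -> Supermatrix:
        chunks = {t: [] for t in m.taxa}
        partitions = []
        pos = 0
        for lid, start, end in m.partitions:
            if labels[lid] != want:
                continue
            for t in m.taxa:
                chunks[t].append(m.rows[t][start:end])
            partitions.append((lid, pos, pos + (end - start)))
            pos += end - start
        if not partitions:
            return Supermatrix(taxa=list(m.taxa), rows={t: "" for t in m.taxa}, partitions=[])
        return Supermatrix(
            taxa=list(m.taxa),
            rows={t: "".join(chunks[t]) for t in m.taxa},
            partitions=partitions,
        )

    return _take(True), _take(False)


class NotOrthologousError(ValueError):
    """Alignment agreement is only defined for fully orthologous clusters."""


def alignment_agreement(
    ca: ClusterAlignment,
    alignment: ReferenceAlignment,
    enzyme: Enzyme,
    read_length: int,
) -> bool:
    """Does a cluster's alignment match the reference genome alignment?

    The reference subalignment for the cluster's (single) true locus is
    projected to the cluster's taxa, all-gap columns are removed, and the
    rows are compared as strings to the cluster alignment.
    """
    if ca.truth_keys is None or len(ca.truth_keys) != 1:
        raise NotOrthologousError(
            f"cluster {ca.locus_id!r} is not fully orthologous (keys={ca.truth_keys})"
        )
    site_column, side = next(iter(ca.truth_keys))
    taxa = [t for t in alignment.taxa if t in ca.rows]
    anchor = taxa[0]
    span = _locus_span(
        alignment.rows[anchor], site_column, side, len(enzyme.motif), read_length
    )
    if span is None:
        return False
    lo, hi = span
    sub = [list(alignment.rows[t][lo:hi]) for t in taxa]
    cols = [
        c for c in range(hi - lo) if any(row[c] != GAP for row in sub)
    ]
    ref_rows = {t: "".join(sub[i][c] for c in cols) for i, t in enumerate(taxa)}
    # drop all-gap columns of the cluster alignment symmetrically
    ca_cols = [
        c
        for c in range(ca.width)
        if any(ca.rows[t][c] != GAP for t in taxa)
    ]
    ca_rows = {t: "".join(ca.rows[t][c] for c in ca_cols) for t in taxa}
    return ref_rows == ca_rows


def agreement_fraction(
    cluster_alignments: Iterable[ClusterAlignment],
    alignment: ReferenceAlignment,
    enzyme: Enzyme,
    read_length: int,
) -> float | None:
    """Mean alignment agreement over the fully orthologous clusters.

    Returns None when no cluster is fully orthologous.
    """
    flags = [
        alignment_agreement(ca, alignment, enzyme, read_length)
        for ca in cluster_alignments
        if ca.truth_keys is not None and len(ca.truth_keys) == 1
    ]
    return float(np.mean(flags)) if flags else None


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_rank_sum_tail(ranks2: np.ndarray, nx: int, r2_obs: int) -> tuple[float, float]:
    """P(R_x <= obs) and P(R_x >= obs) over all C(n, nx) labelings.

    ``ranks2`` are doubled midranks (integers), ``r2_obs`` the doubled
    observed x rank sum.  Counting is by dynamic programming over items,
    which enumerates the permutation distribution exactly, ties included.
    """
    total2 = int(ranks2.sum())
    # dp[k][s] = number of k-subsets with doubled rank sum s
    dp = np.zeros((nx + 1, total2 + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(nx, 0, -1):  # descending: 0/1 item, no reuse
            dp[k, r:] += dp[k - 1, : total2 + 1 - r]
    dist = dp[nx]
    total = comb(len(ranks2), nx)
    le = dist[: r2_obs + 1].sum() / total
    ge = dist[r2_obs:].sum() / total
    return float(le), float(ge)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], sides: str = "two"
) -> tuple[float, float]:
    """Mann-Whitney U with midranks for ties.

    Returns ``(U_x, p)``.  The p-value is exact (full permutation
    distribution, computed by DP over the tied rank multiset) when
    ``n_x * n_y <= 400``, otherwise a tie-corrected normal approximation
    with continuity correction.  ``sides='greater'`` tests x tending larger.
    """
    if sides not in ("two", "greater"):
        raise ValueError(f"sides must be 'two' or 'greater', got {sides!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = ranks[:nx].sum()
    ux = rx - nx * (nx + 1) / 2.0

    if nx * ny <= 400:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        r2_obs = int(round(2 * rx))
        le, ge = _exact_rank_sum_tail(ranks2, nx, r2_obs)
        if sides == "greater":
            p = ge
        else:
            p = min(1.0, 2.0 * min(le, ge))
        return float(ux), float(p)

    n = nx + ny
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(ux), 1.0
    sd = sqrt(var)
    if sides == "greater":
        z = (ux - mu - 0.5) / sd
        p = 0.5 * erfc(z / sqrt(2))
    else:
        z = (abs(ux - mu) - 0.5) / sd
        z = max(z, 0.0)
        p = min(1.0, erfc(z / sqrt(2)))
    return float(ux), float(p)


# ---------------------------------------------------------------------------
# Replicate consistency
# ---------------------------------------------------------------------------

@dataclass
class ReplicateConsistency:
    all_identical: bool
    n_distinct: int
    modal_tree: dendropy.Tree
    modal_count: int
    n_trees: int


def replicate_consistency(trees: Sequence[dendropy.Tree]) -> ReplicateConsistency:
    """Compare per-replicate topologies by bipartition-set equality."""
    trees = list(trees)
    if not trees:
        raise ValueError("at least one tree required")
    base_leaves = _leaf_labels(trees[0])
    groups: list[tuple[set, list[int]]] = []
    for i, t in enumerate(trees):
        if _leaf_labels(t) != base_leaves:
            raise LeafSetMismatchError("replicate trees have differing leaf sets")
        splits = bipartitions(t)
        for g_splits, idxs in groups:
            if g_splits == splits:
                idxs.append(i)
                break
        else:
            groups.append((splits, [i]))
    modal_splits, modal_idxs = max(groups, key=lambda g: (len(g[1]), -g[1][0]))
    return ReplicateConsistency(
        all_identical=len(groups) == 1,
        n_distinct=len(groups),
        modal_tree=trees[modal_idxs[0]],
        modal_count=len(modal_idxs),
        n_trees=len(trees),
    )


@dataclass
class EvalReport:
    """Per-run accuracy metrics (one inferred tree vs the reference)."""

    correct_nodes: int
    total_nodes: int
    supported_correct: int
    supported_incorrect: int
    topology_class: str
    orthologous_fraction: float | None = None
    alignment_agreement: float | None = None
    u_statistic: float | None = None
    p_value: float | None = None


def evaluate_tree(
    supported,
    ref: dendropy.Tree,
    alternatives: Sequence[dendropy.Tree] = (),
    support_threshold: float = SUPPORT_THRESHOLD,
) -> EvalReport:
    """Score one supported tree against the reference (and alternatives).

    Counts correct nodes, correct/incorrect nodes with support strictly
    above the threshold, and classifies the topology.
    """
    tree = supported.tree
    ref_splits = bipartitions(ref)
    ref_keys = {split_key(s) for s in ref_splits}
    t_splits = bipartitions(tree)
    correct = 0
    sup_correct = 0
    sup_incorrect = 0
    for s in t_splits:
        k = split_key(s)
        is_correct = k in ref_keys
        correct += is_correct
        sup = supported.supports.get(k, 0.0)
        if sup > support_threshold:
            if is_correct:
                sup_correct += 1
            else:
                sup_incorrect += 1
    n_leaves = len(_leaf_labels(ref))
    return EvalReport(
        correct_nodes=correct,
        total_nodes=n_leaves - 3,
        supported_correct=sup_correct,
        supported_incorrect=sup_incorrect,
        topology_class=classify_topology(tree, ref, alternatives),
    )
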