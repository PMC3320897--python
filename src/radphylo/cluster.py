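"""Greedy seed-based identity clustering of RAD reads.

This mirrors the heuristic, input-order-dependent behaviour of seed-based
clusterers (UCLUST-style): reads are processed in input order, each is
compared against existing seeds in seed-creation order, and joins the first
seed whose pairwise identity reaches the threshold; otherwise it founds a new
cluster.  Because results depend on input order, the module also provides
seeded input-order permutations for replicate runs and the replicate
variation statistic (proportional difference of cluster counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _align
from .digest import RadRead


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the score-optimal global alignment of ``a`` and ``b``.

    Scoring: match +1, mismatch -1, gap -2, no free end gaps; ties prefer a
    match/mismatch column over a gap in ``a`` over a gap in ``b``.  Identity
    is identical-residue columns over total alignment columns; N matches
    nothing.  Because the tie preference distinguishes the arguments, rare
    score-tied pairs can give slightly different identities under argument
    swap; clustering always passes the incoming read as ``a`` and the seed
    as ``b``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _align.identity(a, b)


@dataclass
class Cluster:
    """One greedy cluster: the seed read followed by its members."""

    cluster_id: str
    seed_read_id: str
    members: list[RadRead]

    @property
    def taxa(self) -> set[str]:
        return {r.taxon for r in self.members}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class ClusterSet:
    """Greedy clustering output with the parameters that produced it."""

    clusters: list[Cluster]
    threshold: float
    order_seed: int | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_reads(self) -> int:
        return sum(len(c.members) for c in self.clusters)


def greedy_cluster(
    reads: Sequence[RadRead],
    threshold: float,
    order_seed: int | None = None,
) -> ClusterSet:
    """Cluster reads greedily at identity ``threshold`` in their given order.

    Deterministic given the input order; ``order_seed`` is recorded metadata
    only (the permutation applied upstream, if any).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    reads = list(reads)
    if not reads:
        return ClusterSet(clusters=[], threshold=threshold, order_seed=order_seed)
    lengths = {len(r.sequence) for r in reads}
    if len(lengths) == 1:
        # identical reads always follow their first occurrence's decision
        # (they scan the same seeds in the same order and tie at identity 1),
        # so clustering the unique sequences is exactly equivalent
        uniq_of: dict[str, int] = {}
        uniq_seqs: list[str] = []
        read_uniq = np.empty(len(reads), dtype=np.int64)
        for i, r in enumerate(reads):
            u = uniq_of.get(r.sequence)
            if u is None:
                u = len(uniq_seqs)
                uniq_of[r.sequence] = u
                uniq_seqs.append(r.sequence)
            read_uniq[i] = u
        codes = _align.encode_matrix(uniq_seqs)
        u_assign, u_seed_idx = _align.greedy_assign(codes, float(threshold))
        u_assign = np.asarray(u_assign)
        assign = u_assign[read_uniq]
        # seed read = first input read whose sequence founded the cluster
        first_read_of_uniq = np.full(len(uniq_seqs), -1, dtype=np.int64)
        for i in range(len(reads) - 1, -1, -1):
            first_read_of_uniq[read_uniq[i]] = i
        seed_idx = first_read_of_uniq[np.asarray(u_seed_idx)]
    else:  # mixed lengths: plain python loop over full-DP identities
        assign = np.empty(len(reads), dtype=np.int64)
        seeds: list[int] = []
        enc = [_align.encode(r.sequence) for r in reads]
        for i in range(len(reads)):
            for s, j in enumerate(seeds):
                if _align.identity(enc[i], enc[j]) >= threshold:
                    assign[i] = s
                    break
            else:
                assign[i] = len(seeds)
                seeds.append(i)
        seed_idx = np.asarray(seeds, dtype=np.int64)

    clusters = []
    for s, j in enumerate(seed_idx):
        seed_read = reads[int(j)]
        members = [seed_read] + [
            reads[int(i)] for i in np.nonzero(assign == s)[0] if int(i) != int(j)
        ]
        clusters.append(
            Cluster(cluster_id=f"c{s}", seed_read_id=seed_read.read_id, members=members)
        )
    return ClusterSet(clusters=clusters, threshold=threshold, order_seed=order_seed)


def shuffle_replicates(
    reads: Sequence[RadRead], n_reps: int, master_seed: int
) -> list[list[RadRead]]:
    """``n_reps`` seeded uniform permutations of the read list.

    Replicate ``r`` is reproducible from ``(master_seed, r)`` alone.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reads = list(reads)
    out = []
    for r in range(n_reps):
        rng = np.random.default_rng([master_seed, r])
        perm = rng.permutation(len(reads))
        out.append([reads[i] for i in perm])
    return out


def proportional_difference(cluster_counts: Sequence[int]) -> float:
    """Replicate variation statistic: 1 - min/max of the cluster counts."""
    counts = list(cluster_counts)
    if not counts:
        raise ValueError("at least one count required")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    m = max(counts)
    if m == 0:
        raise ValueError("max count is zero")
    return 1.0 - min(counts) / m
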