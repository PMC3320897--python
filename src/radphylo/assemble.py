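"""Cluster filtering, per-cluster alignment, and supermatrix assembly.

Clusters that contain more than one read from a single taxon are discarded
(paralog filter: duplicated or repetitive loci), then clusters below the
minimum taxon count ("min. taxa") are discarded.  Survivors are aligned with
a seed-anchored progressive (star) aligner and concatenated into a total
evidence supermatrix, with '?' filling the partitions of absent taxa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _align
from .cluster import Cluster
from .io_formats import GAP, MISSING

logger = logging.getLogger(__name__)

_VALID_CODES = frozenset(b"ACGT")


@dataclass
class ClusterAlignment:
    """Gapped alignment of one cluster's reads, one row per taxon."""

    locus_id: str
    rows: dict[str, str]
    truth_keys: frozenset | None = None  # distinct (site_column, side) labels, if known

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> set[str]:
        return set(self.rows)


@dataclass
class Supermatrix:
    """Concatenated locus alignments over a fixed taxon set.

    ``partitions`` holds (locus_id, start, end) with 0-based half-open column
    ranges tiling the full width.  '?' marks a taxon absent from a locus,
    '-' an alignment gap within a locus.
    """

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        widths = {len(self.rows[t]) for t in self.taxa}
        if len(widths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(widths)}")
        pos = 0
        for _, start, end in self.partitions:
            if start != pos or end <= start:
                raise ValueError("partitions must tile the matrix width")
            pos = end
        if pos != self.width:
            raise ValueError("partitions do not cover the matrix width")

    @property
    def width(self) -> int:
        return len(self.rows[self.taxa[0]])

    @property
    def incomplete(self) -> bool:
        """True when at least one taxon has no data at any locus."""
        return any(set(self.rows[t]) <= {MISSING} for t in self.taxa)

    def codes(self) -> np.ndarray:
        """(n_taxa, width) uint8 view of the matrix characters."""
        return np.vstack(
            [np.frombuffer(self.rows[t].encode("ascii"), dtype=np.uint8) for t in self.taxa]
        )


@dataclass
class MatrixStats:
    """Summary statistics of a supermatrix (and the clusters behind it)."""

    total_length: int
    missing_fraction: float  # '?', '-' and N cells over all cells
    absent_fraction: float  # '?' cells only (locus absent in taxon)
    variable_sites: int
    parsimony_informative_sites: int
    invariant_cluster_fraction: float
    per_taxon_missing: dict[str, float]
    per_taxon_pi_sites: dict[str, int]
    incomplete: bool


def filter_paralogs(clusters: Iterable[Cluster]) -> list[Cluster]:
    """Drop clusters containing more than one read from any single taxon."""
    kept = []
    for c in clusters:
        taxa = [r.taxon for r in c.members]
        if len(taxa) == len(set(taxa)):
            kept.append(c)
    return kept


def filter_min_taxa(clusters: Iterable[Cluster], min_taxa: int) -> list[Cluster]:
    """Drop clusters with fewer distinct taxa than ``min_taxa``.

    Values below 4 are allowed but warned about: four taxa is the minimum for
    an informative unrooted tree.
    """
    if min_taxa < 4:
        warnings.warn(
            f"min_taxa={min_taxa} is below 4, the minimum for an informative "
            "unrooted phylogenetic tree",
            stacklevel=2,
        )
    return [c for c in clusters if c.n_taxa >= min_taxa]


def align_cluster(cluster: Cluster) -> ClusterAlignment:
    """Seed-anchored progressive alignment of one (paralog-free) cluster.

    Every member is pairwise-aligned to the seed; the pairwise alignments are
    merged on the seed's coordinate frame, inserting gap columns as the union
    of member insertions.  Equal-length gap-free inputs with no indels yield
    a gapless alignment identical to the inputs.
    """
    members = cluster.members
    taxa = [r.taxon for r in members]
    if len(taxa) != len(set(taxa)):
        raise ValueError(f"cluster {cluster.cluster_id} has duplicate taxa (unfiltered?)")
    seed = members[0].sequence
    n = len(seed)
    if all(r.sequence == seed for r in members):  # common fast path
        rows = {r.taxon: r.sequence for r in members}
        return ClusterAlignment(cluster.cluster_id, rows, _truth_keys(cluster))

    # Pairwise-align each member to the seed and record, per seed position,
    # the member character (or gap) plus any insertion immediately before it.
    # slot k in [0, n] = insertion point before seed position k.
    per_member: list[tuple[list[str], dict[int, str]]] = []
    ins_len = [0] * (n + 1)
    for r in members[1:]:
        a_seed, a_mem = _align.align_pair(seed, r.sequence)
        chars = []  # member char aligned to each seed position
        inserts: dict[int, str] = {}
        k = 0  # next seed position
        pending = []
        for cs, cm in zip(a_seed, a_mem):
            if cs == GAP:
                pending.append(cm)
            else:
                if pending:
                    inserts[k] = "".join(pending)
                    pending = []
                chars.append(cm)
                k += 1
        if pending:
            inserts[k] = "".join(pending)
        for pos, s in inserts.items():
            ins_len[pos] = max(ins_len[pos], len(s))
        per_member.append((chars, inserts))

    def build_row(chars: Sequence[str], inserts: dict[int, str]) -> str:
        out = []
        for k in range(n + 1):
            if ins_len[k]:
                s = inserts.get(k, "")
                out.append(s.rjust(ins_len[k], GAP))
            if k < n:
                out.append(chars[k])
        return "".join(out)

    rows = {members[0].taxon: build_row(list(seed), {})}
    for r, (chars, inserts) in zip(members[1:], per_member):
        rows[r.taxon] = build_row(chars, inserts)
    return ClusterAlignment(cluster.cluster_id, rows, _truth_keys(cluster))


def _truth_keys(cluster: Cluster) -> frozenset | None:
    keys = {r.truth.locus_key for r in cluster.members if r.truth is not None}
    return frozenset(keys) if keys else None


class EmptyAlignmentListError(ValueError):
    """concatenate() was given no cluster alignments."""


def concatenate(
    alignments: Sequence[ClusterAlignment], taxa: Sequence[str]
) -> Supermatrix:
    """Concatenate locus alignments into a supermatrix over ``taxa``.

    Loci are ordered by descending taxon count then locus id (a fixed,
    reproducible order); taxa absent from a locus get '?' across that
    partition.  The result's ``incomplete`` property is true when a taxon is
    '?' across the whole matrix — such matrices are excluded from tree
    inference downstream.
    """
    alignments = list(alignments)
    if not alignments:
        raise EmptyAlignmentListError("no cluster alignments to concatenate")
    ids = [a.locus_id for a in alignments]
    if len(ids) != len(set(ids)):
        raise ValueError("locus ids must be unique")
    taxa = list(taxa)
    ordered = sorted(alignments, key=lambda a: (-len(a.rows), a.locus_id))
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for a in ordered:
        w = a.width
        for t in taxa:
            chunks[t].append(a.rows.get(t, MISSING * w))
        partitions.append((a.locus_id, pos, pos + w))
        pos += w
    m = Supermatrix(
        taxa=taxa,
        rows={t: "".join(chunks[t]) for t in taxa},
        partitions=partitions,
    )
    if m.incomplete:
        empty = [t for t in taxa if set(m.rows[t]) <= {MISSING}]
        logger.info("supermatrix is incomplete: no data for %s", ",".join(empty))
    return m


def matrix_stats(
    m: Supermatrix, clusters: Sequence[Cluster] | None = None
) -> MatrixStats:
    """Site and missing-data statistics of a supermatrix.

    A variable site has >= 2 distinct A/C/G/T states; a parsimony-informative
    site has >= 2 states each held by >= 2 taxa.  '?', '-' and N all count as
    missing.  The invariant-cluster fraction (clusters whose reads are all
    identical) is computed when ``clusters`` is given, else reported as 0.
    """
    codes = m.codes()
    n_taxa, width = codes.shape
    valid = (
        (codes == ord("A")) | (codes == ord("C")) | (codes == ord("G")) | (codes == ord("T"))
    )
    missing_fraction = 1.0 - valid.sum() / codes.size

    # per-column state counts over A,C,G,T
    counts = np.zeros((4, width), dtype=np.int32)
    for i, base in enumerate(b"ACGT"):
        counts[i] = (codes == base).sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    variable = n_states >= 2
    pi = ((counts >= 2).sum(axis=0) >= 2)

    absent = codes == ord(MISSING)
    per_taxon_missing = {
        t: float(1.0 - valid[i].sum() / width) for i, t in enumerate(m.taxa)
    }
    per_taxon_pi = {
        t: int((valid[i] & pi).sum()) for i, t in enumerate(m.taxa)
    }

    if clusters:
        inv = sum(
            1
            for c in clusters
            if len({r.sequence for r in c.members}) == 1
        )
        inv_fraction = inv / len(clusters)
    else:
        inv_fraction = 0.0

    return MatrixStats(
        total_length=width,
        missing_fraction=float(missing_fraction),
        absent_fraction=float(absent.sum() / codes.size),
        variable_sites=int(variable.sum()),
        parsimony_informative_sites=int(pi.sum()),
        invariant_cluster_fraction=float(inv_fraction),
        per_taxon_missing=per_taxon_missing,
        per_taxon_pi_sites=per_taxon_pi,
        incomplete=m.incomplete,
    )
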