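"""In-silico restriction digest: harvest fixed-length flanks around enzyme sites.

For every exact occurrence of the recognition motif, the read pair is the
``L`` bases immediately upstream and downstream of the site; the motif itself
is never part of a read.  Reads whose flank would run past a contig end are
dropped.  Harvesting from a reference whole-genome alignment additionally
labels each read with its true locus (the alignment column of the motif
start), which is what orthology scoring and the known-orthology benchmark
matrices are built from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .io_formats import GAP, MISSING, Genome, ReferenceAlignment

if TYPE_CHECKING:  # pragma: no cover
    from .assemble import Supermatrix


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: name plus exact recognition motif."""

    name: str
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("motif must be at least 4 bases")
        if set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be over ACGT, got {self.motif!r}")


SBFI = Enzyme("SbfI", "CCTGCAGG")
NOTI = Enzyme("NotI", "GCGGCCGC")
ECORI = Enzyme("EcoRI", "GAATTC")
ENZYMES = {e.name: e for e in (SBFI, NOTI, ECORI)}


def get_enzyme(spec: str) -> Enzyme:
    """Look up a named enzyme, or build one from ``custom:MOTIF``."""
    if spec in ENZYMES:
        return ENZYMES[spec]
    if spec.startswith("custom:"):
        motif = spec.split(":", 1)[1].upper()
        return Enzyme(f"custom_{motif}", motif)
    raise KeyError(f"unknown enzyme {spec!r} (use one of {sorted(ENZYMES)} or custom:MOTIF)")


@dataclass(frozen=True)
class LocusTruth:
    """True locus label: alignment column of the motif start, plus the side."""

    site_column: int
    side: str

    @property
    def locus_key(self) -> tuple[int, str]:
        return (self.site_column, self.side)


@dataclass(frozen=True)
class RadRead:
    """One simulated flank read with its source coordinates."""

    read_id: str
    taxon: str
    contig: str
    side: str  # 'upstream' | 'downstream'
    interval: tuple[int, int]  # 0-based half-open on the source sequence
    sequence: str
    truth: LocusTruth | None = None


def find_sites(seq: str, motif: str) -> list[int]:
    """All 0-based start positions of exact motif matches (overlaps included)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    positions = []
    start = 0
    while True:
        p = seq.find(motif, start)
        if p < 0:
            return positions
        positions.append(p)
        start = p + 1  # overlapping occurrences count


def _flanks(
    seq: str, p: int, motif_len: int, L: int
) -> list[tuple[str, int, int, str]]:
    """(side, start, end, sequence) for the flanks of a site, length-filtered."""
    out = []
    if p - L >= 0:
        out.append(("upstream", p - L, p, seq[p - L : p]))
    dstart = p + motif_len
    if dstart + L <= len(seq):
        out.append(("downstream", dstart, dstart + L, seq[dstart : dstart + L]))
    return out


def harvest_reads(
    genome: Genome,
    enzyme: Enzyme,
    read_length: int,
    drop_ambiguous: bool = False,
) -> list[RadRead]:
    """Harvest the upstream/downstream flanks of every enzyme site in a genome.

    Reads extending past a contig end are dropped; with ``drop_ambiguous``,
    reads containing N are dropped too.  Read ids are deterministic:
    ``taxon:contig:site_position:side``.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    m = len(enzyme.motif)
    reads = []
    for contig_id, seq in genome.contigs.items():
        for p in find_sites(seq, enzyme.motif):
            for side, start, end, flank in _flanks(seq, p, m, read_length):
                if drop_ambiguous and "N" in flank:
                    continue
                reads.append(
                    RadRead(
                        read_id=f"{genome.taxon}:{contig_id}:{p}:{side}",
                        taxon=genome.taxon,
                        contig=contig_id,
                        side=side,
                        interval=(start, end),
                        sequence=flank,
                    )
                )
    return reads


def harvest_from_alignment(
    alignment: ReferenceAlignment,
    enzyme: Enzyme,
    read_length: int,
    drop_ambiguous: bool = False,
) -> list[RadRead]:
    """Harvest flank reads from each row of a reference alignment, with truth.

    Sites are located on each taxon's ungapped sequence; every read carries a
    :class:`LocusTruth` whose ``site_column`` is the alignment column of the
    motif's first base in that taxon's row, so reads from the same ancestral
    site share a label even when gap patterns differ between rows.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    m = len(enzyme.motif)
    reads = []
    for taxon in alignment.taxa:
        row = alignment.rows[taxon]
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        col_of = np.nonzero(arr != ord(GAP))[0]  # ungapped index -> column
        seq = row.replace(GAP, "")
        for p in find_sites(seq, enzyme.motif):
            truth_col = int(col_of[p])
            for side, start, end, flank in _flanks(seq, p, m, read_length):
                if drop_ambiguous and "N" in flank:
                    continue
                reads.append(
                    RadRead(
                        read_id=f"{taxon}:aln:{p}:{side}",
                        taxon=taxon,
                        contig="aln",
                        side=side,
                        interval=(start, end),
                        sequence=flank,
                        truth=LocusTruth(site_column=truth_col, side=side),
                    )
                )
    return reads


class EmptyMatrixError(ValueError):
    """No loci survived benchmark-matrix construction."""


def _locus_span(
    row: str, site_column: int, side: str, motif_len: int, read_length: int
) -> tuple[int, int] | None:
    """Column span of a flank locus, walking outward along ``row``.

    The span accumulates ``read_length`` ungapped characters of ``row``
    starting adjacent to the motif (whose first base sits at alignment column
    ``site_column``).  Returns a half-open column interval, or None if the
    row runs out of columns first.
    """
    n = len(row)
    if side == "upstream":
        need = read_length
        c = site_column - 1
        while c >= 0 and need > 0:
            if row[c] != GAP:
                need -= 1
            c -= 1
        if need > 0:
            return None
        return (c + 1, site_column)
    # downstream: first skip the motif's ungapped characters
    c = site_column
    consumed = 0
    while c < n and consumed < motif_len:
        if row[c] != GAP:
            consumed += 1
        c += 1
    if consumed < motif_len:
        return None
    start = c
    need = read_length
    while c < n and need > 0:
        if row[c] != GAP:
            need -= 1
        c += 1
    if need > 0:
        return None
    return (start, c)


def build_benchmark_matrix(
    alignment: ReferenceAlignment,
    enzyme: Enzyme,
    read_length: int,
    min_taxa: int = 4,
) -> "Supermatrix":
    """Known-orthology supermatrix straight from the reference alignment.

    Loci are groups of harvested reads sharing (site column, side).  Each
    locus's subalignment is the span of reference columns that accumulates
    ``read_length`` ungapped characters of the locus's first present taxon
    (in alignment taxon order), walking outward from the site.  Taxa missing
    the site are '?'-filled; loci with fewer than ``min_taxa`` present taxa
    are dropped; survivors are concatenated in site-column order (upstream
    flank before downstream at the same site).
    """
    from .assemble import Supermatrix

    if min_taxa < 4:
        raise ValueError("min_taxa must be >= 4 for an informative unrooted tree")
    reads = harvest_from_alignment(alignment, enzyme, read_length)
    loci: dict[tuple[int, str], list[RadRead]] = {}
    for r in reads:
        loci.setdefault(r.truth.locus_key, []).append(r)

    side_rank = {"upstream": 0, "downstream": 1}
    order = sorted(loci, key=lambda k: (k[0], side_rank[k[1]]))
    pieces: list[tuple[str, dict[str, str], int]] = []
    for key in order:
        members = loci[key]
        present = {r.taxon for r in members}
        if len(present) < min_taxa:
            continue
        anchor = next(t for t in alignment.taxa if t in present)
        span = _locus_span(
            alignment.rows[anchor], key[0], key[1], len(enzyme.motif), read_length
        )
        if span is None:  # anchor's own read exists, so this cannot happen
            continue
        lo, hi = span
        width = hi - lo
        rows = {
            t: (alignment.rows[t][lo:hi] if t in present else MISSING * width)
            for t in alignment.taxa
        }
        side_tag = "u" if key[1] == "upstream" else "d"
        pieces.append((f"s{key[0]}{side_tag}", rows, width))

    if not pieces:
        raise EmptyMatrixError(
            f"no loci with >= {min_taxa} taxa for {enzyme.name} at L={read_length}"
        )
    rows_out = {t: [] for t in alignment.taxa}
    partitions = []
    pos = 0
    for locus_id, rows, width in pieces:
        for t in alignment.taxa:
            rows_out[t].append(rows[t])
        partitions.append((locus_id, pos, pos + width))
        pos += width
    return Supermatrix(
        taxa=list(alignment.taxa),
        rows={t: "".join(rows_out[t]) for t in alignment.taxa},
        partitions=partitions,
    )
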