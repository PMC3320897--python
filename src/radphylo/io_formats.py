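"""Readers and writers for the formats the pipeline touches.

Genomes and reference whole-genome alignments are FASTA; trees are Newick
(dendropy containers throughout); supermatrices are written as relaxed PHYLIP
or FASTA plus a RAxML-style partition file; clusters travel as TSV.

Conventions used everywhere in this package:

* coordinates are 0-based, half-open, on the forward strand;
* ``?`` means "locus absent in this taxon" (missing data), ``-`` is an
  alignment gap within a locus; both are ignored by distance and site
  counting downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import dendropy
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .assemble import Supermatrix

logger = logging.getLogger(__name__)

GENOME_ALPHABET = set("ACGTN")
ALIGNMENT_ALPHABET = set("ACGTN-")
MATRIX_ALPHABET = set("ACGTN-?")

MISSING = "?"
GAP = "-"


class FastaError(ValueError):
    """Base class for FASTA reading problems."""


class EmptyFastaError(FastaError):
    """The file contained no records."""


class DuplicateHeaderError(FastaError):
    """Two records share an identifier."""


class GapInGenomeError(FastaError):
    """A gap character appeared in a sequence read in genome mode."""


class UnequalAlignmentRowsError(FastaError):
    """Alignment rows have differing lengths."""


class NewickParseError(ValueError):
    """Malformed Newick, or duplicate leaf labels."""


@dataclass
class Genome:
    """One taxon's assembly: ordered contigs of A/C/G/T/N."""

    taxon: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("taxon label must be non-empty")
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} is empty")

    @property
    def size(self) -> int:
        """Total bases across contigs."""
        return sum(len(s) for s in self.contigs.values())


@dataclass
class ReferenceAlignment:
    """A multiple whole-genome alignment: equal-length gapped rows, one per taxon."""

    taxa: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) != 1:
            raise UnequalAlignmentRowsError(
                f"alignment rows have unequal lengths: {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.taxa[0]])

    def ungapped(self, taxon: str) -> str:
        return self.rows[taxon].replace(GAP, "")


_CLEAN_RE = re.compile(r"[^ACGTN\-]")


def _normalize(seq: str, *, allow_gaps: bool, name: str) -> str:
    s = seq.upper().replace("U", "T")
    if GAP in s and not allow_gaps:
        raise GapInGenomeError(f"gap character in {name!r} while reading as genome")
    bad = _CLEAN_RE.findall(s)
    if bad:
        logger.warning(
            "record %r: replaced %d non-nucleotide character(s) (%s) with N",
            name, len(bad), ",".join(sorted(set(bad))),
        )
        s = _CLEAN_RE.sub("N", s)
    return s


def read_fasta(path: str | Path, kind: str = "genome", taxon: str | None = None):
    """Read a FASTA file as a :class:`Genome` or a :class:`ReferenceAlignment`.

    Sequences are uppercased, U mapped to T, and anything outside the
    nucleotide alphabet replaced by N with a logged warning.  In genome mode
    the taxon label defaults to the file stem.
    """
    path = Path(path)
    if kind not in ("genome", "alignment"):
        raise ValueError(f"kind must be 'genome' or 'alignment', got {kind!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateHeaderError(f"duplicate FASTA header {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    if kind == "genome":
        contigs = {
            rid: _normalize(seq, allow_gaps=False, name=rid) for rid, seq in records
        }
        return Genome(taxon=taxon or path.stem, contigs=contigs)
    rows = {rid: _normalize(seq, allow_gaps=True, name=rid) for rid, seq in records}
    return ReferenceAlignment(taxa=[rid for rid, _ in records], rows=rows)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)
# ---------------------------------------------------------------------------

PhyloTree = dendropy.Tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into an (unrooted) dendropy tree.

    Rooted inputs are accepted but deprooted: all downstream topology
    comparisons are over unrooted trees.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf names: {dupes}")
    tree.is_rooted = False
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (10 significant digits on branch lengths)."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def n_internal_edges(tree: dendropy.Tree) -> int:
    """Number of internal (nontrivial) edges of the unrooted tree."""
    from .evaluate import bipartitions  # local import to avoid a cycle

    return len(bipartitions(tree))


# ---------------------------------------------------------------------------
# Supermatrix output
# ---------------------------------------------------------------------------

def write_supermatrix(
    m: "Supermatrix",
    prefix: str | Path,
    format: str = "relaxed-phylip",
) -> tuple[Path, Path]:
    """Write a supermatrix plus its RAxML-style partition file.

    ``prefix`` is extended with ``.phy`` or ``.fasta`` and ``.partitions``.
    Partition lines are 1-based inclusive, ``DNA, <locus> = <start>-<end>``.
    Returns (matrix path, partition path).
    """
    prefix = Path(prefix)
    if format == "relaxed-phylip":
        mat_path = prefix.with_suffix(".phy")
        with open(mat_path, "w") as fh:
            fh.write(f"{len(m.taxa)} {m.width}\n")
            for t in m.taxa:
                fh.write(f"{t}  {m.rows[t]}\n")
    elif format == "fasta":
        mat_path = prefix.with_suffix(".fasta")
        write_fasta(((t, m.rows[t]) for t in m.taxa), mat_path)
    else:
        raise ValueError(f"unknown supermatrix format {format!r}")
    part_path = prefix.with_suffix(".partitions")
    with open(part_path, "w") as fh:
        for locus_id, start, end in m.partitions:
            fh.write(f"DNA, {locus_id} = {start + 1}-{end}\n")
    return mat_path, part_path


def read_supermatrix(matrix_path: str | Path, partitions_path: str | Path | None = None):
    """Read back a supermatrix written by :func:`write_supermatrix`.

    Accepts both formats (sniffed from the first character).  Returns a
    :class:`~radphylo.assemble.Supermatrix`; with no partition file the whole
    width becomes a single partition named ``all``.
    """
    from .assemble import Supermatrix

    matrix_path = Path(matrix_path)
    text = matrix_path.read_text()
    taxa: list[str] = []
    rows: dict[str, str] = {}
    if text.lstrip().startswith(">"):
        cur = None
        chunks: dict[str, list[str]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                cur = line[1:].split()[0]
                if cur in chunks:
                    raise DuplicateHeaderError(f"duplicate header {cur!r}")
                taxa.append(cur)
                chunks[cur] = []
            else:
                chunks[cur].append(line)
        rows = {t: "".join(chunks[t]).upper() for t in taxa}
    else:
        lines = [l for l in text.splitlines() if l.strip()]
        for line in lines[1:]:
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows[name] = seq.strip().upper()
    widths = {len(s) for s in rows.values()}
    if len(widths) != 1:
        raise UnequalAlignmentRowsError(f"matrix rows have unequal lengths: {sorted(widths)}")
    width = widths.pop()
    bad = set("".join(rows.values())) - MATRIX_ALPHABET
    if bad:
        raise FastaError(f"invalid matrix characters: {sorted(bad)}")
    if partitions_path is not None:
        partitions = []
        for line in Path(partitions_path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            # "DNA, name = start-end" with 1-based inclusive bounds
            _, rest = line.split(",", 1)
            name, rng = rest.split("=")
            start, end = rng.strip().split("-")
            partitions.append((name.strip(), int(start) - 1, int(end)))
    else:
        partitions = [("all", 0, width)]
    return Supermatrix(taxa=taxa, rows=rows, partitions=partitions)


# ---------------------------------------------------------------------------
# Cluster / truth tables as TSV
# ---------------------------------------------------------------------------

def write_clusters_tsv(cluster_set, path: str | Path) -> None:
    """Write clusters as TSV: cluster_id, seed_flag, taxon, read_id, sequence."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tseed_flag\ttaxon\tread_id\tsequence\n")
        for cl in cluster_set.clusters:
            for i, read in enumerate(cl.members):
                fh.write(
                    f"{cl.cluster_id}\t{int(i == 0)}\t{read.taxon}\t{read.read_id}\t{read.sequence}\n"
                )


def read_clusters_tsv(path: str | Path, threshold: float | None = None):
    """Read a cluster TSV back into a ClusterSet (reads carry taxon+sequence)."""
    from .cluster import Cluster, ClusterSet
    from .digest import RadRead

    by_cluster: dict[str, list] = {}
    seeds: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cid = parts[idx["cluster_id"]]
            read = RadRead(
                read_id=parts[idx["read_id"]],
                taxon=parts[idx["taxon"]],
                contig="",
                side="",
                interval=(0, 0),
                sequence=parts[idx["sequence"]],
            )
            if parts[idx["seed_flag"]] == "1":
                seeds[cid] = read.read_id
                by_cluster.setdefault(cid, []).insert(0, read)
            else:
                by_cluster.setdefault(cid, []).append(read)
    clusters = [
        Cluster(cluster_id=cid, seed_read_id=seeds.get(cid, members[0].read_id), members=members)
        for cid, members in by_cluster.items()
    ]
    return ClusterSet(clusters=clusters, threshold=threshold if threshold is not None else 0.0)


def write_reads_fasta(reads, fasta_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write harvested reads as FASTA (headers = read ids) plus metadata TSV."""
    write_fasta(((r.read_id, r.sequence) for r in reads), fasta_path)
    if sidecar_path is not None:
        write_truth_tsv(reads, sidecar_path)


def read_reads(fasta_path: str | Path, sidecar_path: str | Path | None = None):
    """Read back a reads FASTA (+ optional metadata sidecar) as RadRead objects."""
    from .digest import LocusTruth, RadRead

    meta: dict[str, dict] = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                p = line.rstrip("\n").split("\t")
                meta[p[idx["read_id"]]] = {
                    "taxon": p[idx["taxon"]],
                    "contig": p[idx["contig"]],
                    "interval": (int(p[idx["start"]]), int(p[idx["end"]])),
                    "side": p[idx["side"]],
                    "site_column": p[idx["site_column"]],
                }
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        rid = rec.id
        if rid in meta:
            m = meta[rid]
            truth = (
                LocusTruth(site_column=int(m["site_column"]), side=m["side"])
                if m["site_column"] != ""
                else None
            )
            reads.append(
                RadRead(
                    read_id=rid,
                    taxon=m["taxon"],
                    contig=m["contig"],
                    side=m["side"],
                    interval=m["interval"],
                    sequence=str(rec.seq).upper(),
                    truth=truth,
                )
            )
        else:
            taxon = rid.split(":", 1)[0]
            reads.append(
                RadRead(
                    read_id=rid,
                    taxon=taxon,
                    contig="",
                    side="",
                    interval=(0, 0),
                    sequence=str(rec.seq).upper(),
                )
            )
    return reads


def write_truth_tsv(reads, path: str | Path) -> None:
    """Sidecar TSV for harvested reads (orthology truth where available)."""
    with open(path, "w") as fh:
        fh.write("read_id\ttaxon\tcontig\tstart\tend\tside\tsite_column\n")
        for r in reads:
            col = r.truth.site_column if r.truth is not None else ""
            fh.write(
                f"{r.read_id}\t{r.taxon}\t{r.contig}\t{r.interval[0]}\t{r.interval[1]}\t{r.side}\t{col}\n"
            )
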