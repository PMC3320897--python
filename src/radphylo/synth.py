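"""Synthetic genomes with known phylogeny, restriction loci, and truth tables.

The generator plants restriction-site motifs at evenly spaced positions in a
random root genome and evolves the sequence along a given tree under
Jukes-Cantor (per-branch substitution probability 3/4*(1 - e^(-4t/3)), t in
expected substitutions/site).  Because only deletions are modelled as indels,
every lineage stays in the root coordinate frame and the true multiple
alignment falls straight out of the simulation.  With motif protection on,
the planted motif columns are immune to change and every taxon retains every
locus; with protection off, restriction sites are lost along branches the way
they are in real genomes (losses favoured over gains), so phylogenetically
isolated taxa retain fewer loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .digest import SBFI, Enzyme
from .io_formats import (
    GAP,
    MISSING,
    Genome,
    ReferenceAlignment,
    parse_newick,
    write_fasta,
    write_newick,
)

_BASES = "ACGT"


class PackingError(ValueError):
    """The requested site count does not fit in the genome length."""


@dataclass
class SynthParams:
    """Simulation controls.

    ``tree``: Newick with branch lengths in expected substitutions/site.
    ``genome_length``: root genome size in bp.  ``n_sites``: planted motif
    copies, evenly spaced.  ``read_length`` reserves flank room at the edges.
    ``indel_rate``: expected deletion events per site per unit branch length
    (geometric lengths, mean 2); default 0.  ``motif_protection``: planted
    motif columns are immune to substitution and deletion.
    """

    tree: str
    genome_length: int
    n_sites: int
    enzyme: Enzyme = SBFI
    read_length: int = 100
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    indel_rate: float = 0.0
    motif_protection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass
class TruthTable:
    """Per-locus truth: flank sequences per taxon and side, or None if lost.

    Loci are keyed by (alignment column of the motif start, side); they
    cover every motif occurrence in any final genome, planted or arisen.
    """

    read_length: int
    motif: str
    planted_columns: list[int]
    flanks: dict[tuple[int, str], dict[str, str | None]]

    def present(self, site_column: int, side: str, taxon: str) -> bool:
        return self.flanks[(site_column, side)].get(taxon) is not None

    @property
    def locus_keys(self) -> list[tuple[int, str]]:
        side_rank = {"upstream": 0, "downstream": 1}
        return sorted(self.flanks, key=lambda k: (k[0], side_rank[k[1]]))


@dataclass
class SyntheticData:
    genomes: dict[str, Genome]
    alignment: ReferenceAlignment
    truth: TruthTable
    tree: dendropy.Tree
    params: SynthParams


def _evolve_branch(
    seq: np.ndarray,
    t: float,
    protected: np.ndarray,
    indel_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of Jukes-Cantor evolution (+ optional deletions) in place-copy."""
    child = seq.copy()
    if t > 0:
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        eligible = (child != 255) & ~protected
        hit = eligible & (rng.random(child.size) < p_sub)
        idx = np.nonzero(hit)[0]
        if idx.size:
            child[idx] = (child[idx] + 1 + rng.integers(0, 3, idx.size)) % 4
        if indel_rate > 0:
            n_events = rng.poisson(indel_rate * t * child.size)
            for _ in range(n_events):
                start = int(rng.integers(0, child.size))
                length = int(rng.geometric(0.5))
                span = slice(start, min(start + length, child.size))
                mask = ~protected[span]
                child[span][mask] = 255
    return child


def _scan_row_loci(
    row: str, motif: str, read_length: int
) -> dict[tuple[int, str], str]:
    """(site column, side) -> flank for every motif occurrence in a gapped row."""
    arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    col_of = np.nonzero(arr != ord(GAP))[0]
    seq = row.replace(GAP, "")
    m = len(motif)
    out: dict[tuple[int, str], str] = {}
    start = 0
    while True:
        p = seq.find(motif, start)
        if p < 0:
            break
        col = int(col_of[p])
        if p - read_length >= 0:
            out[(col, "upstream")] = seq[p - read_length : p]
        if p + m + read_length <= len(seq):
            out[(col, "downstream")] = seq[p + m : p + m + read_length]
        start = p + 1
    return out


def simulate_genomes(params: SynthParams) -> SyntheticData:
    """Simulate genomes, true alignment, truth table, and return the true tree.

    Deterministic from ``params.seed``.
    """
    tree = parse_newick(params.tree) if isinstance(params.tree, str) else params.tree
    rng = np.random.default_rng(params.seed)
    G = params.genome_length
    motif = params.enzyme.motif
    m = len(motif)
    L = params.read_length

    stride = G // params.n_sites
    offset = stride // 2
    positions = [offset + i * stride for i in range(params.n_sites)]
    if positions[0] - L < 0 or positions[-1] + m + L > G:
        raise PackingError(
            f"cannot fit {params.n_sites} sites with L={L} flanks in {G} bp"
        )

    root = rng.choice(4, size=G, p=list(params.base_composition)).astype(np.uint8)
    motif_codes = np.frombuffer(motif.encode(), dtype=np.uint8)
    motif_arr = np.array(["ACGT".index(c) for c in motif], dtype=np.uint8)
    protected = np.zeros(G, dtype=bool)
    for pos in positions:
        root[pos : pos + m] = motif_arr
        if params.motif_protection:
            protected[pos : pos + m] = True

    # evolve down the tree; node sequences live in the root coordinate frame
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root}
    leaf_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_seq = root
        else:
            t = node.edge.length or 0.0
            parent_seq = _evolve_branch(
                seqs[id(node.parent_node)], t, protected, params.indel_rate, rng
            )
            seqs[id(node)] = parent_seq
        if node.is_leaf():
            leaf_rows[node.taxon.label] = parent_seq

    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    rows = {}
    for t in taxa:
        arr = leaf_rows[t]
        chars = np.full(G, ord(GAP), dtype=np.uint8)
        live = arr != 255
        chars[live] = lut[arr[live]]
        rows[t] = chars.tobytes().decode("ascii")
    alignment = ReferenceAlignment(taxa=list(taxa), rows=rows)
    genomes = {
        t: Genome(taxon=t, contigs={"chr1": rows[t].replace(GAP, "")}) for t in taxa
    }

    # truth table: every motif occurrence in any final genome
    flanks: dict[tuple[int, str], dict[str, str | None]] = {}
    for t in taxa:
        for key, flank in _scan_row_loci(rows[t], motif, L).items():
            flanks.setdefault(key, {})[t] = flank
    for key in flanks:
        for t in taxa:
            flanks[key].setdefault(t, None)
    truth = TruthTable(
        read_length=L,
        motif=motif,
        planted_columns=positions,
        flanks=flanks,
    )
    return SyntheticData(
        genomes=genomes, alignment=alignment, truth=truth, tree=tree, params=params
    )


def truth_supermatrix(truth: TruthTable, taxa: list[str], min_taxa: int = 4):
    """Concatenate truth-table flanks into a known-orthology supermatrix.

    Intended for indel-free simulations, where each locus is exactly
    ``read_length`` columns wide; loci with fewer than ``min_taxa`` present
    taxa are dropped, ordering and naming match the benchmark-matrix builder
    so the two can be compared byte for byte.
    """
    from .assemble import Supermatrix

    L = truth.read_length
    chunks = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for col, side in truth.locus_keys:
        per_taxon = truth.flanks[(col, side)]
        present = [t for t in taxa if per_taxon.get(t) is not None]
        if len(present) < min_taxa:
            continue
        for t in taxa:
            flank = per_taxon.get(t)
            chunks[t].append(flank if flank is not None else MISSING * L)
        side_tag = "u" if side == "upstream" else "d"
        partitions.append((f"s{col}{side_tag}", pos, pos + L))
        pos += L
    if not partitions:
        raise ValueError(f"no truth loci with >= {min_taxa} taxa")
    return Supermatrix(
        taxa=list(taxa),
        rows={t: "".join(chunks[t]) for t in taxa},
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

TINY_TREE = "((A:0.03,B:0.03):0.02,(C:0.03,D:0.03):0.02);"

# 12 taxa, Drosophila-flavoured: two short-branch species pairs and several
# long, phylogenetically isolated branches; max root-to-tip depth 0.15.
DROS12_TREE = (
    "(((((sim:0.015,sec:0.015):0.01,mel:0.03):0.01,(yak:0.02,ere:0.02):0.02):0.02,"
    "ana:0.1):0.03,((pse:0.008,per:0.008):0.09,wil:0.12):0.02,"
    "((vir:0.06,moj:0.06):0.02,gri:0.09):0.04);"
)

# two clades straddling a deep split; the far clade's taxa sit on long
# individual branches, so shared loci between them are essentially absent
SATURATED_TREE = (
    "(((A1:0.01,A2:0.01):0.01,(A3:0.01,A4:0.01):0.01):0.01,"
    "((B1:0.35,B2:0.35):0.01,(B3:0.35,B4:0.35):0.01):0.09);"
)

_FIXTURES = {
    "tiny": dict(tree=TINY_TREE, genome_length=5_000, n_sites=10, read_length=50),
    "dros12": dict(tree=DROS12_TREE, genome_length=200_000, n_sites=300, read_length=100),
    "saturated": dict(
        tree=SATURATED_TREE,
        genome_length=60_000,
        n_sites=80,
        read_length=50,
        motif_protection=False,
    ),
}


def make_fixture(
    name: str, seed: int = 0, out_dir: str | Path | None = None, **overrides
) -> SyntheticData:
    """Build a named fixture (``tiny`` | ``dros12`` | ``saturated``).

    Keyword overrides are applied on top of the preset (e.g.
    ``motif_protection=False`` or a different ``read_length``).  With
    ``out_dir``, genomes, alignment, truth table, and true tree are written
    to disk.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    cfg = dict(_FIXTURES[name])
    cfg.update(overrides)
    params = SynthParams(seed=seed, **cfg)
    data = simulate_genomes(params)
    if out_dir is not None:
        write_fixture(data, out_dir)
    return data


def write_fixture(data: SyntheticData, out_dir: str | Path) -> None:
    """Write a simulated data set: per-taxon genome FASTAs, alignment FASTA,
    truth TSV, and the true tree as Newick."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome_dir = out / "genomes"
    genome_dir.mkdir(exist_ok=True)
    for taxon, g in data.genomes.items():
        write_fasta(g.contigs.items(), genome_dir / f"{taxon}.fasta")
    write_fasta(
        ((t, data.alignment.rows[t]) for t in data.alignment.taxa),
        out / "alignment.fasta",
    )
    with open(out / "truth.tsv", "w") as fh:
        fh.write("site_column\tside\ttaxon\tpresent\tflank\n")
        for col, side in data.truth.locus_keys:
            for taxon in data.alignment.taxa:
                flank = data.truth.flanks[(col, side)].get(taxon)
                fh.write(
                    f"{col}\t{side}\t{taxon}\t{int(flank is not None)}\t{flank or ''}\n"
                )
    write_newick(data.tree, out / "true_tree.nwk")
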