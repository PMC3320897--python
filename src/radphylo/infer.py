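"""Distance-based tree inference on supermatrices.

Pairwise distances use pairwise deletion (a site contributes to a pair only
when both taxa hold A/C/G/T there), as either raw p-distances or Jukes-Cantor
corrected distances capped for saturated pairs.  Trees come from canonical
Saitou-Nei neighbor joining; node support from a nonparametric bootstrap that
resamples matrix columns with replacement and counts bipartition recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .assemble import Supermatrix

logger = logging.getLogger(__name__)

DIST_MAX = 5.0  # cap for saturated (p >= 0.749) pairs
_P_SAT = 0.749


class IncompleteMatrixError(ValueError):
    """The supermatrix lacks all data for at least one taxon."""


class ZeroOverlapError(ValueError):
    """A pair of taxa shares no comparable sites."""


@dataclass
class DistanceMatrix:
    """Symmetric distances with zero diagonal, in supermatrix taxon order."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite and non-negative")
        self.values = v


def _matrix_patterns(m: Supermatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse matrix columns to unique patterns with multiplicities.

    Returns (valid mask per unique column, codes per unique column, counts).
    """
    codes = m.codes()
    uniq, inverse, counts = np.unique(
        codes, axis=1, return_inverse=True, return_counts=True
    )
    valid = (
        (uniq == ord("A")) | (uniq == ord("C")) | (uniq == ord("G")) | (uniq == ord("T"))
    )
    return valid, uniq, counts.astype(np.float64)


def _pairwise_p(
    valid: np.ndarray, uniq: np.ndarray, weights: np.ndarray, taxa: list[str]
) -> np.ndarray:
    """p-distance matrix from weighted unique column patterns."""
    n = len(taxa)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = weights[both].sum()
            if compared == 0:
                raise ZeroOverlapError(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable sites"
                )
            mism = weights[both & (uniq[i] != uniq[j])].sum()
            p[i, j] = p[j, i] = mism / compared
    return p


def _jc69(p: np.ndarray) -> np.ndarray:
    d = np.empty_like(p)
    sat = p >= _P_SAT
    with np.errstate(invalid="ignore", divide="ignore"):
        d[~sat] = -0.75 * np.log1p(-(4.0 / 3.0) * p[~sat])
    d[sat] = DIST_MAX
    if sat.any():
        logger.info("capped %d saturated pair(s) at %.1f", sat.sum() // 2, DIST_MAX)
    np.fill_diagonal(d, 0.0)
    return d


def pairwise_distance(m: Supermatrix, model: str = "jc69") -> DistanceMatrix:
    """Pairwise-deletion distances between all taxa of a supermatrix.

    ``model='p'`` gives raw proportions of mismatching compared sites;
    ``'jc69'`` applies the Jukes-Cantor correction -(3/4)ln(1-4p/3), capped
    at 5.0 substitutions/site for saturated pairs.
    """
    if model not in ("p", "jc69"):
        raise ValueError(f"model must be 'p' or 'jc69', got {model!r}")
    if m.incomplete:
        raise IncompleteMatrixError(
            "matrix has taxa with no data; trees are not inferred in this case"
        )
    valid, uniq, weights = _matrix_patterns(m)
    p = _pairwise_p(valid, uniq, weights, m.taxa)
    values = p if model == "p" else _jc69(p)
    return DistanceMatrix(taxa=list(m.taxa), values=values)


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor joining.

    Q-matrix ties are broken by the lowest (i, j) taxon-index pair; negative
    branch lengths are clamped to zero.  Deterministic.  The returned tree is
    unrooted (seed node of degree 3).
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(d.taxa)
    nodes = []
    for label in d.taxa:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    D = d.values.copy()
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - (r[:, None] + r[None, :])
        iu = np.triu_indices(k, 1)
        # argmin over the upper triangle is row-major, so ties resolve to the
        # lowest (i, j) index pair automatically
        best = int(np.argmin(Q[iu]))
        ai, aj = int(iu[0][best]), int(iu[1][best])
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (k - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, length in ((nodes[i_glob], li), (nodes[j_glob], lj)):
            parent.add_child(child)
            child.edge.length = max(0.0, float(length))
        # distances from the new node to the remaining actives
        new_row = np.zeros(D.shape[0] + 1)
        for am, m_glob in enumerate(active):
            if m_glob in (i_glob, j_glob):
                continue
            new_row[m_glob] = 0.5 * (sub[ai, am] + sub[aj, am] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i_glob, j_glob)] + [len(nodes) - 1]

    a, b, c = active
    center = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, float(length))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


@dataclass
class SupportedTree:
    """An NJ point-estimate tree with per-internal-edge bootstrap support."""

    tree: dendropy.Tree
    supports: dict  # bipartition key -> percent in [0, 100]
    n_replicates: int
    n_failed: int  # replicates skipped for zero-overlap pairs


def bootstrap_support(
    m: Supermatrix, n_replicates: int = 100, seed: int = 0, model: str = "jc69"
) -> SupportedTree:
    """Nonparametric bootstrap support for the NJ tree of a supermatrix.

    Columns are resampled with replacement (width preserved), a tree is
    inferred per replicate, and each internal edge of the point-estimate tree
    is scored with the percentage of replicate trees containing the same
    taxon bipartition.  Replicates that produce a zero-overlap pair are
    skipped and counted.  Reproducible from ``seed``.
    """
    from .evaluate import bipartitions, split_key

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = nj_tree(pairwise_distance(m, model=model))
    point_splits = bipartitions(point)
    keys = {split_key(s, m.taxa): s for s in point_splits}
    tally = {k: 0 for k in keys}

    valid, uniq, weights = _matrix_patterns(m)
    n_states = sum(
        ((uniq == b) & valid).any(axis=0).astype(int) for b in (65, 67, 71, 84)
    )
    if not np.any(np.asarray(n_states) >= 2):
        warnings.warn("matrix has no variable sites; all supports are 0", stacklevel=2)
        _annotate(point, {k: 0.0 for k in keys}, m.taxa)
        return SupportedTree(point, {k: 0.0 for k in keys}, n_replicates, 0)

    rng = np.random.default_rng(seed)
    width = int(weights.sum())
    probs = weights / width
    n_failed = 0
    n_ok = 0
    for _ in range(n_replicates):
        w = rng.multinomial(width, probs).astype(np.float64)
        try:
            p = _pairwise_p(valid, uniq, w, m.taxa)
        except ZeroOverlapError:
            n_failed += 1
            continue
        values = p if model == "p" else _jc69(p)
        rep_tree = nj_tree(DistanceMatrix(list(m.taxa), values))
        rep_keys = {split_key(s, m.taxa) for s in bipartitions(rep_tree)}
        for k in tally:
            if k in rep_keys:
                tally[k] += 1
        n_ok += 1
    if n_failed:
        logger.info("bootstrap: %d/%d replicates skipped (zero overlap)", n_failed, n_replicates)
    denom = max(n_ok, 1)
    supports = {k: 100.0 * tally[k] / denom for k in tally}
    _annotate(point, supports, m.taxa)
    return SupportedTree(point, supports, n_replicates, n_failed)


def _annotate(tree: dendropy.Tree, supports: dict, taxa: list[str]) -> None:
    """Write supports onto internal node labels for Newick output."""
    from .evaluate import _edge_split, split_key

    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        split = _edge_split(node, tree)
        if split is None:
            continue
        k = split_key(split, taxa)
        if k in supports:
            node.label = f"{supports[k]:.0f}"
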