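"""Distance computation, neighbor-joining, and bootstrap support.

Distances come from a consumed multiple alignment under pairwise gap
deletion, either as raw p-distances or with the Poisson correction
``d = -ln(1 - p)`` (the default for proteins).  Trees are built with the
Saitou–Nei neighbor-joining algorithm; ties in the Q criterion break on
the lowest (row, column) pair and negative branch lengths are clamped to
zero (the raw value is logged).  Bootstrap support of an internal edge is
the fraction of column-resampled replicate trees containing the same
bipartition of taxa.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .io_formats import GAP, AlignmentSet

logger = logging.getLogger(__name__)

_MODELS = ("p", "poisson")


def pairwise_distance(
    aln: AlignmentSet, model: str = "poisson", max_p: float | None = None
) -> DistanceMatrix:
    """Pairwise distances from an alignment under pairwise gap deletion.

    ``model="p"`` returns the proportion of differing sites over columns
    where neither sequence has a gap; ``model="poisson"`` applies
    ``d = -ln(1 - p)``.  A pair with no comparable columns is an error, as
    is a saturated pair (p = 1) under the Poisson correction.  ``max_p``
    optionally caps p below 1 before correction (used internally by the
    bootstrap, where resampled columns can saturate a pair).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown distance model {model!r}; use one of {_MODELS}")
    arr = np.array([list(row) for row in aln.rows])
    nongap = arr != GAP
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = nongap[i] & nongap[j]
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.taxa[i]!r} and "
                    f"{aln.taxa[j]!r} after pairwise gap deletion"
                )
            p = float((arr[i, mask] != arr[j, mask]).sum()) / m
            if model == "poisson":
                if max_p is not None:
                    p = min(p, max_p)
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair ({aln.taxa[i]!r}, {aln.taxa[j]!r}): "
                        "p = 1 leaves the Poisson distance undefined"
                    )
                d[i, j] = d[j, i] = -np.log1p(-p)
            else:
                d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=aln.taxa)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted dendropy tree.  For two taxa, the single edge of
    length d is split evenly between the pendant branches; for the final
    three nodes the closed-form pendant lengths are used.  Negative branch
    lengths are clamped to zero.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    tns = dendropy.TaxonNamespace(ids)
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=tns.get_taxon(label)) for label in ids
    ]
    D = dm.data.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative branch length %.6g to 0", x)
            return 0.0
        return x

    if n == 2:
        root = dendropy.Node()
        for node in nodes:
            root.add_child(node)
            node.edge.length = clamp(D[0, 1] / 2.0)
    else:
        while len(nodes) > 3:
            m = len(nodes)
            r = D.sum(axis=1)
            best = None
            best_q = np.inf
            for i in range(m):
                for j in range(i + 1, m):
                    q = (m - 2) * D[i, j] - r[i] - r[j]
                    if q < best_q:  # strict: ties keep the lowest (i, j)
                        best_q, best = q, (i, j)
            i, j = best  # type: ignore[misc]
            dij = D[i, j]
            li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
            lj = dij - li
            parent = dendropy.Node()
            parent.add_child(nodes[i])
            nodes[i].edge.length = clamp(li)
            parent.add_child(nodes[j])
            nodes[j].edge.length = clamp(lj)
            d_new = np.array(
                [0.5 * (D[i, k] + D[j, k] - dij) for k in range(m)]
            )
            keep = [k for k in range(m) if k not in (i, j)]
            D2 = np.zeros((len(keep) + 1, len(keep) + 1))
            D2[:-1, :-1] = D[np.ix_(keep, keep)]
            D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
            D = D2
            nodes = [nodes[k] for k in keep] + [parent]
        # final three nodes around the central vertex
        root = dendropy.Node()
        (a, b, c) = (0, 1, 2)
        lengths = (
            0.5 * (D[a, b] + D[a, c] - D[b, c]),
            0.5 * (D[a, b] + D[b, c] - D[a, c]),
            0.5 * (D[a, c] + D[b, c] - D[a, b]),
        )
        for node, length in zip(nodes, lengths):
            root.add_child(node)
            node.edge.length = clamp(length)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def path_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf patristic distances of a tree, as a DistanceMatrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (leaf.taxon for leaf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    ids = [t.label for t in taxa]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(d, ids=ids)


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a tree as normalized leaf-label sets.

    Each internal edge is represented by the side NOT containing the
    lexicographically smallest taxon, so that the representation does not
    depend on rooting or child rotation.
    """
    all_taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(all_taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if 2 <= len(clade) <= len(all_taxa) - 2:
            if ref in clade:
                clade = all_taxa - clade
            splits.add(clade)
    return splits


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: AlignmentSet,
    model: str = "poisson",
    n_reps: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal edge of the tree built from the full alignment is
    the fraction of replicate trees containing the same bipartition.
    Supports are stored on internal nodes as ``node.support`` in [0, 1]
    (and mirrored into ``node.label``).  Resampled replicates can
    saturate a pair under the Poisson model, so replicate distances cap
    p at ``1 - 1/(2 * n_sites)``; the tree from the full alignment is
    computed without the cap.  Deterministic under ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(pairwise_distance(aln, model))
    rng = np.random.default_rng(seed)
    n_sites = aln.n_sites
    cap = 1.0 - 0.5 / n_sites
    rows = np.array([list(r) for r in aln.rows])
    counts: Counter[frozenset[str]] = Counter()
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = AlignmentSet(
            list(aln.taxa), ["".join(row) for row in rows[:, cols]]
        )
        rep_tree = nj_tree(pairwise_distance(rep, model, max_p=cap))
        counts.update(tree_splits(rep_tree))

    all_taxa = frozenset(aln.taxa)
    ref = min(all_taxa)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if not (2 <= len(clade) <= len(all_taxa) - 2):
            continue
        key = all_taxa - clade if ref in clade else clade
        support = counts.get(key, 0) / n_reps
        node.support = support  # type: ignore[attr-defined]
        node.label = f"{support:.3f}"
    return tree


# ---------------------------------------------------------------------------
# cluster proportions
# ---------------------------------------------------------------------------

def cluster_proportions_from_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Cluster share of the total, as fractions summing to 1."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("cluster counts sum to zero")
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative cluster count")
    return {k: v / total for k, v in counts.items()}


def cluster_proportions(
    assignments: Mapping[str, str], taxa: Sequence[str] | None = None
) -> dict[str, float]:
    """Proportion of taxa per cluster from an explicit assignment map.

    ``taxa``, when given, is the full taxon list; any taxon without an
    assignment is an error.  Report to 0.1% by rounding downstream.
    """
    if taxa is not None:
        missing = [t for t in taxa if t not in assignments]
        if missing:
            raise ValueError(f"unassigned taxa: {missing}")
        assignments = {t: assignments[t] for t in taxa}
    if not assignments:
        raise ValueError("no taxa assigned")
    return cluster_proportions_from_counts(Counter(assignments.values()))
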