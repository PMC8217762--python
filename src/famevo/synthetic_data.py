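"""Seeded generators producing inputs with known ground truth.

Every stage of the pipeline can be exercised without downloads: protein
families evolving along a shared tree with optionally correlated rates
(mirror-tree recovery), chromosome gene orders with planted tandem
groups, ortholog presence tables with planted stratum counts, and
expression matrices with planted up/down genes.

All generators draw from named substreams of a single master seed, so
adding a generator never perturbs the output of an existing one, and an
identical spec (including seed) reproduces identical outputs bitwise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import AlignmentSet, GeneLocus
from .phylostrat import PATTERN_LABELS, pattern_to_flags
from .io_formats import SPECIES_ORDER, ExpressionMatrix, OrthologPresence
import pandas as pd

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
N_STATES = 20


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child stream of a master seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, key]))


@dataclass
class SimSpec:
    """Study-condition defaults for all generators.

    The defaults mirror the analyzed study system: a 19-member and a
    6-member family, 24 species, four planted tandem pairs among 19
    family genes, stratum counts 10/7/1/1, and a two-group expression
    design with 3 up and 7 down genes out of 19 at effect size 3 log2
    units over unit noise, 5 samples per group.
    """

    seed: int = 0
    n_taxa: int = 24
    sequence_length: int = 300
    rate_correlation: float = 0.9
    n_members_a: int = 19
    n_members_b: int = 6
    n_family_genes: int = 19
    planted_group_sizes: tuple[int, ...] = (2, 2, 2, 2)
    n_chromosomes: int = 10
    n_spacers: int = 150
    stratum_counts: dict[str, int] = field(
        default_factory=lambda: {"+++-": 10, "++--": 7, "+---": 1, "----": 1}
    )
    n_genes_de: int = 19
    n_up: int = 3
    n_down: int = 7
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_per_group: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_correlation <= 1.0:
            raise ValueError("rate_correlation must be in [0, 1]")
        if any(s < 2 for s in self.planted_group_sizes):
            raise ValueError("planted tandem groups need >= 2 members")
        if self.n_up + self.n_down > self.n_genes_de:
            raise ValueError("more planted DE genes than genes")
        bad = sorted(set(self.stratum_counts) - set(PATTERN_LABELS))
        if bad:
            raise ValueError(f"unknown stratum label(s): {bad}")
        if any(v < 0 for v in self.stratum_counts.values()):
            raise ValueError("stratum counts must be >= 0")


# ---------------------------------------------------------------------------
# trees and sequences
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int,
    seed: int | None = None,
    mean_branch: float = 0.1,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """A random Yule (pure-birth) tree with exponential branch lengths.

    A uniformly chosen leaf splits at each step until ``n_taxa`` leaves
    exist; every edge then receives an Exponential(``mean_branch``)
    length in expected substitutions per site.  Leaves are labelled
    ``sp1..spN``.  Deterministic under ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if rng is None:
        rng = substream(seed if seed is not None else 0, "tree")
    root = dendropy.Node()
    leaves = [dendropy.Node(), dendropy.Node()]
    for leaf in leaves:
        root.add_child(leaf)
    while len(leaves) < n_taxa:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        children = [dendropy.Node(), dendropy.Node()]
        for child in children:
            parent.add_child(child)
        leaves.extend(children)
    labels = [f"sp{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    i = 0
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.edge.length = float(rng.exponential(mean_branch))
        if node.is_leaf():
            node.taxon = tns.get_taxon(labels[i])
            i += 1
    return tree


def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    edge_rates: Sequence[float] | None = None,
) -> AlignmentSet:
    """Evolve an equal-rates 20-state alignment along a tree.

    The root sequence is uniform over the 20 states.  Along a branch of
    length ``t`` each site keeps its state with probability
    ``exp(-rate * t)`` and is otherwise redrawn uniformly over all 20
    states (the jump-chain form of the 20-state equal-rates model), so
    the expected proportion of sites differing from the parent is
    ``(19/20) * (1 - exp(-rate * t))`` and saturates at 19/20 on long
    branches.  ``edge_rates`` optionally supplies one rate multiplier
    per edge in preorder.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rng is None:
        rng = substream(seed if seed is not None else 0, "seq")
    edges = [
        node for node in tree.preorder_node_iter() if node is not tree.seed_node
    ]
    if edge_rates is not None and len(edge_rates) != len(edges):
        raise ValueError(
            f"edge_rates has {len(edge_rates)} entries for {len(edges)} edges"
        )
    seqs: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.integers(0, N_STATES, size=length)
    }
    rows: dict[str, str] = {}
    for idx, node in enumerate(edges):
        mult = 1.0 if edge_rates is None else float(edge_rates[idx])
        if mult < 0:
            raise ValueError("negative edge rate multiplier")
        t = (node.edge.length or 0.0) * rate * mult
        parent_seq = seqs[id(node.parent_node)]
        child = parent_seq.copy()
        if t > 0:
            changed = rng.random(length) < -np.expm1(-t)
            n_changed = int(changed.sum())
            if n_changed:
                child[changed] = rng.integers(0, N_STATES, size=n_changed)
        seqs[id(node)] = child
        if node.is_leaf():
            rows[node.taxon.label] = "".join(AA_ORDER[s] for s in child)
    def label_key(lab: str) -> tuple:
        head = lab.rstrip("0123456789")
        tail = lab[len(head):]
        return (head, int(tail)) if tail else (lab, -1)

    taxa = sorted(rows, key=label_key)
    return AlignmentSet(taxa, [rows[t] for t in taxa])


def simulate_family_pair(
    tree: dendropy.Tree,
    rho: float,
    n_members_a: int,
    n_members_b: int,
    length: int,
    seed: int = 0,
    sigma: float = 0.75,
) -> tuple[dict[str, AlignmentSet], dict[str, AlignmentSet]]:
    """Two families of member alignments with correlated branch rates.

    All members evolve along the shared ``tree``; each member's per-edge
    log rate multiplier mixes a shared standard-normal profile with a
    member-specific one: ``z = sigma * (sqrt(rho) * shared +
    sqrt(1 - rho) * own)``, giving log-rate correlation ``rho`` between
    any two members.  ``rho = 1`` means identical rate profiles,
    ``rho = 0`` fully independent ones.  Multipliers are mean-corrected
    log-normals ``exp(z - sigma^2 / 2)``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    rng = substream(seed, "coevo")
    n_edges = sum(
        1 for node in tree.preorder_node_iter() if node is not tree.seed_node
    )
    shared = rng.normal(size=n_edges)

    def make_member(name: str) -> AlignmentSet:
        own = rng.normal(size=n_edges)
        z = sigma * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own)
        mults = np.exp(z - sigma**2 / 2.0)
        return evolve_sequences(tree, length, rng=rng, edge_rates=mults)

    fam_a = {f"A{i + 1}": make_member(f"A{i + 1}") for i in range(n_members_a)}
    fam_b = {f"B{i + 1}": make_member(f"B{i + 1}") for i in range(n_members_b)}
    return fam_a, fam_b


# ---------------------------------------------------------------------------
# genomes, ortholog tables, expression matrices
# ---------------------------------------------------------------------------

def synth_genome(
    n_family: int = 19,
    planted_group_sizes: Sequence[int] = (2, 2, 2, 2),
    n_chromosomes: int = 10,
    n_spacers: int = 150,
    seed: int = 0,
    family: str = "Wnt",
) -> tuple[list[GeneLocus], list[tuple[str, ...]]]:
    """A gene table with planted tandem groups and isolated singletons.

    Family genes are laid out as blocks (each planted group is one block
    of adjacent genes; every remaining family gene is its own block);
    blocks land on random chromosomes with at least one spacer gene
    between consecutive blocks, so tandem detection must recover exactly
    the planted groups.  Returns (loci, planted groups as gene-id
    tuples).
    """
    if any(s < 2 for s in planted_group_sizes):
        raise ValueError("planted groups need >= 2 members")
    n_grouped = sum(planted_group_sizes)
    if n_grouped > n_family:
        raise ValueError("planted groups exceed the family size")
    rng = substream(seed, "genome")

    blocks: list[list[str]] = []
    gene_no = 0
    planted: list[tuple[str, ...]] = []
    for size in planted_group_sizes:
        members = tuple(f"{family}{gene_no + k + 1}" for k in range(size))
        gene_no += size
        planted.append(members)
        blocks.append(list(members))
    for _ in range(n_family - n_grouped):
        blocks.append([f"{family}{gene_no + 1}"])
        gene_no += 1

    chrom_of_block = rng.integers(0, n_chromosomes, size=len(blocks))
    # at least one spacer between blocks plus extras spread at random
    extra = rng.multinomial(n_spacers, np.full(len(blocks) + 1, 1.0 / (len(blocks) + 1)))
    layouts: dict[str, list[tuple[str, str]]] = {
        f"chr{i + 1}": [] for i in range(n_chromosomes)
    }
    spacer_no = 0

    order = rng.permutation(len(blocks))
    for pos, b in enumerate(order):
        chrom = f"chr{chrom_of_block[b] + 1}"
        for _ in range(1 + int(extra[pos])):
            spacer_no += 1
            layouts[chrom].append((f"g{spacer_no}", "other"))
        for gid in blocks[b]:
            layouts[chrom].append((gid, family))
    for _ in range(int(extra[-1])):
        spacer_no += 1
        chrom = f"chr{int(rng.integers(n_chromosomes)) + 1}"
        layouts[chrom].append((f"g{spacer_no}", "other"))

    loci: list[GeneLocus] = []
    for chrom, genes in layouts.items():
        pos = 1
        for gid, fam in genes:
            g_len = int(rng.integers(2_000, 50_000))
            loci.append(GeneLocus(gid, chrom, pos, pos + g_len, fam))
            pos += g_len + int(rng.integers(5_000, 100_000))
    return loci, planted


def synth_orthologs(
    stratum_counts: Mapping[str, int], seed: int = 0
) -> OrthologPresence:
    """An ortholog presence table with exactly the requested strata."""
    bad = sorted(set(stratum_counts) - set(PATTERN_LABELS))
    if bad:
        raise ValueError(f"unknown stratum label(s): {bad}")
    if any(v < 0 for v in stratum_counts.values()):
        raise ValueError("stratum counts must be >= 0")
    rng = substream(seed, "orthologs")
    rows = []
    gene_no = 0
    for label in PATTERN_LABELS:
        flags = pattern_to_flags(label)
        for _ in range(int(stratum_counts.get(label, 0))):
            gene_no += 1
            rows.append((f"gene{gene_no}", flags))
    if not rows:
        raise ValueError("all stratum counts are zero")
    rng.shuffle(rows)
    table = pd.DataFrame(
        [flags for _, flags in rows],
        index=[gid for gid, _ in rows],
        columns=list(SPECIES_ORDER),
    )
    table.index.name = "gene_id"
    return OrthologPresence(table)


def synth_expression(
    n_genes: int = 19,
    n_up: int = 3,
    n_down: int = 7,
    effect: float = 3.0,
    noise_sd: float = 1.0,
    n_per_group: int = 5,
    seed: int = 0,
    group_case: str = "case",
    group_control: str = "control",
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """A log2 expression matrix with planted up/down genes.

    Every value is gene baseline plus Gaussian noise; planted genes get
    a mean shift of +/- ``effect`` log2 units in the case group.
    Returns (matrix with groups attached, true class per gene).
    """
    if n_up + n_down > n_genes:
        raise ValueError("more planted DE genes than genes")
    rng = substream(seed, "expression")
    genes = [f"gene{i + 1}" for i in range(n_genes)]
    truth = {}
    for i, g in enumerate(genes):
        truth[g] = "up" if i < n_up else "down" if i < n_up + n_down else "unchanged"
    samples = [f"{group_case}{j + 1}" for j in range(n_per_group)] + [
        f"{group_control}{j + 1}" for j in range(n_per_group)
    ]
    groups = {
        s: (group_case if s.startswith(group_case) else group_control)
        for s in samples
    }
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    values = baseline[:, None] + rng.normal(
        scale=noise_sd, size=(n_genes, 2 * n_per_group)
    )
    shift = np.array(
        [effect if truth[g] == "up" else -effect if truth[g] == "down" else 0.0
         for g in genes]
    )
    values[:, :n_per_group] += shift[:, None]
    mat = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), groups
    )
    return mat, truth
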