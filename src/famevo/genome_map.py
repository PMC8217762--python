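"""Chromosomal distribution summaries and tandem-duplication detection.

A tandem group is a maximal run of two or more same-family genes that are
immediately adjacent in the genome-wide gene order of their chromosome —
no spacer gene of any kind between them.  Adjacency is judged on the
gene-order index over ALL annotated genes (family and non-family), not on
a base-pair distance cutoff; an optional bp-threshold mode exists but is
off by default.  Strand is ignored throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import GeneLocus


@dataclass(frozen=True)
class TandemGroup:
    """Two or more same-family genes at consecutive gene-order positions."""

    chromosome: str
    members: tuple[str, ...]  # gene ids ordered by position

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem group needs at least 2 members")

    def __len__(self) -> int:
        return len(self.members)


def assign_order_index(loci: Iterable[GeneLocus]) -> list[GeneLocus]:
    """Rank genes along each chromosome by (start, end), 1-based.

    Returns new loci sorted by (chromosome, order_index).  Two genes with
    identical coordinates on one chromosome are an error: their order —
    and hence adjacency — would be undefined.
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    out: list[GeneLocus] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        for prev, cur in zip(genes, genes[1:]):
            if (prev.start, prev.end) == (cur.start, cur.end):
                raise ValueError(
                    f"{chrom}: genes {prev.gene_id!r} and {cur.gene_id!r} "
                    "share identical coordinates; gene order is undefined"
                )
        for idx, g in enumerate(genes, 1):
            out.append(
                GeneLocus(
                    g.gene_id, g.chromosome, g.start, g.end,
                    g.family, g.strand, order_index=idx,
                )
            )
    return out


def _validate_indices(loci: Sequence[GeneLocus]) -> None:
    seen: dict[str, set[int]] = {}
    for g in loci:
        idxs = seen.setdefault(g.chromosome, set())
        assert g.order_index is not None
        if g.order_index in idxs:
            raise ValueError(
                f"duplicate order_index {g.order_index} on {g.chromosome}"
            )
        idxs.add(g.order_index)


def detect_tandem(
    loci: Iterable[GeneLocus],
    family: str,
    max_gap_bp: int | None = None,
) -> list[TandemGroup]:
    """Find tandem-duplicated genes of ``family`` among all annotated loci.

    ``loci`` must cover every annotated gene so that intervening
    non-family genes break runs.  Order indexes are computed from
    coordinates when absent.  Runs of three or more adjacent family genes
    chain transitively into a single group.  Input row order is
    irrelevant; loci are sorted internally.

    ``max_gap_bp``, when set, additionally requires consecutive members
    to lie within that many bp of each other (off by default).
    """
    loci = list(loci)
    if any(g.order_index is None for g in loci):
        loci = assign_order_index(loci)
    else:
        _validate_indices(loci)

    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in loci:
        by_chrom.setdefault(g.chromosome, []).append(g)

    groups: list[TandemGroup] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: g.order_index)  # type: ignore[arg-type,return-value]
        run: list[GeneLocus] = []

        def flush() -> None:
            if len(run) >= 2:
                groups.append(
                    TandemGroup(chrom, tuple(g.gene_id for g in run))
                )
            run.clear()

        for g in genes:
            if g.family != family:
                flush()
                continue
            if run and g.order_index == run[-1].order_index + 1:  # type: ignore[operator]
                if max_gap_bp is not None and g.start - run[-1].end > max_gap_bp:
                    flush()
                run.append(g)
            else:
                flush()
                run.append(g)
        flush()
    return groups


@dataclass(frozen=True)
class ChromosomeSummary:
    family: str
    counts: dict[str, int]  # chromosome -> gene count
    total: int
    top_k: int
    top_k_fraction: float


def chromosome_summary(
    loci: Iterable[GeneLocus], family: str, top_k: int = 3
) -> ChromosomeSummary:
    """Per-chromosome counts for one family and the top-k concentration.

    ``top_k_fraction`` is the share of family genes carried by the ``k``
    most populous chromosomes.
    """
    counts = Counter(g.chromosome for g in loci if g.family == family)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no loci of family {family!r}")
    if top_k > len(counts):
        raise ValueError(
            f"top_k={top_k} exceeds number of chromosomes ({len(counts)})"
        )
    top = sum(n for _, n in counts.most_common(top_k))
    return ChromosomeSummary(
        family=family,
        counts=dict(counts),
        total=total,
        top_k=top_k,
        top_k_fraction=top / total,
    )
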