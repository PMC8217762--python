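"""Worked-example data for the mouse Wnt and DIX families.

These tables encode the published count-level facts about the two
families — ortholog presence patterns across the four reference species,
the chromosomal tandem layout, phylogenetic cluster sizes, and
expression-change counts after pressure-overload surgery — so that every
downstream summary can be recomputed from scratch without any downloads.

Per-gene attributions that the published counts do not determine (for
example, exactly which of the 19 Wnt genes carries which ortholog
pattern) are synthetic placeholders; every count-level quantity is
faithful.  Chromosome coordinates in the gene table are likewise
synthetic: only the per-chromosome membership, adjacency, and spacer
structure matter for the analyses.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import SPECIES_ORDER, GeneLocus, OrthologPresence
from .phylostrat import pattern_to_flags

#: The 19 mouse Wnt genes.
MOUSE_WNT_GENES = (
    "Wnt1", "Wnt2", "Wnt2b", "Wnt3", "Wnt3a", "Wnt4", "Wnt5a", "Wnt5b",
    "Wnt6", "Wnt7a", "Wnt7b", "Wnt8a", "Wnt8b", "Wnt9a", "Wnt9b",
    "Wnt10a", "Wnt10b", "Wnt11", "Wnt16",
)

#: The 6 mouse DIX-domain genes (Dishevelled, Axin, Dixin).
MOUSE_DIX_GENES = ("Dvl1", "Dvl2", "Dvl3", "Axin1", "Axin2", "Dixdc1")

#: Published stratum counts for the 19 Wnt genes: 10 with orthologs out
#: to nematode, 7 out to sea urchin, 1 zebrafish-only, 1 mouse-only.
MOUSE_WNT_STRATUM_COUNTS = {"+++-": 10, "++--": 7, "+---": 1, "----": 1}

#: All six DIX genes have orthologs out to nematode but not yeast.
MOUSE_DIX_STRATUM_COUNTS = {"+++-": 6}

#: Genome-background share of mouse protein-coding genes with orthologs
#: out to nematode, used in the family-vs-background ratio.
MOUSE_GENOME_NEMATODE_PROP = 0.3680

#: Published protein lengths (aa) at the extremes of the Wnt family.
MOUSE_WNT_LENGTH_EXTREMES = {"Wnt10a": 417, "Wnt7a": 349}

#: DIX-family phylogenetic cluster sizes over 57 proteins from 24 species.
MOUSE_DIX_CLUSTER_COUNTS = {"Dvl": 24, "Axin": 21, "Dixin": 12}

#: Wnt-family cluster sizes over 118 proteins.  Only four of the seven
#: cluster sizes were published; the remaining three clusters are lumped.
MOUSE_WNT_CLUSTER_COUNTS = {"I": 18, "III": 20, "IV": 10, "VII": 23, "II+V+VI": 47}

#: Expression-change counts in pressure-overload hypertrophy (left
#: ventricle, 4 weeks after transverse aortic constriction).
MOUSE_DE_COUNTS = {
    "wnt_tac": {"down": 7, "up": 3, "unchanged": 9},
    "dix_tac": {"down": 3, "up": 1, "unchanged": 2},
}


def _presence(genes: tuple[str, ...], counts: dict[str, int]) -> OrthologPresence:
    labels: list[str] = []
    for label in ("++++", "+++-", "++--", "+---", "----"):
        labels.extend([label] * counts.get(label, 0))
    if len(labels) != len(genes):
        raise ValueError("stratum counts do not cover the gene list")
    table = pd.DataFrame(
        [pattern_to_flags(lab) for lab in labels],
        index=list(genes),
        columns=list(SPECIES_ORDER),
    )
    table.index.name = "gene_id"
    return OrthologPresence(table)


def mouse_wnt_ortholog_presence() -> OrthologPresence:
    """19-gene x 4-species presence matrix with the published strata.

    Which named gene carries which pattern is a placeholder assignment
    (the counts, not the per-gene attributions, are published).
    """
    return _presence(MOUSE_WNT_GENES, MOUSE_WNT_STRATUM_COUNTS)


def mouse_dix_ortholog_presence() -> OrthologPresence:
    """6-gene DIX presence matrix: every gene out to nematode only."""
    return _presence(MOUSE_DIX_GENES, MOUSE_DIX_STRATUM_COUNTS)


# Chromosome layout of the 19 Wnt and 6 DIX genes.  "." entries are
# spacer genes (non-family annotated genes); family genes listed
# adjacently with no "." between them form the four published tandem
# pairs.  Per-chromosome Wnt counts: chr6 and chr11 carry four each,
# chr15 three, chr1 two, and six chromosomes one each.
_CHR_LAYOUT: dict[str, tuple[str, ...]] = {
    "chr1": (".", "Wnt6", "Wnt10a", ".", "."),
    "chr3": (".", "Wnt2b", "."),
    "chr4": (".", "Wnt4", ".", "Dvl1", "."),
    "chr6": (".", "Wnt2", ".", "Wnt5a", ".", "Wnt7a", ".", "Wnt16", "."),
    "chr7": (".", "Wnt1", "."),
    "chr9": (".", "Dixdc1", "."),
    "chr11": (".", "Wnt3a", "Wnt9a", ".", "Dvl2", ".", "Wnt9b", "Wnt3", ".", "Axin2", "."),
    "chr14": (".", "Wnt8b", "."),
    "chr15": (".", "Wnt10b", "Wnt11", ".", "Wnt5b", "."),
    "chr16": (".", "Dvl3", "."),
    "chr17": (".", "Axin1", "."),
    "chr18": (".", "Wnt8a", "."),
    "chr19": (".", "Wnt7b", "."),
}

#: The four published tandem pairs among the 19 Wnt genes (8 genes, 42%).
MOUSE_WNT_TANDEM_PAIRS = (
    ("Wnt6", "Wnt10a"),
    ("Wnt3a", "Wnt9a"),
    ("Wnt9b", "Wnt3"),
    ("Wnt10b", "Wnt11"),
)


def mouse_gene_table() -> list[GeneLocus]:
    """Annotated gene table for the tandem/chromosome worked example.

    Contains the 19 Wnt genes, the 6 DIX genes, and spacer genes laid
    out per chromosome so that exactly the four published Wnt tandem
    pairs are adjacent and no DIX genes are.  Coordinates are synthetic
    and deterministic.
    """
    wnt = set(MOUSE_WNT_GENES)
    dix = set(MOUSE_DIX_GENES)
    loci: list[GeneLocus] = []
    spacer_no = 0
    for chrom, layout in _CHR_LAYOUT.items():
        pos = 100_000
        for entry in layout:
            if entry == ".":
                spacer_no += 1
                gid, family = f"spacer{spacer_no}", "other"
            else:
                gid = entry
                family = "Wnt" if entry in wnt else "DIX" if entry in dix else "other"
            loci.append(GeneLocus(gid, chrom, pos, pos + 10_000, family))
            pos += 60_000
    return loci
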