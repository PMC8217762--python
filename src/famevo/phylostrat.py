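"""Ortholog-pattern phylostratigraphy and family-size correlation.

Each gene carries four ortholog presence flags over reference species
ordered zebrafish, sea urchin, nematode, yeast (most recent to most
ancient divergence from mouse).  The stratum label is set by the most
distant species with an ortholog: yeast -> "++++" (origin with
eukaryotes), nematode -> "+++-", sea urchin -> "++--", zebrafish ->
"+---", none -> "----" (origin after the invertebrate–vertebrate split).
Presence patterns with a gap (a distant species present while a nearer
one is absent) cannot be written in the five symbols; they are labelled
by the deepest present species and flagged ``non_nested``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SPECIES_ORDER, OrthologPresence

#: The five stratum labels, oldest origin first.
PATTERN_LABELS = ("++++", "+++-", "++--", "+---", "----")

#: Labels indicating emergence after the invertebrate–vertebrate split.
POST_SPLIT_LABELS = ("+---", "----")


@dataclass(frozen=True)
class PhyloPattern:
    """A stratum label plus a flag for non-nested presence patterns."""

    label: str
    non_nested: bool = False

    def __post_init__(self) -> None:
        if self.label not in PATTERN_LABELS:
            raise ValueError(f"unknown pattern label {self.label!r}")


def classify_pattern(flags: Sequence[bool]) -> PhyloPattern:
    """Stratum label from four presence flags in :data:`SPECIES_ORDER`.

    The label is set by the most distant species with an ortholog;
    ``non_nested`` is True when a species is absent while a more distant
    one is present (e.g. present in nematode but not sea urchin).
    """
    if len(flags) != len(SPECIES_ORDER):
        raise ValueError(
            f"expected {len(SPECIES_ORDER)} flags, got {len(flags)}"
        )
    flags = tuple(bool(f) for f in flags)
    present = [i for i, f in enumerate(flags) if f]
    if not present:
        return PhyloPattern("----")
    deepest = max(present)
    label = PATTERN_LABELS[len(SPECIES_ORDER) - 1 - deepest]
    non_nested = any(not flags[i] for i in range(deepest))
    return PhyloPattern(label, non_nested)


def pattern_to_flags(label: str) -> tuple[bool, bool, bool, bool]:
    """The nested presence flags corresponding to a stratum label."""
    if label not in PATTERN_LABELS:
        raise ValueError(f"unknown pattern label {label!r}")
    n_present = len(SPECIES_ORDER) - PATTERN_LABELS.index(label)
    return tuple(
        i < n_present for i in range(len(SPECIES_ORDER))
    )  # type: ignore[return-value]


def classify_presence(presence: OrthologPresence) -> dict[str, PhyloPattern]:
    """Classify every gene of an ortholog presence table."""
    return {
        gene: classify_pattern(presence.flags(gene)) for gene in presence.genes
    }


@dataclass(frozen=True)
class StratumSummary:
    """Counts and proportions per stratum label for one gene set."""

    counts: dict[str, int]
    proportions: dict[str, float]
    #: Share of genes that emerged after the invertebrate–vertebrate
    #: split ("+---" plus "----").
    post_vertebrate_split: float
    n_genes: int


def stratum_proportions(
    patterns: Iterable[PhyloPattern | str],
) -> StratumSummary:
    """Proportion of genes per stratum label (sums to 1 over the five)."""
    labels = [
        p.label if isinstance(p, PhyloPattern) else str(p) for p in patterns
    ]
    if not labels:
        raise ValueError("empty gene set")
    bad = sorted(set(labels) - set(PATTERN_LABELS))
    if bad:
        raise ValueError(f"unknown pattern label(s): {bad}")
    counts = Counter(labels)
    n = len(labels)
    proportions = {lab: counts.get(lab, 0) / n for lab in PATTERN_LABELS}
    post = sum(proportions[lab] for lab in POST_SPLIT_LABELS)
    return StratumSummary(
        counts={lab: counts.get(lab, 0) for lab in PATTERN_LABELS},
        proportions=proportions,
        post_vertebrate_split=post,
        n_genes=n,
    )


def compare_to_background(
    family_counts: Mapping[str, int],
    genome_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Family vs genome-background stratum enrichment.

    For each stratum: the proportion in the family, the proportion in the
    genome background, their ratio, and a two-sided Fisher exact p-value
    from the 2x2 table (in-stratum vs not) x (family vs genome).
    """
    fam_total = sum(family_counts.get(lab, 0) for lab in PATTERN_LABELS)
    gen_total = sum(genome_counts.get(lab, 0) for lab in PATTERN_LABELS)
    if gen_total == 0:
        raise ValueError("genome background has zero total count")
    if fam_total == 0:
        raise ValueError("family has zero total count")
    rows = []
    for lab in PATTERN_LABELS:
        f_in = family_counts.get(lab, 0)
        g_in = genome_counts.get(lab, 0)
        f_prop = f_in / fam_total
        g_prop = g_in / gen_total
        ratio = np.inf if g_prop == 0 and f_prop > 0 else (
            f_prop / g_prop if g_prop > 0 else np.nan
        )
        _, p = stats.fisher_exact(
            [[f_in, fam_total - f_in], [g_in, gen_total - g_in]],
            alternative="two-sided",
        )
        rows.append(
            {
                "pattern": lab,
                "family_prop": f_prop,
                "genome_prop": g_prop,
                "ratio": ratio,
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("pattern")


def family_size_correlation(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of two family-size vectors across species.

    Returns (r, two-sided p from the t distribution with n-2 df).
    Requires at least 3 species and non-constant vectors.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("family-size vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant family-size vector: correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
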