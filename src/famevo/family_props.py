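"""Family membership and per-protein physicochemical characterization.

Membership comes from Pfam domain hits filtered at the classic
``E-value <= 1e-5 and bit score >= 0`` thresholds (both inclusive), with
one representative isoform per gene.  Each representative gets a
molecular weight (average residue masses plus one water) and an
isoelectric point (bisection on the Henderson–Hasselbalch net charge with
the Bjellqvist/ExPASy pK set), plus an ordered domain-architecture string.
Cross-species family sizes are summarized as a census with group means and
a one-way ANOVA with Dunnett-adjusted pairwise comparisons.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AMINO_ACIDS, DomTblRow

# Average (not monoisotopic) residue masses in Daltons, as used by the
# ExPASy Compute pI/Mw tool.  A peptide's mass is the sum of residue
# masses plus one water.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
#: Unknown residue X contributes the average of the 20 canonical masses
#: and is ignored for charge.
X_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

#: Bjellqvist/ExPASy pK values; swappable via the ``pk`` argument of
#: :func:`isoelectric_point`.
PK_BJELLQVIST: dict[str, float] = {
    "nterm": 7.5, "cterm": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    "H": 5.98, "K": 10.0, "R": 12.0,
}
_ACIDIC = ("cterm", "D", "E", "C", "Y")
_BASIC = ("nterm", "H", "K", "R")


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Daltons of a protein sequence.

    Sum of average residue masses plus one water (18.0153 Da).
    ``X`` contributes the mean canonical residue mass.
    """
    if not sequence:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    total = WATER_MASS
    for ch in sequence:
        if ch == "X":
            total += X_MASS
        elif ch in RESIDUE_MASS:
            total += RESIDUE_MASS[ch]
        else:
            raise ValueError(f"non-canonical residue {ch!r}")
    return total


def net_charge(sequence: str, ph: float, pk: Mapping[str, float] = PK_BJELLQVIST) -> float:
    """Henderson–Hasselbalch net charge of a protein at a given pH.

    Ionizable groups: the two termini plus D, E, C, Y (acidic) and
    H, K, R (basic).  ``X`` carries no charge.  The result is strictly
    decreasing in pH, so the isoelectric point is a unique root.
    """
    counts = Counter(sequence)
    counts["nterm"] = 1
    counts["cterm"] = 1
    charge = 0.0
    for grp in _BASIC:
        n = counts.get(grp, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pk[grp]))
    for grp in _ACIDIC:
        n = counts.get(grp, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pk[grp] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    tol: float = 1e-3,
    pk: Mapping[str, float] = PK_BJELLQVIST,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    A composition-only function: permuting the sequence cannot change it.
    """
    if not sequence:
        raise ValueError("cannot compute pI of an empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pk) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def orf_length_bp(n_residues: int) -> int:
    """CDS length in bp for a protein of ``n_residues`` amino acids.

    Three bases per codon plus one stop codon: ``3 * (n + 1)``.
    """
    if n_residues < 1:
        raise ValueError("protein length must be >= 1")
    return 3 * (n_residues + 1)


# ---------------------------------------------------------------------------
# records and membership
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """One protein per gene with computed physicochemical properties."""

    protein_id: str
    gene_id: str
    species: str
    sequence: str
    group_label: str | None = None
    length: int = field(init=False)
    mw: float = field(init=False)
    pi: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        self.length = len(self.sequence)
        self.mw = molecular_weight(self.sequence)
        self.pi = isoelectric_point(self.sequence)
        assert self.mw > 0 and 0.0 < self.pi < 14.0


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein, 1-based residue coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    bit_score: float
    i_evalue: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: domain start > end")


def filter_hits(
    rows: Iterable[DomTblRow],
    e_max: float = 1e-5,
    score_min: float = 0.0,
    use_domain_evalue: bool = False,
) -> list[DomTblRow]:
    """Keep hits with E-value <= ``e_max`` and score >= ``score_min``.

    Both comparisons are inclusive.  By default the full-sequence E-value
    is filtered; set ``use_domain_evalue`` to filter on the per-domain
    independent E-value instead.  Idempotent by construction.
    """
    if not (math.isfinite(e_max) and math.isfinite(score_min)):
        raise ValueError("thresholds must be finite")
    out = []
    for row in rows:
        ev = row.domain_ievalue if use_domain_evalue else row.full_seq_evalue
        if ev <= e_max and row.full_seq_score >= score_min:
            out.append(row)
    return out


def deduplicate(proteins: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """One representative isoform per gene: longest, ties by smallest id.

    Output order follows the first appearance of each gene.
    """
    by_gene: dict[str, list[ProteinRecord]] = {}
    for prot in proteins:
        if not prot.gene_id:
            raise ValueError(f"protein {prot.protein_id!r} has no gene_id")
        by_gene.setdefault(prot.gene_id, []).append(prot)
    return [
        min(group, key=lambda p: (-p.length, p.protein_id))
        for group in by_gene.values()
    ]


def domain_architecture(hits: Sequence[DomainHit]) -> str:
    """Ordered domain string for one protein, e.g. ``"DIX-PDZ-DEP"``.

    Domains are sorted by start coordinate; of two overlapping hits the
    one with the higher bit score wins.  No hits gives an empty string.
    """
    if not hits:
        return ""
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    accepted: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (-h.bit_score, h.start, h.end)):
        if all(hit.end < a.start or a.end < hit.start for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: h.start)
    return "-".join(h.domain_name for h in accepted)


# ---------------------------------------------------------------------------
# cross-species census and group statistics
# ---------------------------------------------------------------------------

@dataclass
class FamilyCensus:
    """Per-(species, family) gene counts with a group label per species."""

    counts: pd.DataFrame  # index: species, columns: families, values: int
    group_labels: dict[str, str]  # species -> group

    def group_means(self, family: str) -> dict[str, float]:
        """Arithmetic mean family size per species group."""
        means: dict[str, list[int]] = {}
        for species, group in self.group_labels.items():
            means.setdefault(group, []).append(int(self.counts.loc[species, family]))
        return {g: float(np.mean(v)) for g, v in means.items()}


def census(
    genes_by_species: Mapping[str, Mapping[str, Sequence[str]]],
    groups: Mapping[str, Sequence[str]],
) -> FamilyCensus:
    """Build a family census from per-species gene lists.

    ``genes_by_species`` maps species -> family -> gene ids; ``groups``
    maps a group label (e.g. ``vertebrate``) to its species.  A species
    listed under two groups is an error; a species with no hits for a
    family gets count 0 and still enters the group mean.
    """
    label_of: dict[str, str] = {}
    for group, members in groups.items():
        for sp in members:
            if sp in label_of:
                raise ValueError(f"species {sp!r} assigned to two groups")
            label_of[sp] = group
    families = sorted(
        {fam for fams in genes_by_species.values() for fam in fams}
    )
    species = list(label_of)
    data = {
        fam: [
            len(genes_by_species.get(sp, {}).get(fam, ())) for sp in species
        ]
        for fam in families
    }
    counts = pd.DataFrame(data, index=species, dtype=int)
    return FamilyCensus(counts, label_of)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    #: Dunnett-adjusted p-value for each non-control group vs the control.
    dunnett_p: dict[str, float]
    control: str


def compare_groups_anova(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
) -> AnovaResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons.

    ``control`` names the reference group (default: first key).  Each
    group needs at least 2 values.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = list(groups)
    if control is None:
        control = names[0]
    if control not in groups:
        raise ValueError(f"unknown control group {control!r}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    f_stat, p_val = stats.f_oneway(*arrays.values())
    if not np.isfinite(f_stat):  # all groups identical and constant
        f_stat, p_val = 0.0, 1.0
    treatments = [k for k in names if k != control]
    res = stats.dunnett(
        *(arrays[k] for k in treatments), control=arrays[control]
    )
    dunnett_p = {k: float(p) for k, p in zip(treatments, res.pvalue)}
    return AnovaResult(float(f_stat), float(p_val), dunnett_p, control)
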