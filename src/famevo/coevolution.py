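"""Mirror-tree co-evolution scoring between two protein families.

The co-evolution score of one member of family A against one member of
family B is the Pearson correlation between their inter-species
evolutionary distance matrices, restricted to the species both members
share and compared over the strict upper triangles.  Distances are
Poisson-corrected pairwise distances from each member's ortholog
alignment.  Pairs sharing fewer than a minimum number of species
(default 4) yield a missing value with a reason rather than a
meaningless correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .io_formats import AlignmentSet
from .phylo import pairwise_distance

DEFAULT_MIN_COMMON = 4


@dataclass(frozen=True)
class MirrorScore:
    """One Wnt-DIX-style pair score: r, shared-species count, or a reason."""

    r: float | None
    n_common: int
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.r is None


def mirror_correlation(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    min_common: int = DEFAULT_MIN_COMMON,
) -> MirrorScore:
    """Pearson correlation of two distance matrices over shared taxa.

    Both matrices are restricted to the taxa they share (in a canonical
    sorted order, so the score is invariant to input taxa ordering and
    symmetric in its arguments); r is computed over the n(n-1)/2 strict
    upper-triangle entries.  Fewer than ``min_common`` shared taxa gives
    a missing score; a constant triangle is an error.
    """
    common = sorted(set(dm_a.ids) & set(dm_b.ids))
    if len(common) < min_common:
        return MirrorScore(
            None,
            len(common),
            f"only {len(common)} common taxa (< {min_common})",
        )
    tri_a = dm_a.filter(common).condensed_form()
    tri_b = dm_b.filter(common).condensed_form()
    if np.ptp(tri_a) == 0 or np.ptp(tri_b) == 0:
        raise ValueError("constant distance triangle: correlation undefined")
    r = stats.pearsonr(tri_a, tri_b).statistic
    return MirrorScore(float(r), len(common))


@dataclass
class CoevolutionResult:
    """All cross-family mirror-tree scores between families A and B."""

    matrix: pd.DataFrame  # r values; NaN where missing
    n_common: pd.DataFrame  # shared-species counts per pair
    reasons: dict[tuple[str, str], str]  # missing pairs -> reason

    @property
    def n_pairs(self) -> int:
        return int(self.matrix.size)

    @property
    def n_missing(self) -> int:
        return int(self.matrix.isna().sum().sum())

    @property
    def mean_r(self) -> float:
        """Mean over non-missing coefficients."""
        return float(np.nanmean(self.matrix.to_numpy()))


def family_coevolution(
    alns_a: Mapping[str, AlignmentSet],
    alns_b: Mapping[str, AlignmentSet],
    model: str = "poisson",
    min_common: int = DEFAULT_MIN_COMMON,
) -> CoevolutionResult:
    """Mirror-tree scores for every cross-family member pair.

    Each member contributes the distance matrix of its ortholog
    alignment (taxa named by species).  A member whose alignment covers
    too few species makes its row/column missing; the run continues.
    """
    dms_a = {name: pairwise_distance(aln, model) for name, aln in alns_a.items()}
    dms_b = {name: pairwise_distance(aln, model) for name, aln in alns_b.items()}
    names_a = list(dms_a)
    names_b = list(dms_b)
    r_mat = pd.DataFrame(np.nan, index=names_a, columns=names_b, dtype=float)
    n_mat = pd.DataFrame(0, index=names_a, columns=names_b, dtype=int)
    reasons: dict[tuple[str, str], str] = {}
    for a in names_a:
        for b in names_b:
            score = mirror_correlation(dms_a[a], dms_b[b], min_common)
            n_mat.loc[a, b] = score.n_common
            if score.is_missing:
                reasons[(a, b)] = score.reason or "missing"
            else:
                r_mat.loc[a, b] = score.r
    return CoevolutionResult(r_mat, n_mat, reasons)
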