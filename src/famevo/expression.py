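"""Up/down/unchanged classification of genes from expression matrices.

Input matrices carry normalized log2 intensities (e.g. RMA output
consumed from upstream).  The classifier is fully specified rather than
a moderated-statistics fit: the log2 fold change is the case-group mean
minus the control-group mean, a gene is *up* when the fold change meets
``lfc_min`` (and, in ``welch`` mode, the Welch t-test p-value is below
``alpha``), *down* symmetrically, otherwise *unchanged*.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

CLASSES = ("up", "down", "unchanged")


@dataclass(frozen=True)
class DECall:
    """Differential-expression call for one gene."""

    gene_id: str
    log2fc: float
    p_value: float | None
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")


def classify_de(
    mat: ExpressionMatrix,
    group_case: str,
    group_control: str,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    mode: str = "fc_only",
    genes: Sequence[str] | None = None,
) -> list[DECall]:
    """Classify genes as up / down / unchanged between two sample groups.

    ``mode="fc_only"`` thresholds the fold change alone; ``mode="welch"``
    additionally requires the Welch two-sample t-test p-value below
    ``alpha`` (each group then needs >= 2 samples).  Unknown requested
    genes are skipped with a warning.  Swapping case and control flips
    up and down calls.
    """
    if mode not in ("fc_only", "welch"):
        raise ValueError(f"unknown mode {mode!r}")
    case = mat.samples_in(group_case)
    control = mat.samples_in(group_control)
    if not case or not control:
        missing = group_case if not case else group_control
        raise ValueError(f"group {missing!r} has no samples in the matrix")
    if set(case) & set(control):
        raise ValueError("case and control groups overlap")
    if mode == "welch" and (len(case) < 2 or len(control) < 2):
        raise ValueError("welch mode needs >= 2 samples per group")

    if genes is None:
        genes = list(mat.values.index)
    else:
        known = set(mat.values.index)
        unknown = [g for g in genes if g not in known]
        if unknown:
            warnings.warn(f"skipping unknown gene(s): {unknown}")
        genes = [g for g in genes if g in known]

    calls: list[DECall] = []
    for gene in genes:
        x = mat.values.loc[gene, case].to_numpy(dtype=float)
        y = mat.values.loc[gene, control].to_numpy(dtype=float)
        lfc = float(x.mean() - y.mean())
        p: float | None = None
        significant = True
        if mode == "welch":
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            significant = p < alpha
        if lfc >= lfc_min and significant:
            label = "up"
        elif lfc <= -lfc_min and significant:
            label = "down"
        else:
            label = "unchanged"
        calls.append(DECall(gene, lfc, p, label))
    return calls


def de_proportions(
    calls: Iterable[DECall] | Mapping[str, int],
) -> dict[str, float]:
    """Proportion of up / down / unchanged calls (fractions summing to 1).

    Accepts either a list of calls or precomputed per-class counts.
    """
    if isinstance(calls, Mapping):
        counts = {k: int(v) for k, v in calls.items()}
        bad = sorted(set(counts) - set(CLASSES))
        if bad:
            raise ValueError(f"unknown class label(s): {bad}")
    else:
        counts = Counter(c.label for c in calls)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no calls")
    return {cls: counts.get(cls, 0) / total for cls in CLASSES}


def heatmap_matrix(
    mat: ExpressionMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Row-scaled (z-scored) genes-by-samples matrix for heatmap export.

    Rows with zero variance become all-zero rather than NaN.
    """
    values = mat.values if genes is None else mat.values.loc[list(genes)]
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        (arr - mu) / sd, index=values.index, columns=values.columns
    )
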