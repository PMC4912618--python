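"""Gene-set signature scores and the two-sample tests used with them.

A signature score is the per-sample arithmetic mean of log2 expression
over the set's genes present in the matrix (with the covered fraction
reported).  Group comparisons use the two-tailed unequal-variance
Welch t-test and the exact Wilcoxon rank-sum test (exact enumeration
up to a configurable combined sample size, then the normal
approximation with continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "SignatureScores",
    "score_gene_set",
    "welch_t",
    "wilcoxon_exact",
    "EXACT_WILCOXON_LIMIT",
]

#: Combined sample size up to which the Wilcoxon test is computed exactly.
EXACT_WILCOXON_LIMIT = 50


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


@dataclass
class SignatureScores:
    set_name: str
    scores: pd.Series  # per-sample mean log2 expression over present genes
    coverage: float  # fraction of set genes present in the matrix


def score_gene_set(expr: ExpressionMatrix, gene_set: GeneSet) -> SignatureScores:
    """Mean log2 expression over the set's genes present in the matrix."""
    present = [g for g in gene_set.genes if g in expr.values.columns]
    if not present:
        raise ValueError(
            f"no gene of set {gene_set.name!r} is present in the matrix"
        )
    coverage = len(present) / len(gene_set.genes)
    if coverage < 1.0:
        logger.info(
            "gene set %s: %d/%d genes present",
            gene_set.name,
            len(present),
            len(gene_set.genes),
        )
    scores = expr.values[present].mean(axis=1)
    scores.name = gene_set.name
    return SignatureScores(set_name=gene_set.name, scores=scores, coverage=coverage)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed unequal-variance t-test (Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def wilcoxon_exact(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = EXACT_WILCOXON_LIMIT,
) -> float:
    """Two-sided Wilcoxon rank-sum p; exact when len(a)+len(b) <= limit.

    Above the limit, the normal approximation with continuity
    correction is used and a note is logged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    if len(a) + len(b) <= exact_limit:
        method = "exact"
    else:
        method = "asymptotic"
        logger.info(
            "Wilcoxon: combined n=%d exceeds exact limit %d; normal "
            "approximation with continuity correction used",
            len(a) + len(b),
            exact_limit,
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
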