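"""Cross-sample association statistics.

Four tools used throughout the analysis:

* percentile ranking of Spearman correlations — each focal gene's
  mutated-yes/no indicator is correlated with a per-sample target
  (MSI, metastasis, another gene's indicator, a signature score) and
  placed as a percentile within the distribution of the same
  correlation over a large background of mutated genes;
* pairwise two-sided Fisher exact tests of mutation co-occurrence;
* per-cell chi-square contribution flags for contingency tables
  (arrow annotations at p<0.05 / 0.01 / 0.001 per cell);
* trend tests across ordered groups (Cochran–Armitage for binary
  outcomes with equally spaced scores; score-on-outcome linear
  regression Wald test for continuous outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "MIN_BACKGROUND_MUTATIONS",
    "background_gene_indicators",
    "spearman_percentile",
    "pairwise_fisher",
    "CellFlagTable",
    "cell_chi2_flags",
    "trend_test",
]

#: Background for percentile ranking: genes with at least this many
#: non-silent mutations in the cohort.
MIN_BACKGROUND_MUTATIONS = 5

_FLAG_ALPHAS = (0.05, 0.01, 0.001)


def background_gene_indicators(
    mutations, sample_ids: Sequence[str], min_mutations: int = MIN_BACKGROUND_MUTATIONS
) -> pd.DataFrame:
    """Samples x genes 0/1 mutated-indicator matrix for background genes.

    A gene enters the background when it carries >= ``min_mutations``
    non-silent mutation events in the cohort.
    """
    events: dict[str, int] = {}
    mutated: dict[str, set[str]] = {}
    for m in mutations:
        if m.variant_class.is_silent:
            continue
        events[m.gene] = events.get(m.gene, 0) + 1
        mutated.setdefault(m.gene, set()).add(m.sample_id)
    genes = sorted(g for g, n in events.items() if n >= min_mutations)
    data = {
        g: [1 if s in mutated[g] else 0 for s in sample_ids] for g in genes
    }
    return pd.DataFrame(data, index=list(sample_ids), columns=genes)


def spearman_percentile(
    indicators: pd.DataFrame,
    target: pd.Series,
    focal_genes: Sequence[str],
) -> pd.DataFrame:
    """Percentile rank of each focal gene's Spearman r with ``target``.

    ``indicators`` is the background indicator matrix (focal genes must
    be columns of it); the percentile is the mid-rank of the focal
    gene's correlation within the background correlations, scaled to
    0-100.  Constant targets are an error.
    """
    target = target.reindex(indicators.index).astype(float)
    if target.nunique() < 2:
        raise ValueError("target is constant; Spearman correlation undefined")
    missing = [g for g in focal_genes if g not in indicators.columns]
    if missing:
        raise ValueError(f"focal gene(s) not in background: {missing}")
    t_rank = target.rank()
    r = indicators.rank().corrwith(t_rank)  # Spearman via rank-Pearson
    # Mid-rank percentile within the background distribution.
    pct = r.rank(method="average") / len(r) * 100.0
    out = pd.DataFrame(
        {"spearman_r": r.loc[list(focal_genes)], "percentile": pct.loc[list(focal_genes)]}
    )
    out.index.name = "gene"
    return out


def pairwise_fisher(
    indicators: Mapping[str, Sequence[int]] | pd.DataFrame,
    gene_pairs: Sequence[tuple[str, str]],
    condition: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Two-sided Fisher exact test for each pair of binary indicators.

    ``condition`` optionally restricts the samples (e.g. APC-mutated
    only).  An empty margin yields p=1 with odds ratio NaN.  Returns a
    frame with columns a/b (pair), p, odds_ratio, direction (+1 co-
    occurrence, -1 exclusivity, 0 empty margin).
    """
    ind = pd.DataFrame(indicators)
    if condition is not None:
        ind = ind.loc[np.asarray(condition, dtype=bool)]
    rows = []
    for ga, gb in gene_pairs:
        x = ind[ga].astype(int)
        y = ind[gb].astype(int)
        n11 = int(((x == 1) & (y == 1)).sum())
        n10 = int(((x == 1) & (y == 0)).sum())
        n01 = int(((x == 0) & (y == 1)).sum())
        n00 = int(((x == 0) & (y == 0)).sum())
        table = np.array([[n11, n10], [n01, n00]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            rows.append(
                {"a": ga, "b": gb, "p": 1.0, "odds_ratio": np.nan, "direction": 0}
            )
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        expected_11 = (n11 + n10) * (n11 + n01) / table.sum()
        rows.append(
            {
                "a": ga,
                "b": gb,
                "p": float(p),
                "odds_ratio": float(odds),
                "direction": int(np.sign(n11 - expected_11)) or 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CellFlagTable:
    """Contingency table with per-cell chi-square contribution flags.

    ``contribution[i,j]`` is (O-E)^2/E; ``level[i,j]`` is 0 (none) or
    1/2/3 for cell p < 0.05/0.01/0.001 against chi-square(1);
    ``direction`` is sign(O-E).  Cells with zero expectation carry
    level -1 (undefined).
    """

    observed: np.ndarray
    expected: np.ndarray
    contribution: np.ndarray
    level: np.ndarray
    direction: np.ndarray

    @property
    def chi2(self) -> float:
        return float(self.contribution[self.expected > 0].sum())

    def arrows(self) -> np.ndarray:
        """Human-readable annotation per cell, Table-style arrows."""
        out = np.empty(self.level.shape, dtype=object)
        for idx, lev in np.ndenumerate(self.level):
            if lev <= 0:
                out[idx] = ""
            else:
                out[idx] = ("↑" if self.direction[idx] > 0 else "↓") * lev
        return out


def cell_chi2_flags(
    table: np.ndarray, alphas: Sequence[float] = _FLAG_ALPHAS
) -> CellFlagTable:
    """Flag cells whose individual chi-square contribution is extreme.

    Expectations are the usual product-of-margins / total; each cell's
    (O-E)^2/E is referred to the chi-square(1) distribution at the
    given alpha levels.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2:
        raise ValueError("need a 2-D contingency table")
    total = observed.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        contribution = (observed - expected) ** 2 / expected
    cutoffs = [stats.chi2.ppf(1 - a, df=1) for a in alphas]
    level = np.zeros(observed.shape, dtype=int)
    for cut in cutoffs:  # ascending severity
        level += (np.nan_to_num(contribution) >= cut).astype(int)
    level[expected == 0] = -1
    direction = np.sign(observed - expected).astype(int)
    return CellFlagTable(
        observed=observed,
        expected=expected,
        contribution=np.where(expected > 0, contribution, np.nan),
        level=level,
        direction=direction,
    )


def trend_test(
    group_index: Sequence[int],
    outcome: Sequence[float],
    binary: Optional[bool] = None,
) -> float:
    """Trend p-value across ordered groups with scores 0..k-1.

    Binary outcomes use the Cochran–Armitage trend test (chi-square
    with 1 df); continuous outcomes use the Wald p of the slope in an
    ordinary linear regression of outcome on group score.  Groups are
    given as integer indices (order = score).
    """
    g = np.asarray(group_index, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(g)) < 2:
        raise ValueError("need >=2 non-empty groups for a trend test")
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        # Cochran-Armitage: z = sum(s_i (y_i - ybar)) / sqrt(pbar qbar Sss)
        n = len(y)
        pbar = y.mean()
        if pbar in (0.0, 1.0):
            return 1.0
        s_centered = g - g.mean()
        num = float((s_centered * y).sum())
        var = pbar * (1 - pbar) * float((s_centered**2).sum())
        chi2 = num**2 / var
        return float(stats.chi2.sf(chi2, df=1))
    X = sm.add_constant(g)
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[1])
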