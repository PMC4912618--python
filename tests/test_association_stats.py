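"""Percentile ranking, Fisher pairs, cell flags and trend tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcclass.association_stats import (
    background_gene_indicators,
    cell_chi2_flags,
    pairwise_fisher,
    spearman_percentile,
    trend_test,
)


def _indicator_frame(rng, n=200, n_genes=60):
    data = rng.random((n, n_genes)) < 0.2
    cols = [f"G{i}" for i in range(n_genes)]
    return pd.DataFrame(data.astype(int), columns=cols, index=[f"s{i}" for i in range(n)])


def test_percentile_extremes(rng):
    ind = _indicator_frame(rng)
    target = ind["G0"].astype(float)
    ind["MATCH"] = target.astype(int)
    ind["ANTI"] = 1 - target.astype(int)
    res = spearman_percentile(ind, target, ["MATCH", "ANTI"])
    assert res.loc["MATCH", "percentile"] == pytest.approx(100.0, abs=2)
    assert res.loc["ANTI", "percentile"] <= 5
    assert res.loc["MATCH", "spearman_r"] == pytest.approx(1.0)
    assert res.loc["ANTI", "spearman_r"] == pytest.approx(-1.0)


def test_percentile_constant_target_errors(rng):
    ind = _indicator_frame(rng)
    with pytest.raises(ValueError, match="constant"):
        spearman_percentile(ind, pd.Series(1.0, index=ind.index), ["G0"])


def test_percentile_monotone_transform_invariance(rng):
    ind = _indicator_frame(rng)
    target = pd.Series(rng.normal(size=len(ind)), index=ind.index)
    a = spearman_percentile(ind, target, ["G0", "G1"])
    b = spearman_percentile(ind, np.exp(3 * target), ["G0", "G1"])
    pd.testing.assert_frame_equal(a, b)


def test_percentile_direction_on_generated_couplings(default_cohort, default_calls):
    """BRAF rides with MSI, APC against it, as generated."""
    cohort, _ = default_cohort
    ind = background_gene_indicators(cohort.mutations, cohort.sample_ids)
    msi = pd.Series(
        {c.sample_id: int(c.msi_final == "MSI_H") for c in default_calls}
    )
    res = spearman_percentile(ind, msi, ["BRAF", "APC"])
    assert res.loc["BRAF", "percentile"] > 95
    assert res.loc["APC", "percentile"] < 5


def _fisher_enumeration(n11, n10, n01, n00):
    """Brute-force two-sided Fisher p over all tables with fixed margins."""
    r1, r2 = n11 + n10, n01 + n00
    c1 = n11 + n01
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )
    observed = prob(n11)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= observed * (1 + 1e-9))


def test_fisher_matches_enumeration_small_tables(rng):
    """Fisher p equals hypergeometric enumeration for all n<=30 tables tried."""
    for _ in range(200):
        cells = rng.integers(0, 8, size=4)
        if cells.sum() == 0 or cells.sum() > 30:
            continue
        n11, n10, n01, n00 = (int(c) for c in cells)
        if (n11 + n10) == 0 or (n01 + n00) == 0 or (n11 + n01) == 0 or (n10 + n00) == 0:
            continue
        p_scipy = stats.fisher_exact([[n11, n10], [n01, n00]])[1]
        p_enum = _fisher_enumeration(n11, n10, n01, n00)
        assert p_scipy == pytest.approx(p_enum, rel=1e-9)


def test_fisher_perfect_disjoint_table():
    # (10,0;0,10): two-sided p = 2/C(20,10)
    p = stats.fisher_exact([[10, 0], [0, 10]])[1]
    assert p == pytest.approx(2 / math.comb(20, 10))


def test_pairwise_fisher_calibration_and_extremes(rng):
    n = 468
    rejections = 0
    reps = 300
    for _ in range(reps):
        df = pd.DataFrame(
            {"a": (rng.random(n) < 0.3).astype(int), "b": (rng.random(n) < 0.4).astype(int)}
        )
        p = pairwise_fisher(df, [("a", "b")])["p"].iloc[0]
        rejections += p < 0.05
    assert rejections / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    co = pd.DataFrame({"a": [1] * 20 + [0] * 20, "b": [1] * 20 + [0] * 20})
    res = pairwise_fisher(co, [("a", "b")])
    assert res["p"].iloc[0] < 1e-10
    assert res["direction"].iloc[0] == 1

    empty = pd.DataFrame({"a": [0] * 10, "b": [1, 0] * 5})
    res = pairwise_fisher(empty, [("a", "b")])
    assert res["p"].iloc[0] == 1.0


def test_cell_flags_uniform_and_spiked():
    uniform = np.full((5, 2), 40.0)
    flags = cell_chi2_flags(uniform)
    assert (flags.level == 0).all()

    table = np.full((5, 2), 40.0)
    table[2, 0] = 120.0
    flags = cell_chi2_flags(table)
    assert flags.level[2, 0] >= 1
    assert flags.direction[2, 0] == 1
    assert flags.arrows()[2, 0].startswith("↑")


def test_cell_flags_sum_equals_pearson_chi2(rng):
    table = rng.integers(5, 60, size=(4, 3)).astype(float)
    flags = cell_chi2_flags(table)
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    assert flags.chi2 == pytest.approx(chi2)


def test_cell_flags_row_permutation_symmetry(rng):
    table = rng.integers(5, 60, size=(4, 3)).astype(float)
    perm = rng.permutation(4)
    a = cell_chi2_flags(table)
    b = cell_chi2_flags(table[perm])
    assert np.array_equal(a.level[perm], b.level)


def test_trend_calibration_uniform_null(rng):
    reps = 300
    rej = 0
    for _ in range(reps):
        g = rng.integers(0, 5, size=400)
        y = (rng.random(400) < 0.3).astype(float)
        rej += trend_test(g, y) < 0.05
    assert abs(rej / reps - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / reps)


def test_trend_power_monotone_proportions(rng):
    g = np.repeat(np.arange(5), 80)
    probs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])[g]
    y = (rng.random(400) < probs).astype(float)
    assert trend_test(g, y) < 0.001


def test_trend_two_groups_matches_chi2_trend(rng):
    g = np.repeat([0, 1], 100)
    y = np.concatenate([(rng.random(100) < 0.2), (rng.random(100) < 0.5)]).astype(float)
    p = trend_test(g, y)
    # two groups: CA trend == 2x2 Pearson chi-square (no correction)
    table = np.array(
        [
            [(y[g == 0] == 1).sum(), (y[g == 0] == 0).sum()],
            [(y[g == 1] == 1).sum(), (y[g == 1] == 0).sum()],
        ]
    )
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-6)


def test_trend_continuous_outcome(rng):
    g = np.repeat(np.arange(5), 50)
    age = 60 + 2.0 * g + rng.normal(0, 8, size=250)
    assert trend_test(g, age, binary=False) < 0.01
    with pytest.raises(ValueError):
        trend_test(np.zeros(10), np.ones(10))
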