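"""Mutation-rate formula, robust-regression outlier scan, reference check."""

import numpy as np
import pytest
from scipy import stats

from crcclass.cohort_io import GeneCatalog
from crcclass.smg_detection import (
    compare_rates_to_reference,
    mutation_rate,
    nonsilent_counts,
    robust_fit,
)


@pytest.mark.parametrize(
    "n,aa,expected",
    [
        (192, 189, 72.4),
        (292, 393, 52.9),
        (494, 2843, 12.4),
        (59, 552, 7.6),
        (61, 766, 5.7),
    ],
)
def test_rate_formula_published_rows(n, aa, expected):
    assert mutation_rate(n, aa, 468) == pytest.approx(expected, abs=0.05)


def test_rate_formula_direct_evaluation():
    assert mutation_rate(10, 100, 468) == pytest.approx(1e5 * 10 / 140400)
    assert mutation_rate(0, 123, 468) == 0.0
    with pytest.raises(ValueError):
        mutation_rate(1, 0, 468)


def test_rate_linear_in_n_inverse_in_length(rng):
    n = int(rng.integers(1, 500))
    aa = int(rng.integers(100, 5000))
    assert mutation_rate(2 * n, aa, 468) == pytest.approx(2 * mutation_rate(n, aa, 468))
    assert mutation_rate(n, 2 * aa, 468) == pytest.approx(mutation_rate(n, aa, 468) / 2)


def _null_catalog_counts(rng, n_genes=1000, per_base=1.4e-5, n_samples=468):
    """Cohort-level null: per-gene event counts ~ Poisson(rate * 3L * n)."""
    lengths = np.clip(rng.lognormal(np.log(450), 0.85, n_genes), 100, 35000).astype(int)
    catalog = GeneCatalog({f"G{i}": int(L) for i, L in enumerate(lengths)})
    lam = per_base * 3 * lengths * n_samples
    counts = {f"G{i}": int(rng.poisson(lam[i])) for i in range(n_genes)}
    return catalog, counts, lengths


def test_robust_fit_recovers_null_line_and_flags_spikes(rng):
    catalog, counts, lengths = _null_catalog_counts(rng)
    spiked = rng.choice(1000, size=15, replace=False)
    for i in spiked:
        counts[f"G{i}"] = int(counts[f"G{i}"] * 20 + 30)
    fit = robust_fit(counts, catalog)
    z = dict(zip(counts, fit.z))
    order = sorted(counts, key=lambda g: -z[g])
    top15 = {order[i] for i in range(15)}
    assert top15 == {f"G{i}" for i in spiked}
    # false positives among null genes stay a small z>=3 tail (the
    # length-only model is heteroscedastic, so the tail exceeds the
    # Gaussian 0.13% but remains far below the spiked signal)
    null_genes = [g for g in counts if g not in top15]
    fp = sum(1 for g in null_genes if z[g] >= 3)
    assert fp / len(null_genes) <= 0.04


def test_robust_fit_gene_on_line_has_small_z(rng):
    catalog, counts, lengths = _null_catalog_counts(rng)
    fit = robust_fit(counts, catalog)
    g = "G0"
    on_line = int(round(fit.intercept + fit.slope * catalog[g]))
    counts[g] = max(on_line, 0)
    refit = robust_fit(counts, catalog)
    assert abs(refit.z[0]) < 1.0


def test_robust_fit_duplication_invariance(rng):
    catalog, counts, _ = _null_catalog_counts(rng, n_genes=400)
    fit = robust_fit(counts, catalog)
    doubled_catalog = GeneCatalog(
        {**catalog.aa_length, **{f"D_{g}": catalog[g] for g in counts}}
    )
    doubled_counts = {**counts, **{f"D_{g}": c for g, c in counts.items()}}
    refit = robust_fit(doubled_counts, doubled_catalog)
    assert refit.slope == pytest.approx(fit.slope, rel=0.02)
    assert refit.scale == pytest.approx(fit.scale, rel=0.05)


def test_robust_fit_resists_single_extreme_gene(rng):
    """One 100-fold inflated gene moves the slope by <5%."""
    catalog, counts, _ = _null_catalog_counts(rng)
    fit = robust_fit(counts, catalog)
    poisoned = dict(counts)
    poisoned["G5"] = counts["G5"] * 100 + 100
    refit = robust_fit(poisoned, catalog)
    assert refit.slope == pytest.approx(fit.slope, rel=0.05)


def test_robust_fit_degenerate_inputs():
    catalog = GeneCatalog({f"G{i}": 500 for i in range(40)})
    counts = {f"G{i}": i for i in range(40)}
    with pytest.raises(ValueError, match="aa_length"):
        robust_fit(counts, catalog)
    with pytest.raises(ValueError, match=">=30"):
        robust_fit({"G1": 2}, GeneCatalog({"G1": 100}))


def test_nonsilent_counts_events_not_samples(default_cohort, default_calls):
    cohort, truth = default_cohort
    msi_by = {c.sample_id: c.msi_final for c in default_calls}
    counts = nonsilent_counts(cohort, "overall", msi_by)
    # KRAS was generated as one event per KRAS-mutated sample
    assert counts["KRAS"] == int(truth["true_kras"].sum())
    # APC events exceed APC-mutated samples (multi-hit tumours)
    n_apc_samples = int((truth["true_apc_count"] >= 1).sum())
    assert counts["APC"] == int(truth["true_apc_count"].sum()) > n_apc_samples
    msi_counts = nonsilent_counts(cohort, "MSI", msi_by)
    mss_counts = nonsilent_counts(cohort, "MSS", msi_by)
    for g in ("KRAS", "APC", "TP53"):
        assert msi_counts[g] + mss_counts[g] == counts[g]


def test_nonsilent_counts_silent_excluded_and_catalog_errors(default_cohort):
    cohort, _ = default_cohort
    counts = nonsilent_counts(cohort)
    silent_genes = {
        m.gene for m in cohort.mutations if m.variant_class.is_silent
    }
    assert all(g in counts for g in silent_genes)
    from crcclass.cohort_io import Cohort

    broken = Cohort(
        mutations=cohort.mutations,
        clinical=cohort.clinical,
        catalog=GeneCatalog({"APC": 2843}),
    )
    with pytest.raises(ValueError, match="catalog"):
        nonsilent_counts(broken)


def test_reference_comparison_fisher():
    from crcclass.smg_detection import SmgRow

    rows = [
        SmgRow("SAME", 50, 500, 1.0),
        SmgRow("DISC", 102, 500, 1.0),
        SmgRow("MISSING", 10, 500, 1.0),
    ]
    ours = {"SAME": 50, "DISC": 102, "MISSING": 10}
    ref = {"SAME": 24, "DISC": 2}  # SAME: 24/224 ~ 50/468
    res = compare_rates_to_reference(rows, ours, 468, ref, 224)
    p_same, disc_same = res["SAME"]
    assert p_same > 0.9 and disc_same is False
    p_disc, disc_disc = res["DISC"]
    # oracle: hypergeometric tail for 102/468 vs 2/224
    oracle_p = stats.fisher_exact([[102, 366], [2, 222]])[1]
    assert p_disc == pytest.approx(oracle_p)
    assert p_disc < 1e-4 and disc_disc is True
    assert res["MISSING"] == (None, None)
    assert rows[2].discordant_vs_reference is None
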