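"""Zone partition, loss inference, Poisson GOF and zone pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcclass.apc_profile import (
    ApcProfile,
    assign_zone,
    build_apc_profile,
    count_hits_with_cn,
    infer_allelic_loss,
    poisson_gof,
    poisson_gof_from_counts,
    zone_pairing_test,
)
from crcclass.cohort_io import MutationRecord, VariantClass
from crcclass.functional_calls import DriverCalls


@pytest.mark.parametrize(
    "codon,zone",
    [(1, 1), (218, 1), (219, 2), (1262, 2), (1263, 3), (1300, 3), (1587, 3), (1588, 4), (2843, 4)],
)
def test_zone_boundaries(codon, zone):
    assert assign_zone(codon) == zone


def test_zone_out_of_range():
    for codon in (0, 2844, -5):
        with pytest.raises(ValueError, match="2843"):
            assign_zone(codon)


@given(st.integers(min_value=1, max_value=2843))
@settings(max_examples=500, deadline=None, derandomize=True)
def test_zone_partition_total_and_disjoint(codon):
    zones = [z for z, (lo, hi) in ((1, (1, 218)), (2, (219, 1262)), (3, (1263, 1587)), (4, (1588, 2843))) if lo <= codon <= hi]
    assert len(zones) == 1
    assert assign_zone(codon) == zones[0]


def _trunc(sid, codon, vaf=None, canonical=True, vc=VariantClass.STOPGAIN):
    return MutationRecord(
        sid, "APC", vc, codon=codon, alt_read_fraction=vaf, is_canonical_isoform=canonical
    )


def test_allelic_loss_threshold():
    assert infer_allelic_loss([_trunc("s", 100, 0.55)]) is True
    assert infer_allelic_loss([_trunc("s", 100, 0.50)]) is True  # inclusive
    assert infer_allelic_loss([_trunc("s", 100, 0.30)]) is False
    assert infer_allelic_loss([_trunc("s", 100, None)]) is False
    assert infer_allelic_loss([]) is False


def test_build_profile_zone_counts_and_groups():
    calls = DriverCalls(sample_id="s")
    recs = [_trunc("s", 302, 0.3), _trunc("s", 1450, 0.4)]
    prof = build_apc_profile(calls, recs)
    assert prof.zone_counts == (0, 1, 1, 0)
    assert prof.wnt_group == "two_plus_mut"
    assert prof.n_trunc == 2 and prof.n_trunc_capped == 2

    one_loss = build_apc_profile(calls, [_trunc("s", 1300, 0.6)])
    assert one_loss.wnt_group == "one_mut_loss"
    one = build_apc_profile(calls, [_trunc("s", 1300, 0.3)])
    assert one.wnt_group == "one_mut"
    wt = build_apc_profile(calls, [])
    assert wt.wnt_group == "wt" and wt.n_trunc == 0


def test_noncanonical_truncation_excluded_from_zones():
    calls = DriverCalls(sample_id="s", apc_noncanonical_trunc=1)
    recs = [_trunc("s", 1450, 0.3), _trunc("s", 900, 0.3, canonical=False)]
    prof = build_apc_profile(calls, recs)
    assert prof.n_trunc == 1
    assert prof.noncanonical_events == 1


def test_profile_invariant_to_record_order(rng):
    calls = DriverCalls(sample_id="s")
    recs = [_trunc("s", c, v) for c, v in [(100, 0.2), (400, 0.6), (1400, 0.3)]]
    base = build_apc_profile(calls, recs)
    for _ in range(5):
        perm = [recs[i] for i in rng.permutation(3)]
        assert build_apc_profile(calls, perm) == base


def test_cap_rule_three_truncations():
    calls = DriverCalls(sample_id="s")
    prof = build_apc_profile(calls, [_trunc("s", c, 0.3) for c in (100, 400, 1400)])
    assert prof.n_trunc == 3 and prof.n_trunc_capped == 2


def _profiles_from_counts(counts, rng=None):
    rng = rng or np.random.default_rng(0)
    out = []
    for i, k in enumerate(counts):
        zones = [0, 0, 0, 0]
        for _ in range(k):
            zones[int(rng.choice(4, p=[0.01, 0.40, 0.58, 0.01]))] += 1
        out.append(ApcProfile(sample_id=f"s{i}", zone_counts=tuple(zones)))
    return out


def test_poisson_gof_calibration(rng):
    """On true Poisson data the GOF p-value rejects at ~nominal rate."""
    rejections = 0
    reps = 200
    for _ in range(reps):
        counts = rng.poisson(0.8, size=468)
        if len(np.unique(counts)) < 3:
            continue
        res = poisson_gof_from_counts(counts)
        rejections += res.p < 0.05
    # binomial 3-sigma band around 5%
    assert rejections / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def test_poisson_gof_rejects_two_hit_excess():
    counts = np.concatenate(
        [np.zeros(156), np.ones(187), np.full(120, 2), np.full(5, 3)]
    ).astype(int)
    res = poisson_gof_from_counts(counts)
    assert res.p < 1e-6
    assert res.observed.sum() == 468
    assert abs(res.expected.sum() - 468) < 1e-6


def test_poisson_gof_degenerate():
    with pytest.raises(ValueError):
        poisson_gof_from_counts(np.ones(100, dtype=int))


def test_zone_pairing_null_calibration(rng):
    """Independent zone draws give a roughly uniform pairing p-value."""
    pvals = []
    for _ in range(200):
        counts = rng.choice([0, 1, 2], size=300, p=[0.3, 0.4, 0.3])
        profs = _profiles_from_counts(counts, rng)
        pvals.append(zone_pairing_test(profs).p)
    pvals = np.array(pvals)
    assert 0.01 <= (pvals < 0.05).mean() <= 0.10


def test_zone_pairing_detects_forced_pairing(rng):
    profs = []
    # 100 tumours forced to pair one zone-2 hit with one zone-3 hit,
    # against a marginal that is mostly zone 3
    for i in range(100):
        profs.append(ApcProfile(sample_id=f"t{i}", zone_counts=(0, 1, 1, 0)))
    for i in range(200):
        profs.append(ApcProfile(sample_id=f"o{i}", zone_counts=(0, 0, 1, 0)))
    res = zone_pairing_test(profs)
    assert res.p < 1e-6
    assert res.observed[2] == 100  # all one-each


def test_zone_pairing_needs_enough_tumours():
    profs = _profiles_from_counts([2, 2, 1, 0])
    with pytest.raises(ValueError, match=">=5"):
        zone_pairing_test(profs)


@pytest.mark.parametrize("trunc,dels,hits", [(1, 1, 2), (0, 0, 0), (3, 0, 2), (1, 0, 1), (0, 5, 2)])
def test_hit_counting_with_cn(trunc, dels, hits):
    assert count_hits_with_cn("s", trunc, dels).hits == hits


def test_gof_type_one_error_default_cohort_size(rng):
    """Type-I error stays near nominal at the study's cohort size."""
    reps = 300
    rej = 0
    used = 0
    for _ in range(reps):
        counts = rng.poisson(0.9, size=468)
        if len(np.unique(counts)) < 3:
            continue
        used += 1
        rej += poisson_gof_from_counts(counts).p < 0.05
    assert rej / used <= 0.06
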