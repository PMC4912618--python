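"""APC truncation zones, two-hit profiles and the biallelic-inactivation tests.

The APC protein (canonical isoform, 2,843 aa) is partitioned into four
zones by truncation density: zone 1 (codons 1-218), zone 2 (219-1,262),
zone 3 (1,263-1,587; the mutation cluster region) and zone 4
(1,588-2,843).  Allelic loss of the wild-type copy is inferred when any
truncating event has a variant allele fraction >= 0.50.  Two statistics
probe the two-hit model: a chi-square goodness-of-fit of the per-sample
truncation counts against a Poisson law (biallelic selection produces an
excess of exactly-two-hit tumours), and a test of whether two-hit
tumours pair one early-zone with one late-zone mutation more often than
independent draws from the marginal zone distribution would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_io import MutationRecord
from .functional_calls import DriverCalls, FunctionalCall, call_functional

logger = logging.getLogger(__name__)

__all__ = [
    "APC_CANONICAL_LENGTH",
    "ZONE_BOUNDS",
    "ALLELIC_LOSS_VAF",
    "ApcProfile",
    "PoissonGofResult",
    "ZonePairingResult",
    "HitCount",
    "assign_zone",
    "infer_allelic_loss",
    "build_apc_profile",
    "poisson_gof",
    "zone_pairing_test",
    "count_hits_with_cn",
]

#: Length of the canonical APC isoform (NM_0001127511) in amino acids.
APC_CANONICAL_LENGTH = 2843

#: Inclusive codon ranges of the four truncation zones.
ZONE_BOUNDS = {1: (1, 218), 2: (219, 1262), 3: (1263, 1587), 4: (1588, 2843)}

#: VAF at or above which a truncating event implies loss of the wild-type
#: allele (loss of heterozygosity and/or somatic recombination; the two
#: cannot be distinguished from read fractions).
ALLELIC_LOSS_VAF = 0.50


@dataclass
class ApcProfile:
    """Per-sample APC truncation profile."""

    sample_id: str
    zone_counts: tuple[int, int, int, int] = (0, 0, 0, 0)
    allelic_loss: bool = False
    wnt_group: str = "wt"  # wt | one_mut | one_mut_loss | two_plus_mut
    noncanonical_events: int = 0

    @property
    def n_trunc(self) -> int:
        return sum(self.zone_counts)

    @property
    def n_trunc_capped(self) -> int:
        """Classification-facing count: 2 means "2 or more"."""
        return min(self.n_trunc, 2)


@dataclass
class PoissonGofResult:
    lambda_hat: float
    bin_labels: list[str]
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass
class ZonePairingResult:
    """Pairing pattern of the two hits in two-hit tumours.

    Categories: both hits in zones 1-2, both in zones 3-4, or one from
    each half.  Expectations come from independent draws of both hits
    from the marginal zone-half distribution among ALL truncations.
    """

    observed: np.ndarray  # (both_12, both_34, one_each)
    expected: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass
class HitCount:
    sample_id: str
    n_truncating: int
    n_cn_deletions: int

    @property
    def hits(self) -> int:
        return min(self.n_truncating + self.n_cn_deletions, 2)


def assign_zone(codon: int) -> int:
    """Zone (1-4) of a canonical-isoform codon; out of range is an error."""
    if not 1 <= codon <= APC_CANONICAL_LENGTH:
        raise ValueError(
            f"codon {codon} outside the canonical APC protein "
            f"(1-{APC_CANONICAL_LENGTH})"
        )
    for zone, (lo, hi) in ZONE_BOUNDS.items():
        if lo <= codon <= hi:
            return zone
    raise AssertionError("unreachable: zones partition 1..2843")


def infer_allelic_loss(
    trunc_records: Sequence[MutationRecord],
    vaf_threshold: float = ALLELIC_LOSS_VAF,
) -> bool:
    """True iff any truncating event has alt_read_fraction >= threshold.

    Events without a read fraction contribute nothing (no inference).
    """
    return any(
        r.alt_read_fraction is not None and r.alt_read_fraction >= vaf_threshold
        for r in trunc_records
    )


def build_apc_profile(
    calls: DriverCalls,
    records: Sequence[MutationRecord],
    vaf_threshold: float = ALLELIC_LOSS_VAF,
) -> ApcProfile:
    """Zone counts, inferred loss and WNT group for one sample.

    Only canonical-isoform truncations enter the zone counts; variant-
    isoform truncations are tallied in ``noncanonical_events``.  The
    WNT group consults allelic loss only for one-truncation tumours
    (loss in multi-hit tumours is recorded but the group stays
    ``two_plus_mut``).
    """
    apc_trunc = [
        r
        for r in records
        if r.sample_id == calls.sample_id
        and call_functional(r) is FunctionalCall.APC_TRUNCATING
    ]
    zone_counts = [0, 0, 0, 0]
    for r in apc_trunc:
        if r.codon is None:
            logger.warning(
                "APC truncation without codon in %s ignored in zone counts",
                calls.sample_id,
            )
            continue
        zone_counts[assign_zone(r.codon) - 1] += 1
    loss = infer_allelic_loss(apc_trunc, vaf_threshold)
    n_trunc = sum(zone_counts)
    if n_trunc == 0:
        group = "wt"
    elif n_trunc == 1:
        group = "one_mut_loss" if loss else "one_mut"
    else:
        group = "two_plus_mut"
    return ApcProfile(
        sample_id=calls.sample_id,
        zone_counts=tuple(zone_counts),
        allelic_loss=loss,
        wnt_group=group,
        noncanonical_events=calls.apc_noncanonical_trunc,
    )


def poisson_gof(profiles: Sequence[ApcProfile]) -> PoissonGofResult:
    """Chi-square goodness of fit of truncation counts to Poisson.

    Bins {0, 1, 2, >=3}; the Poisson mean is the MLE over all tumours
    (including zero-count ones); df = bins - 2 (one estimated
    parameter).  Expected bins below 1 are merged into their neighbour.
    """
    counts = np.array([p.n_trunc for p in profiles])
    return poisson_gof_from_counts(counts)


def poisson_gof_from_counts(counts: np.ndarray) -> PoissonGofResult:
    counts = np.asarray(counts)
    if len(np.unique(counts)) < 3:
        raise ValueError("need >=3 distinct truncation counts for the GOF test")
    n = counts.size
    lam = counts.mean()
    observed = np.array(
        [(counts == 0).sum(), (counts == 1).sum(), (counts == 2).sum(), (counts >= 3).sum()],
        dtype=float,
    )
    pm = stats.poisson.pmf([0, 1, 2], lam)
    probs = np.append(pm, 1.0 - pm.sum())
    expected = n * probs
    labels = ["0", "1", "2", ">=3"]
    # Merge tail bins whose expectation is below 1 into the neighbour.
    while len(expected) > 3 and expected[-1] < 1.0:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        labels[-2] = labels[-2] + "+" + labels[-1]
        expected, observed, labels = expected[:-1], observed[:-1], labels[:-1]
    df = len(observed) - 2
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df))
    return PoissonGofResult(
        lambda_hat=float(lam),
        bin_labels=labels,
        observed=observed,
        expected=expected,
        chi2=chi2,
        df=df,
        p=p,
    )


def zone_pairing_test(profiles: Sequence[ApcProfile]) -> ZonePairingResult:
    """Do two-hit tumours pair one zone-1-2 hit with one zone-3-4 hit?

    Uses samples with exactly two canonical truncations.  The marginal
    probability of a hit falling in zones 1-2 is estimated from ALL
    truncations across the input profiles; the chi-square compares the
    (both-early, both-late, one-each) pattern counts with independent
    pairing, df = 2.
    """
    all_zone_mass = np.zeros(4)
    for p in profiles:
        all_zone_mass += np.asarray(p.zone_counts)
    total = all_zone_mass.sum()
    if total == 0:
        raise ValueError("no truncations in input profiles")
    p_early = (all_zone_mass[0] + all_zone_mass[1]) / total

    two_hit = [p for p in profiles if p.n_trunc == 2]
    if len(two_hit) < 5:
        raise ValueError(
            f"need >=5 two-hit tumours for the pairing test, got {len(two_hit)}"
        )
    observed = np.zeros(3)
    for p in two_hit:
        early = p.zone_counts[0] + p.zone_counts[1]
        if early == 2:
            observed[0] += 1
        elif early == 0:
            observed[1] += 1
        else:
            observed[2] += 1
    n = len(two_hit)
    q = 1.0 - p_early
    expected = n * np.array([p_early**2, q**2, 2 * p_early * q])
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = (observed - expected) ** 2 / expected
    chi2 = float(np.nansum(cells[expected > 0]))
    df = 2
    p_val = float(stats.chi2.sf(chi2, df))
    return ZonePairingResult(
        observed=observed, expected=expected, chi2=chi2, df=df, p=p_val
    )


def count_hits_with_cn(
    sample_id: str, trunc_count: int, cn_deletion_count: int
) -> HitCount:
    """Two-hit bookkeeping when copy-number deletions are available."""
    if trunc_count < 0 or cn_deletion_count < 0:
        raise ValueError("counts must be >=0")
    return HitCount(
        sample_id=sample_id,
        n_truncating=trunc_count,
        n_cn_deletions=cn_deletion_count,
    )
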