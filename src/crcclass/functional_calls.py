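"""Per-sample functional driver calls and the MSI indel proxy.

Only two genes get a restricted functional definition: APC counts only
truncating events (stopgain or frameshift) on the canonical isoform,
and BRAF counts only the V600E hotspot missense.  KRAS and TP53 use any
non-silent mutation.  Microsatellite instability (MSI) is called by a
proxy: a tumour is MSI-high iff it carries homopolymer-region indels in
BOTH TGFBR2 and ACVR2A; an assay label, when available, takes
precedence over the proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .cohort_io import Cohort, MutationRecord, VariantClass

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalCall",
    "DriverCalls",
    "filter_germline",
    "call_functional",
    "msi_proxy_call",
    "driver_profile",
    "DEFAULT_MAX_POP_FREQ",
    "DEFAULT_HOMOPOLYMER_MIN_RUN",
]

#: Germline-suspect filter: population frequency above this removes a record.
DEFAULT_MAX_POP_FREQ = 0.01
#: Minimum reference homopolymer length for an indel to count as a
#: homopolymer-region event (the proxy's unit of evidence).
DEFAULT_HOMOPOLYMER_MIN_RUN = 6

_MSI_PROXY_GENES = ("TGFBR2", "ACVR2A")


class FunctionalCall(str, Enum):
    APC_TRUNCATING = "apc_truncating"
    NONCANONICAL_APC_TRUNCATING = "noncanonical_apc_truncating"
    BRAF_V600E = "braf_v600e"
    GENERIC_NONSILENT = "generic_nonsilent"
    SILENT = "silent"


@dataclass
class DriverCalls:
    """Functional driver status of one sample."""

    sample_id: str
    apc_trunc_positions: list[int] = field(default_factory=list)
    apc_noncanonical_trunc: int = 0
    kras_mut: bool = False
    tp53_mut: bool = False
    braf_v600e: bool = False
    tgfbr2_hp_indel: bool = False
    acvr2a_hp_indel: bool = False
    msi_proxy: str = "MSS"
    msi_final: str = "MSS"

    @property
    def apc_trunc_count(self) -> int:
        return len(self.apc_trunc_positions)

    @property
    def is_msi(self) -> bool:
        return self.msi_final == "MSI_H"


def filter_germline(
    records: Sequence[MutationRecord],
    max_pop_freq: float = DEFAULT_MAX_POP_FREQ,
) -> tuple[list[MutationRecord], int]:
    """Drop germline-suspect records; return (kept, n_removed).

    A record is removed when its population frequency exceeds
    ``max_pop_freq`` or it was seen in the panel of normals.  Records
    without a frequency annotation pass through.
    """
    kept = [
        r
        for r in records
        if not r.normal_panel_hit
        and (r.population_frequency is None or r.population_frequency <= max_pop_freq)
    ]
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info("germline filter removed %d record(s)", n_removed)
    return kept, n_removed


def call_functional(record: MutationRecord) -> FunctionalCall:
    """Classify one record's functional role.

    APC: truncating (stopgain/frameshift) on the canonical isoform;
    truncations on a variant isoform are reported separately and do not
    enter the truncation count.  BRAF: codon-600 missense (V600E).
    Splice variants are generic non-silent — they are not counted as
    truncating.
    """
    if record.variant_class.is_silent:
        return FunctionalCall.SILENT
    if record.gene == "APC" and record.variant_class.is_truncating:
        if record.is_canonical_isoform:
            return FunctionalCall.APC_TRUNCATING
        return FunctionalCall.NONCANONICAL_APC_TRUNCATING
    if (
        record.gene == "BRAF"
        and record.variant_class is VariantClass.MISSENSE
        and record.codon == 600
    ):
        return FunctionalCall.BRAF_V600E
    return FunctionalCall.GENERIC_NONSILENT


def _has_hp_indel(
    records: Sequence[MutationRecord], gene: str, min_run: int
) -> bool:
    return any(
        r.gene == gene
        and r.variant_class
        in (VariantClass.FRAMESHIFT_INDEL, VariantClass.INFRAME_INDEL)
        and r.homopolymer_run >= min_run
        for r in records
    )


def msi_proxy_call(
    sample_records: Sequence[MutationRecord],
    homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN,
) -> str:
    """MSI_H iff BOTH TGFBR2 and ACVR2A carry a homopolymer-region indel."""
    both = all(
        _has_hp_indel(sample_records, g, homopolymer_min_run)
        for g in _MSI_PROXY_GENES
    )
    return "MSI_H" if both else "MSS"


def driver_profile(
    cohort: Cohort,
    homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN,
) -> list[DriverCalls]:
    """One :class:`DriverCalls` per sample (in clinical-table order).

    ``msi_final`` prefers the assay label when the clinical record has
    one; proxy/assay discordances are logged.
    """
    by_sample = cohort.mutations_by_sample()
    out: list[DriverCalls] = []
    n_discord = 0
    for clin in cohort.clinical:
        recs = by_sample.get(clin.sample_id, [])
        calls = DriverCalls(sample_id=clin.sample_id)
        for r in recs:
            fc = call_functional(r)
            if fc is FunctionalCall.APC_TRUNCATING:
                if r.codon is None:
                    logger.warning(
                        "APC truncation without codon in %s; excluded from "
                        "positional analyses but counted",
                        clin.sample_id,
                    )
                calls.apc_trunc_positions.append(r.codon if r.codon else 0)
            elif fc is FunctionalCall.NONCANONICAL_APC_TRUNCATING:
                calls.apc_noncanonical_trunc += 1
            elif fc is FunctionalCall.BRAF_V600E:
                calls.braf_v600e = True
            if r.gene == "KRAS" and r.variant_class.is_nonsilent:
                calls.kras_mut = True
            if r.gene == "TP53" and r.variant_class.is_nonsilent:
                calls.tp53_mut = True
        calls.apc_trunc_positions.sort()
        calls.tgfbr2_hp_indel = _has_hp_indel(recs, "TGFBR2", homopolymer_min_run)
        calls.acvr2a_hp_indel = _has_hp_indel(recs, "ACVR2A", homopolymer_min_run)
        calls.msi_proxy = msi_proxy_call(recs, homopolymer_min_run)
        calls.msi_final = clin.msi_label if clin.msi_label else calls.msi_proxy
        if clin.msi_label and clin.msi_label != calls.msi_proxy:
            n_discord += 1
        out.append(calls)
    if n_discord:
        logger.info("MSI assay/proxy discordant in %d sample(s)", n_discord)
    return out
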