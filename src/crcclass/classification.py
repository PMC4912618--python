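"""Driver-combination classifications.

Two schemes are produced from the per-sample driver calls:

* a 10-group classification over the four drivers — A (APC truncated),
  K (KRAS), P (TP53) and B (BRAF V600E) — with labels
  WT, B, BP, K, P, KP, A, AK, AP, AKP;
* a five-class prognostic scheme for microsatellite-stable (MSS)
  tumours combining the capped APC truncation count (1 vs 2+) with
  whether both partnering drivers KRAS and TP53 are mutated:

      C0: APC wild type
      C1: APC(1) without both KRAS and TP53
      C2: APC(2+) without both KRAS and TP53
      C3: APC(1)/KRAS/TP53
      C4: APC(2+)/KRAS/TP53

BRAF-positive samples without APC/KRAS map to B (BP with TP53); a rare
sample carrying BRAF together with A or K is assigned by its A/K/P
combination, with the BRAF flag reported alongside (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .apc_profile import ApcProfile
from .functional_calls import DriverCalls

__all__ = [
    "TEN_GROUPS",
    "FIVE_CLASSES",
    "assign_ten_group",
    "assign_five_class",
    "classify_cohort",
    "CohortLabels",
]

TEN_GROUPS = ("WT", "B", "BP", "K", "P", "KP", "A", "AK", "AP", "AKP")
FIVE_CLASSES = ("C0", "C1", "C2", "C3", "C4")


def assign_ten_group(calls: DriverCalls, braf_dominant: bool = False) -> str:
    """10-group label from the driver flags.

    With the default precedence, BRAF defines the B/BP groups only when
    neither APC nor KRAS is mutated; ``braf_dominant=True`` sends every
    BRAF-V600E sample to B/BP regardless.
    """
    a = calls.apc_trunc_count >= 1
    k = calls.kras_mut
    p = calls.tp53_mut
    if calls.braf_v600e and (braf_dominant or not (a or k)):
        return "BP" if p else "B"
    label = ("A" if a else "") + ("K" if k else "") + ("P" if p else "")
    return label or "WT"


def assign_five_class(calls: DriverCalls, profile: ApcProfile) -> str:
    """Five-class label for one MSS sample.

    Calling this on an MSI sample is an error: the scheme is defined
    only on the MSS subcohort.
    """
    if calls.msi_final != "MSS":
        raise ValueError(
            f"five-class labels are defined for MSS samples only "
            f"({calls.sample_id} is {calls.msi_final})"
        )
    apc = profile.n_trunc_capped
    kp = calls.kras_mut and calls.tp53_mut
    if apc == 0:
        return "C0"
    if apc == 1:
        return "C3" if kp else "C1"
    return "C4" if kp else "C2"


@dataclass
class CohortLabels:
    """Per-sample labels plus the class-count summary tables."""

    labels: pd.DataFrame  # sample_id, msi_final, ten_group, five_class
    ten_group_counts: pd.DataFrame  # group x {all, MSI, MSS}
    five_class_counts: pd.Series  # MSS counts per class


def classify_cohort(
    calls: Sequence[DriverCalls],
    profiles: Sequence[ApcProfile],
    braf_dominant: bool = False,
) -> CohortLabels:
    """Label every sample; five-class labels only for MSS samples."""
    prof_by_id = {p.sample_id: p for p in profiles}
    rows = []
    for c in calls:
        profile = prof_by_id[c.sample_id]
        five = (
            assign_five_class(c, profile) if c.msi_final == "MSS" else None
        )
        rows.append(
            {
                "sample_id": c.sample_id,
                "msi_final": c.msi_final,
                "ten_group": assign_ten_group(c, braf_dominant),
                "five_class": five,
                "apc_trunc_capped": profile.n_trunc_capped,
                "wnt_group": profile.wnt_group,
            }
        )
    labels = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "msi_final",
            "ten_group",
            "five_class",
            "apc_trunc_capped",
            "wnt_group",
        ],
    )
    ten = pd.DataFrame(0, index=list(TEN_GROUPS), columns=["all", "MSI", "MSS"])
    if len(labels):
        ten["all"] = labels["ten_group"].value_counts().reindex(TEN_GROUPS, fill_value=0)
        for stratum, tag in (("MSI", "MSI_H"), ("MSS", "MSS")):
            sub = labels[labels["msi_final"] == tag]
            ten[stratum] = (
                sub["ten_group"].value_counts().reindex(TEN_GROUPS, fill_value=0)
            )
    mss = labels[labels["msi_final"] == "MSS"]
    five = (
        mss["five_class"].value_counts().reindex(FIVE_CLASSES, fill_value=0)
        if len(mss)
        else pd.Series(0, index=list(FIVE_CLASSES))
    )
    five.name = "n"
    return CohortLabels(labels=labels, ten_group_counts=ten, five_class_counts=five)
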