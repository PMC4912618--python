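"""Survival analysis: Kaplan–Meier, log-rank and Cox models.

The Cox layer wraps lifelines (Efron tie handling) and adds the two
project-specific pieces: the piecewise-linear Age>=70 term
(0 below 70, age-70 above) and backward elimination on Wald p-values
with a configurable significance-level-to-stay and a protected set.
Four pre-specified models over the MSS subcohort are provided:

* Model 1: APC, KRAS, TP53, BRAF, Age>=70;
* Model 2: Model 1 + AKP + two-APC-mutations, backward elimination
  (stay 0.10);
* Model 3: Model 2 + distant metastasis, backward elimination;
* Model 4: APC, KRAS, TP53, BRAF, APC(2)KP, metastasis, Age>=70,
  backward elimination — APC(2)KP replaces AKP and two-APC-mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "SurvSpec",
    "CoxFit",
    "km_estimate",
    "logrank",
    "age70_term",
    "cox_fit",
    "build_model_frame",
    "run_prognostic_models",
    "MODEL_SPECS",
]


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray  # S(t) at the event times (step function)
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvSpec:
    """Covariates and elimination policy for a Cox fit."""

    covariates: tuple[str, ...]
    eliminate: bool = False
    stay_threshold: float = 0.10
    protected: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates in spec")

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "eliminate": self.eliminate,
            "stay_threshold": self.stay_threshold,
            "protected": list(self.protected),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvSpec":
        return cls(
            covariates=tuple(d["covariates"]),
            eliminate=d.get("eliminate", False),
            stay_threshold=d.get("stay_threshold", 0.10),
            protected=tuple(d.get("protected", ())),
        )


@dataclass
class CoxFit:
    """Hazard ratios, Wald p-values and fit statistics of one Cox model."""

    covariates: list[str]
    hr: pd.Series
    p: pd.Series
    hr_ci_lower: pd.Series
    hr_ci_upper: pd.Series
    lr_chi2: float
    lr_p: float
    n: int
    n_events: int
    eliminated: list[str] = field(default_factory=list)


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Optional[Sequence] = None,
) -> list[KMCurve]:
    """Product-limit survival estimate per group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    curves = []
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            logger.warning("empty survival group %r skipped", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        curves.append(
            KMCurve(
                group=str(g),
                times=surv.index.to_numpy(dtype=float),
                survival=surv.to_numpy(dtype=float),
                at_risk=tbl["at_risk"].to_numpy(dtype=float),
                n=int(mask.sum()),
            )
        )
    return curves


def logrank(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> tuple[float, float]:
    """k-group log-rank test (df = k-1)."""
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("log-rank needs >=2 groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(events, dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


def age70_term(age: float) -> float:
    """Piecewise-linear late-age term: 0 below 70, age-70 at or above."""
    if np.ndim(age):
        a = np.asarray(age, dtype=float)
        return np.maximum(0.0, a - 70.0)
    return max(0.0, float(age) - 70.0)


def cox_fit(spec: SurvSpec, data: pd.DataFrame) -> CoxFit:
    """Proportional-hazards fit (Efron ties) with optional backward
    elimination.

    ``data`` needs columns ``os_months``, ``os_event`` and every
    covariate of the spec.  Elimination repeatedly removes the
    unprotected covariate with the largest Wald p until all exceed none
    of the stay threshold; protected covariates are never removed.
    """
    active = list(spec.covariates)
    for c in active + ["os_months", "os_event"]:
        if c not in data.columns:
            raise ValueError(f"column {c!r} missing from model frame")
    if int(data["os_event"].sum()) == 0:
        raise ValueError("no events in data")
    for c in active:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")

    eliminated: list[str] = []
    while True:
        cph = CoxPHFitter()
        cph.fit(
            data[active + ["os_months", "os_event"]],
            duration_col="os_months",
            event_col="os_event",
        )
        pvals = cph.summary["p"]
        if not spec.eliminate:
            break
        removable = [c for c in active if c not in spec.protected]
        if not removable:
            break
        worst = pvals.loc[removable].idxmax()
        if pvals[worst] <= spec.stay_threshold:
            break
        active.remove(worst)
        eliminated.append(worst)
        if not active:
            raise ValueError("backward elimination removed every covariate")

    summary = cph.summary
    lr = cph.log_likelihood_ratio_test()
    return CoxFit(
        covariates=active,
        hr=summary["exp(coef)"],
        p=summary["p"],
        hr_ci_lower=summary["exp(coef) lower 95%"],
        hr_ci_upper=summary["exp(coef) upper 95%"],
        lr_chi2=float(lr.test_statistic),
        lr_p=float(lr.p_value),
        n=len(data),
        n_events=int(data["os_event"].sum()),
        eliminated=eliminated,
    )


def build_model_frame(clinical, calls, profiles) -> pd.DataFrame:
    """Per-sample covariate frame for the pre-specified Cox models.

    Binary driver covariates (apc, kras, tp53, braf), the combination
    covariates (akp, two_apc_mut, apc2kp), distant metastasis, the
    age70 term and the survival columns.
    """
    calls_by = {c.sample_id: c for c in calls}
    prof_by = {p.sample_id: p for p in profiles}
    rows = []
    for clin in clinical:
        c = calls_by[clin.sample_id]
        p = prof_by[clin.sample_id]
        apc = int(p.n_trunc_capped >= 1)
        kp = int(c.kras_mut and c.tp53_mut)
        rows.append(
            {
                "sample_id": clin.sample_id,
                "msi_final": c.msi_final,
                "apc": apc,
                "kras": int(c.kras_mut),
                "tp53": int(c.tp53_mut),
                "braf": int(c.braf_v600e),
                "akp": int(apc and kp),
                "two_apc_mut": int(p.n_trunc_capped == 2),
                "apc2kp": int(p.n_trunc_capped == 2 and kp),
                "metastasis": int(clin.distant_met),
                "age70": age70_term(clin.age),
                "os_months": float(clin.os_months),
                "os_event": int(clin.os_event),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


#: The four pre-specified overall-survival models (MSS subcohort).
MODEL_SPECS: dict[str, SurvSpec] = {
    "model1": SurvSpec(("apc", "kras", "tp53", "braf", "age70")),
    "model2": SurvSpec(
        ("apc", "kras", "tp53", "braf", "akp", "two_apc_mut", "age70"),
        eliminate=True,
    ),
    "model3": SurvSpec(
        ("apc", "kras", "tp53", "braf", "akp", "two_apc_mut", "metastasis", "age70"),
        eliminate=True,
    ),
    "model4": SurvSpec(
        ("apc", "kras", "tp53", "braf", "apc2kp", "metastasis", "age70"),
        eliminate=True,
    ),
}


def run_prognostic_models(frame: pd.DataFrame) -> dict[str, CoxFit]:
    """Fit the four pre-specified models on the MSS subset of ``frame``."""
    mss = frame[frame["msi_final"] == "MSS"] if "msi_final" in frame else frame
    return {name: cox_fit(spec, mss) for name, spec in MODEL_SPECS.items()}
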