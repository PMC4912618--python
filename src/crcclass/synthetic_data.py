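"""Synthetic tumour-cohort generator.

The study data sit behind controlled access, so every pipeline stage is
exercised on cohorts generated with the statistical structure the
analysis assumes: ~13% MSI prevalence with near-perfect TGFBR2/ACVR2A
homopolymer-indel coupling, driver-combination classes mixed in the
published proportions of the MSS cohort, APC truncation codons placed
by the four-zone density profile with early/late pairing in two-hit
tumours, variant allele fractions separated by allelic-loss status,
gene-length-proportional background mutation loads (hypermutated MSI
vs MSS), exponential survival driven by the final prognostic Cox
model's hazard ratios, and uniform censoring tuned to a ~34-month
median follow-up.

Every draw flows from one ``numpy`` Generator, so a fixed seed fixes
the full cohort; a truth table (true class, true MSI, true loss, the
generative log-hazards) accompanies each cohort for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    ClinicalRecord,
    Cohort,
    ExpressionMatrix,
    GeneCatalog,
    MutationRecord,
    Site,
    VariantClass,
    assemble_cohort,
)

__all__ = [
    "SyntheticConfig",
    "generate_gene_catalog",
    "generate_cohort",
    "generate_mss_survival_frame",
    "default_gene_sets",
    "spike_smg",
]

#: Genes the generator treats specially (drivers + MSI proxy genes),
#: with their canonical protein lengths.
SPECIAL_GENES = {
    "APC": 2843,
    "KRAS": 189,
    "TP53": 393,
    "BRAF": 766,
    "TGFBR2": 567,
    "ACVR2A": 513,
}

_ZONE_BOUNDS = {1: (1, 218), 2: (219, 1262), 3: (1263, 1587), 4: (1588, 2843)}


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults ARE the study conditions."""

    n_samples: int = 468
    # MSI and the indel proxy
    msi_prevalence: float = 61 / 468
    msi_proxy_sensitivity: float = 59 / 61  # P(both indels | MSI)
    msi_proxy_specificity: float = 0.99  # P(not both | MSS)
    single_indel_prob: float = 0.01  # one proxy gene only, per gene, MSS
    homopolymer_run: int = 7
    # MSS driver-class mixture (C0..C4), published MSS class sizes
    mss_class_mixture: tuple[float, ...] = (111, 135, 76, 45, 40)
    # KRAS/TP53 conditionals for classes that leave them free
    kras_given_c0: float = 0.35
    tp53_given_c0: float = 0.55
    # pattern (neither, KRAS only, TP53 only) for C1/C2
    kp_pattern_c12: tuple[float, ...] = (0.30, 0.25, 0.45)
    braf_given_msi: float = 52 / 61
    braf_given_mss: float = 18 / 407
    # MSI driver marginals (APC truncation count distribution, then flags)
    msi_apc_count_probs: tuple[float, ...] = (45 / 61, 7 / 61, 9 / 61)
    kras_given_msi: float = 0.25
    tp53_given_msi: float = 0.30
    # APC truncation placement
    apc_zone_weights: tuple[float, ...] = (3.0, 181.0, 259.0, 2.0)
    zone_pairing_prob: float = 0.95  # two-hit: one zone-1/2 + one zone-3 hit
    # allelic loss and the VAF model
    loss_probability_one_hit: float = 59 / 187
    loss_probability_two_hit: float = 0.08
    vaf_mean_loss: float = 0.60
    vaf_mean_no_loss: float = 0.35
    vaf_sd: float = 0.08
    vaf_bounds: tuple[float, float] = (0.05, 0.95)
    # background mutation load (non-silent events per sample)
    background_nonsilent_mean_msi: float = 169.0
    background_nonsilent_mean_mss: float = 33.0
    silent_to_nonsilent: float = 1 / 2.8
    # clinical
    age_mean: float = 64.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (25.0, 95.0)
    met_prob_by_class: tuple[float, ...] = (0.29, 0.37, 0.25, 0.51, 0.51)
    met_prob_msi: float = 0.10
    right_prob_by_class: tuple[float, ...] = (0.53, 0.28, 0.37, 0.40, 0.51)
    right_prob_msi: float = 0.75
    # survival: exponential baseline + final-model log-hazards
    baseline_median_months: float = 60.0
    log_hr: dict = field(
        default_factory=lambda: {
            "apc": math.log(0.59),
            "braf": math.log(2.25),
            "apc2kp": math.log(2.10),
            "metastasis": math.log(4.49),
            "age70": math.log(1.09),  # per year over 70
        }
    )
    censor_months: tuple[float, float] = (6.0, 62.0)  # uniform; median ~34
    # expression
    expression_noise_sd: float = 1.0
    emt_shift_c0: float = 0.8
    ras_shift_kp: float = 0.6
    wnt_shift_apc_mut: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "msi_prevalence",
            "msi_proxy_sensitivity",
            "msi_proxy_specificity",
            "loss_probability_one_hit",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if sum(self.mss_class_mixture) <= 0:
            raise ValueError("mss_class_mixture must have positive mass")
        if sum(self.apc_zone_weights) <= 0:
            raise ValueError("apc_zone_weights must have positive mass")
        if self.mss_class_mixture[1:] == (0, 0, 0, 0) and any(
            self.msi_apc_count_probs[1:]
        ) is False:
            raise ValueError("no APC-mutated class has mass but APC events requested")


def generate_gene_catalog(
    n_genes: int = 1321,
    seed: int | np.random.Generator = 0,
    min_length: int = 100,
    max_length: int = 35000,
) -> GeneCatalog:
    """Catalog with a long-tailed amino-acid-length distribution.

    The driver and proxy genes carry their true canonical lengths; the
    remaining genes get log-normal lengths clipped to
    [min_length, max_length] (median a few hundred aa, giant outliers
    in the tens of thousands).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_genes < 1:
        raise ValueError("n_genes must be >=1")
    lengths = dict(SPECIAL_GENES)
    n_extra = max(0, n_genes - len(lengths))
    raw = rng.lognormal(mean=math.log(450.0), sigma=0.85, size=n_extra)
    for i, L in enumerate(raw):
        lengths[f"G{i + 1:04d}"] = int(np.clip(round(L), min_length, max_length))
    return GeneCatalog(lengths)


def default_gene_sets() -> dict[str, tuple[str, ...]]:
    """Synthetic stand-in gene sets over catalog symbols.

    The published EMT / RAS-MAPK / beta-catenin-target lists are not
    redistributable here; these fixed symbol lists target the same
    scoring machinery and are swappable for real lists via gene-set
    files.
    """
    return {
        "EMT": tuple(f"G{i:04d}" for i in range(1, 26)),
        "RAS": tuple(f"G{i:04d}" for i in range(26, 51)),
        "WNT_BCAT": tuple(f"G{i:04d}" for i in range(51, 115)),
    }


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _draw_zone(rng, weights) -> int:
    w = np.asarray(weights, dtype=float)
    return int(rng.choice(4, p=w / w.sum())) + 1


def _codon_in_zone(rng, zone: int) -> int:
    lo, hi = _ZONE_BOUNDS[zone]
    return int(rng.integers(lo, hi + 1))


def _draw_apc_codons(rng, n_trunc: int, cfg: SyntheticConfig) -> list[int]:
    if n_trunc == 0:
        return []
    if n_trunc == 1:
        return [_codon_in_zone(rng, _draw_zone(rng, cfg.apc_zone_weights))]
    codons = []
    if rng.random() < cfg.zone_pairing_prob:
        w12 = np.asarray(cfg.apc_zone_weights[:2], dtype=float)
        early = int(rng.choice(2, p=w12 / w12.sum())) + 1
        codons = [_codon_in_zone(rng, early), _codon_in_zone(rng, 3)]
    else:
        codons = [
            _codon_in_zone(rng, _draw_zone(rng, cfg.apc_zone_weights))
            for _ in range(2)
        ]
    extra = [
        _codon_in_zone(rng, _draw_zone(rng, cfg.apc_zone_weights))
        for _ in range(n_trunc - 2)
    ]
    return codons + extra


def _mss_class_drivers(rng, cfg: SyntheticConfig) -> tuple[str, int, bool, bool]:
    """(class, apc_count, kras, tp53) for one MSS sample."""
    mix = np.asarray(cfg.mss_class_mixture, dtype=float)
    cls = int(rng.choice(5, p=mix / mix.sum()))
    if cls == 0:
        return "C0", 0, rng.random() < cfg.kras_given_c0, rng.random() < cfg.tp53_given_c0
    if cls in (1, 2):
        pat = np.asarray(cfg.kp_pattern_c12, dtype=float)
        which = int(rng.choice(3, p=pat / pat.sum()))
        kras = which == 1
        tp53 = which == 2
        return ("C1", 1, kras, tp53) if cls == 1 else ("C2", 2, kras, tp53)
    if cls == 3:
        return "C3", 1, True, True
    return "C4", 2, True, True


_NONSILENT_CLASSES = [
    VariantClass.MISSENSE,
    VariantClass.STOPGAIN,
    VariantClass.FRAMESHIFT_INDEL,
    VariantClass.INFRAME_INDEL,
    VariantClass.SPLICE,
    VariantClass.OTHER_NONSILENT,
]
_NONSILENT_PROBS = np.array([0.70, 0.10, 0.08, 0.04, 0.05, 0.03])


def _vaf(rng, cfg: SyntheticConfig, loss: bool) -> float:
    mean = cfg.vaf_mean_loss if loss else cfg.vaf_mean_no_loss
    return float(
        _truncated_normal(rng, mean, cfg.vaf_sd, *cfg.vaf_bounds)
    )


def generate_mss_survival_frame(
    n: int, cfg: Optional[SyntheticConfig] = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Covariate + survival frame for an MSS cohort of size ``n``.

    The frame carries exactly the final prognostic model's covariates
    (apc, kras, tp53, braf, apc2kp, metastasis, age70) plus os_months /
    os_event generated from an exponential proportional-hazards law
    with the configured log-hazards, and the per-sample generative
    linear predictor under ``true_lp``.  This is the light-weight path
    used for hazard-ratio recovery at large n.
    """
    cfg = cfg or SyntheticConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cls, apc_count, kras, tp53 = _mss_class_drivers(rng, cfg)
        braf = rng.random() < cfg.braf_given_mss
        met = rng.random() < cfg.met_prob_by_class[int(cls[1])]
        age = float(_truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_bounds))
        rows.append(
            {
                "five_class_true": cls,
                "apc": int(apc_count >= 1),
                "kras": int(kras),
                "tp53": int(tp53),
                "braf": int(braf),
                "apc_count": apc_count,
                "akp": int(apc_count >= 1 and kras and tp53),
                "two_apc_mut": int(apc_count >= 2),
                "apc2kp": int(apc_count >= 2 and kras and tp53),
                "metastasis": int(met),
                "age": age,
                "age70": max(0.0, age - 70.0),
            }
        )
    frame = pd.DataFrame(rows)
    frame.index = [f"S{i + 1:05d}" for i in range(n)]
    frame.index.name = "sample_id"
    _simulate_survival(frame, cfg, rng)
    frame["msi_final"] = "MSS"
    return frame


def _simulate_survival(frame: pd.DataFrame, cfg: SyntheticConfig, rng) -> None:
    """Exponential survival + uniform censoring, in place."""
    lp = np.zeros(len(frame))
    for cov, beta in cfg.log_hr.items():
        lp += beta * frame[cov].to_numpy(dtype=float)
    h0 = math.log(2.0) / cfg.baseline_median_months
    t_death = rng.exponential(1.0, size=len(frame)) / (h0 * np.exp(lp))
    t_censor = rng.uniform(*cfg.censor_months, size=len(frame))
    frame["os_months"] = np.minimum(t_death, t_censor)
    frame["os_event"] = (t_death <= t_censor).astype(int)
    frame["true_lp"] = lp


def generate_cohort(
    cfg: Optional[SyntheticConfig] = None,
    seed: int | np.random.Generator = 0,
    catalog: Optional[GeneCatalog] = None,
    with_expression: bool = True,
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a full cohort plus its truth table.

    Generative order per sample: MSI status -> driver class (MSS) or
    MSI driver marginals -> APC truncation codons from the zone
    weights (pairing rule for two-hit tumours) -> allelic loss and
    VAFs -> proxy-gene indels -> driver point mutations -> length-
    proportional background mutations -> clinical covariates ->
    exponential survival -> expression shifts.
    """
    cfg = cfg or SyntheticConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    catalog = catalog or generate_gene_catalog(seed=rng)

    background_genes = [g for g in catalog.genes if g not in SPECIAL_GENES]
    bg_weights = np.array([3.0 * catalog[g] for g in background_genes])
    bg_weights = bg_weights / bg_weights.sum()

    mutations: list[MutationRecord] = []
    clinical: list[ClinicalRecord] = []
    truth_rows = []

    surv_rows = []
    sample_ids = [f"S{i + 1:05d}" for i in range(cfg.n_samples)]
    for sid in sample_ids:
        msi = rng.random() < cfg.msi_prevalence
        braf = rng.random() < (cfg.braf_given_msi if msi else cfg.braf_given_mss)
        if msi:
            cls = None
            probs = np.asarray(cfg.msi_apc_count_probs, dtype=float)
            apc_count = int(rng.choice(3, p=probs / probs.sum()))
            kras = rng.random() < cfg.kras_given_msi
            tp53 = rng.random() < cfg.tp53_given_msi
            met = rng.random() < cfg.met_prob_msi
            p_right = cfg.right_prob_msi
        else:
            cls, apc_count, kras, tp53 = _mss_class_drivers(rng, cfg)
            met = rng.random() < cfg.met_prob_by_class[int(cls[1])]
            p_right = cfg.right_prob_by_class[int(cls[1])]

        # APC truncations, loss and VAFs
        codons = _draw_apc_codons(rng, apc_count, cfg)
        if apc_count == 1:
            loss = rng.random() < cfg.loss_probability_one_hit
        elif apc_count >= 2:
            loss = rng.random() < cfg.loss_probability_two_hit
        else:
            loss = False
        for j, codon in enumerate(codons):
            hit_loss = loss and j == 0
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene="APC",
                    variant_class=VariantClass.STOPGAIN
                    if rng.random() < 0.55
                    else VariantClass.FRAMESHIFT_INDEL,
                    codon=codon,
                    alt_read_fraction=_vaf(rng, cfg, hit_loss),
                )
            )

        # MSI proxy indels
        if msi:
            if rng.random() < cfg.msi_proxy_sensitivity:
                proxy = ("TGFBR2", "ACVR2A")
            else:
                proxy = (rng.choice(["TGFBR2", "ACVR2A"]),) if rng.random() < 0.5 else ()
        else:
            if rng.random() < 1.0 - cfg.msi_proxy_specificity:
                proxy = ("TGFBR2", "ACVR2A")
            else:
                proxy = tuple(
                    g
                    for g in ("TGFBR2", "ACVR2A")
                    if rng.random() < cfg.single_indel_prob
                )
        for g in proxy:
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene=g,
                    variant_class=VariantClass.FRAMESHIFT_INDEL,
                    codon=int(rng.integers(1, catalog[g] + 1)),
                    homopolymer_run=cfg.homopolymer_run,
                    alt_read_fraction=_vaf(rng, cfg, False),
                )
            )

        # Driver point mutations
        if kras:
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene="KRAS",
                    variant_class=VariantClass.MISSENSE,
                    codon=int(rng.choice([12, 13, 61, 146], p=[0.6, 0.2, 0.1, 0.1])),
                    alt_read_fraction=_vaf(rng, cfg, False),
                )
            )
        if tp53:
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene="TP53",
                    variant_class=VariantClass.MISSENSE
                    if rng.random() < 0.7
                    else VariantClass.STOPGAIN,
                    codon=int(rng.integers(1, 394)),
                    alt_read_fraction=_vaf(rng, cfg, False),
                )
            )
        if braf:
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene="BRAF",
                    variant_class=VariantClass.MISSENSE,
                    codon=600,
                    alt_read_fraction=_vaf(rng, cfg, False),
                )
            )

        # Background mutations, Poisson totals split across genes by length
        lam = (
            cfg.background_nonsilent_mean_msi
            if msi
            else cfg.background_nonsilent_mean_mss
        )
        n_bg = rng.poisson(lam)
        n_silent = rng.poisson(lam * cfg.silent_to_nonsilent)
        if n_bg + n_silent:
            gene_idx = rng.choice(
                len(background_genes), size=n_bg + n_silent, p=bg_weights
            )
            vclasses = [
                _NONSILENT_CLASSES[i]
                for i in rng.choice(len(_NONSILENT_CLASSES), size=n_bg, p=_NONSILENT_PROBS)
            ] + [VariantClass.SILENT] * n_silent
            for gi, vc in zip(gene_idx, vclasses):
                gene = background_genes[gi]
                mutations.append(
                    MutationRecord(
                        sample_id=sid,
                        gene=gene,
                        variant_class=vc,
                        codon=int(rng.integers(1, catalog[gene] + 1)),
                        alt_read_fraction=_vaf(rng, cfg, False),
                    )
                )

        # Clinical covariates
        age = float(_truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_bounds))
        if met:
            stage = 4 if rng.random() < 0.62 else int(rng.choice([2, 3]))
        else:
            stage = int(rng.choice([1, 2, 3], p=[0.45, 0.35, 0.20]))
        developed = met and stage != 4
        site = (
            Site.CAECUM_ASCENDING
            if rng.random() < p_right
            else Site(
                rng.choice(
                    [
                        "transverse",
                        "descending",
                        "sigmoid",
                        "rectosigmoid",
                        "rectum",
                    ]
                )
            )
        )
        surv_rows.append(
            {
                "apc": int(apc_count >= 1),
                "braf": int(braf),
                "apc2kp": int(apc_count >= 2 and kras and tp53),
                "metastasis": int(met),
                "age70": max(0.0, age - 70.0),
            }
        )
        clinical.append(
            # os filled after the survival pass below
            dict(
                sample_id=sid,
                age=age,
                stage=stage,
                site=site,
                specimen="metastatic" if (met and stage == 4 and rng.random() < 0.4) else "primary",
                msi_label="MSI_H" if msi else "MSS",
                distant_met=met,
                developed_met=developed,
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "true_msi": "MSI_H" if msi else "MSS",
                "true_class": cls,
                "true_apc_count": apc_count,
                "true_kras": int(kras),
                "true_tp53": int(tp53),
                "true_braf": int(braf),
                "true_loss": bool(loss),
                "true_metastasis": int(met),
            }
        )

    surv = pd.DataFrame(surv_rows, index=sample_ids)
    _simulate_survival(surv, cfg, rng)
    clinical_records = [
        ClinicalRecord(
            os_months=float(surv["os_months"].iloc[i]),
            os_event=bool(surv["os_event"].iloc[i]),
            **clinical[i],
        )
        for i in range(len(clinical))
    ]
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    truth["true_lp"] = surv["true_lp"]
    for cov, beta in cfg.log_hr.items():
        truth[f"log_hr_{cov}"] = beta

    expression = None
    if with_expression:
        expression = _generate_expression(rng, cfg, truth, sample_ids)

    cohort = assemble_cohort(mutations, clinical_records, catalog, expression)
    return cohort, truth


def _generate_expression(rng, cfg, truth, sample_ids) -> ExpressionMatrix:
    sets = default_gene_sets()
    genes = sorted({g for gs in sets.values() for g in gs} | {"APC"})
    base = rng.normal(8.0, cfg.expression_noise_sd, size=(len(sample_ids), len(genes)))
    df = pd.DataFrame(base, index=sample_ids, columns=genes)
    cls = truth["true_class"]
    is_c0 = (cls == "C0").to_numpy()
    is_kp = cls.isin(["C3", "C4"]).to_numpy()
    apc_mut = (truth["true_apc_count"] >= 1).to_numpy()
    two_hit = (truth["true_apc_count"] >= 2).to_numpy()
    df.loc[is_c0, list(sets["EMT"])] += cfg.emt_shift_c0
    df.loc[is_kp, list(sets["RAS"])] += cfg.ras_shift_kp
    df.loc[apc_mut, list(sets["WNT_BCAT"])] += cfg.wnt_shift_apc_mut
    df.loc[two_hit, "APC"] += 0.4
    return ExpressionMatrix(df)


def spike_smg(
    cohort: Cohort,
    truth: pd.DataFrame,
    cfg: SyntheticConfig,
    gene: str,
    fold: float,
    seed: int | np.random.Generator = 0,
) -> tuple[Cohort, pd.DataFrame]:
    """Multiply one background gene's mutation rate by ``fold``.

    Replaces the gene's mutation records with a fresh draw at the
    inflated rate (per-sample Poisson with mean proportional to
    3 * aa_length, scaled by ``fold``), and records the spike in a
    copy of the truth table.  ``fold`` < 1 is an error.
    """
    if fold < 1:
        raise ValueError("fold must be >=1")
    if gene not in cohort.catalog:
        raise ValueError(f"gene {gene!r} not in catalog")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bg_total = sum(
        3.0 * cohort.catalog[g] for g in cohort.catalog.genes if g not in SPECIAL_GENES
    )
    share = 3.0 * cohort.catalog[gene] / bg_total
    msi_by_sample = {c.sample_id: c.msi_label for c in cohort.clinical}

    kept = [m for m in cohort.mutations if m.gene != gene]
    new: list[MutationRecord] = []
    for clin in cohort.clinical:
        lam = (
            cfg.background_nonsilent_mean_msi
            if msi_by_sample[clin.sample_id] == "MSI_H"
            else cfg.background_nonsilent_mean_mss
        )
        n = rng.poisson(fold * lam * share)
        for _ in range(n):
            vc = _NONSILENT_CLASSES[
                int(rng.choice(len(_NONSILENT_CLASSES), p=_NONSILENT_PROBS))
            ]
            new.append(
                MutationRecord(
                    sample_id=clin.sample_id,
                    gene=gene,
                    variant_class=vc,
                    codon=int(rng.integers(1, cohort.catalog[gene] + 1)),
                    alt_read_fraction=_vaf(rng, cfg, False),
                )
            )
    truth = truth.copy()
    truth.attrs = dict(truth.attrs)
    spikes = dict(truth.attrs.get("spiked_genes", {}))
    spikes[gene] = fold
    truth.attrs["spiked_genes"] = spikes
    new_cohort = assemble_cohort(
        kept + new, cohort.clinical, cohort.catalog, cohort.expression
    )
    return new_cohort, truth
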