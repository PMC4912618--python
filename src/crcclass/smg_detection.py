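"""Significantly-mutated-gene (SMG) detection by robust regression.

The background model is deliberately simple: across a targeted panel,
the number of non-silent mutations a gene accumulates is roughly
proportional to its coding length.  Genes under positive selection sit
far above the line.  We fit N ~ a + b * aa_length with an MM-type
robust regression (an S-estimate of scale followed by a redescending
bisquare M-step at 95% Gaussian efficiency) so that the handful of
driver genes cannot drag the background line or inflate the residual
scale, and report each gene's standardized robust residual

    z = (N - fitted) / scale.

Genes with z >= 3 in any stratum (overall, MSI-only, MSS-only) are
flagged as outliers.  The per-gene mutation rate is expressed per 1e5
coding nucleotides:

    rate = 1e5 * N / (n_samples * 3 * aa_length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_io import Cohort, GeneCatalog
from .functional_calls import DriverCalls

logger = logging.getLogger(__name__)

__all__ = [
    "RobustFit",
    "SmgRow",
    "nonsilent_counts",
    "mutation_rate",
    "robust_fit",
    "detect_smg",
    "compare_rates_to_reference",
    "Z_OUTLIER",
    "HOTSPOT_MIN_TUMOURS",
]

#: Robust residual score at or above which a gene is an outlier.
Z_OUTLIER = 3.0
#: A codon is a hotspot when mutated in at least this many tumours.
HOTSPOT_MIN_TUMOURS = 8

# Bisquare tuning constants: c=1.547 gives the 50%-breakdown S-scale,
# c=4.685 gives 95% efficiency for the final M-step under Gaussian errors.
_C_SCALE = 1.547
_C_EFF = 4.685
_B_CONSISTENCY = 0.5  # E[rho_norm(u)] under N(0,1) for c=1.547


@dataclass
class RobustFit:
    """A fitted robust line N ~ intercept + slope * aa_length."""

    slope: float
    intercept: float
    scale: float
    z: np.ndarray  # standardized robust residual per input gene

    def predict(self, aa_length) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(aa_length, dtype=float)


@dataclass
class SmgRow:
    gene: str
    n_nonsilent: int
    aa_length: int
    rate: float
    z_overall: Optional[float] = None
    z_msi: Optional[float] = None
    z_mss: Optional[float] = None
    hotspot_codons: int = 0
    discordant_vs_reference: Optional[bool] = None

    @property
    def outlier_overall(self) -> bool:
        return self.z_overall is not None and self.z_overall >= Z_OUTLIER

    @property
    def outlier_msi(self) -> bool:
        return self.z_msi is not None and self.z_msi >= Z_OUTLIER

    @property
    def outlier_mss(self) -> bool:
        return self.z_mss is not None and self.z_mss >= Z_OUTLIER

    @property
    def outlier_any(self) -> bool:
        return self.outlier_overall or self.outlier_msi or self.outlier_mss


def nonsilent_counts(
    cohort: Cohort,
    stratum: str = "overall",
    msi_by_sample: Optional[Mapping[str, str]] = None,
) -> dict[str, int]:
    """Per-gene count of non-silent mutation EVENTS (not mutated samples).

    ``stratum`` is ``overall``, ``MSI`` or ``MSS``; the latter two need
    ``msi_by_sample`` (sample_id -> "MSI_H"/"MSS", normally the
    ``msi_final`` of the driver calls).  Genes present in the catalog
    but unmutated get a count of 0; a mutated gene missing from the
    catalog is a hard error.
    """
    if stratum not in ("overall", "MSI", "MSS"):
        raise ValueError(f"unknown stratum {stratum!r}")
    if stratum != "overall" and msi_by_sample is None:
        raise ValueError("MSI/MSS strata require msi_by_sample")
    wanted = {"MSI": "MSI_H", "MSS": "MSS"}.get(stratum)
    counts = {g: 0 for g in cohort.catalog.genes}
    for m in cohort.mutations:
        if m.variant_class.is_silent:
            continue
        if wanted is not None and msi_by_sample.get(m.sample_id) != wanted:
            continue
        if m.gene not in counts:
            raise ValueError(f"gene {m.gene!r} has mutations but no catalog entry")
        counts[m.gene] += 1
    return counts


def mutation_rate(n: int, aa_length: int, n_samples: int) -> float:
    """Mutations per 1e5 coding nucleotides: 1e5 * n / (n_samples * 3 * aa_length)."""
    if aa_length < 1:
        raise ValueError("aa_length must be >=1")
    if n_samples < 1:
        raise ValueError("n_samples must be >=1")
    return 1e5 * n / (n_samples * 3.0 * aa_length)


def _rho_norm(u: np.ndarray, c: float) -> np.ndarray:
    """Bisquare rho normalized to max 1."""
    v = np.clip(u / c, -1.0, 1.0)
    return 1.0 - (1.0 - v**2) ** 3


def _m_scale(resid: np.ndarray, c: float = _C_SCALE, b: float = _B_CONSISTENCY) -> float:
    """M-estimate of scale: solve mean(rho_norm(r/s)) = b by fixed point."""
    r = np.asarray(resid, dtype=float)
    s = np.median(np.abs(r)) / 0.6745
    if s <= 0:
        s = np.mean(np.abs(r)) or 1.0
    for _ in range(200):
        m = np.mean(_rho_norm(r / s, c))
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= 1e-10 * s:
            s = s_new
            break
        s = s_new
    return float(s)


def _bisquare_weights(u: np.ndarray, c: float) -> np.ndarray:
    v = np.clip(u / c, -1.0, 1.0)
    return (1.0 - v**2) ** 2


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    if sw <= 0:
        raise RuntimeError("all robust weights vanished")
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        raise ValueError("degenerate predictor: no spread in aa_length")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return slope, ym - slope * xm


def robust_fit(
    counts_by_gene: Mapping[str, int],
    catalog: GeneCatalog,
    fit_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> RobustFit:
    """MM-type robust line of mutation count on amino-acid length.

    Stages: (1) Theil–Sen initial line (high-breakdown start);
    (2) S-stage — a few reweighting steps with the 50%-breakdown
    bisquare, re-solving the M-scale each step; (3) final bisquare
    M-step at c=4.685 with the S-scale held fixed.  Genes with zero
    counts are legitimate data and inform the background line.
    """
    genes = list(counts_by_gene)
    if len(genes) < 30:
        raise ValueError(f"robust fit needs >=30 genes, got {len(genes)}")
    x = np.array([catalog[g] for g in genes], dtype=float)
    y = np.array([counts_by_gene[g] for g in genes], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate catalog: all aa_length values equal")

    slope, intercept = stats.theilslopes(y, x)[:2]
    if not fit_intercept:
        intercept = 0.0

    # S-stage: couple the line and the 50%-breakdown M-scale.
    scale = _m_scale(y - (intercept + slope * x))
    for _ in range(20):
        r = (y - (intercept + slope * x)) / scale
        w = _bisquare_weights(r, _C_SCALE)
        if w.sum() == 0:
            break
        if fit_intercept:
            slope, intercept = _wls_line(x, y, w)
        else:
            slope = float((w * x * y).sum() / (w * x * x).sum())
        new_scale = _m_scale(y - (intercept + slope * x))
        if abs(new_scale - scale) <= tol * scale:
            scale = new_scale
            break
        scale = new_scale

    # Efficient M-step at fixed S-scale.
    for _ in range(max_iter):
        r = (y - (intercept + slope * x)) / scale
        w = _bisquare_weights(r, _C_EFF)
        if w.sum() == 0:
            break
        if fit_intercept:
            new_slope, new_intercept = _wls_line(x, y, w)
        else:
            new_slope = float((w * x * y).sum() / (w * x * x).sum())
            new_intercept = 0.0
        if (
            abs(new_slope - slope) <= tol * (1 + abs(slope))
            and abs(new_intercept - intercept) <= tol * (1 + abs(intercept))
        ):
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept

    z = (y - (intercept + slope * x)) / scale
    return RobustFit(slope=float(slope), intercept=float(intercept), scale=scale, z=z)


def _hotspot_codons(cohort: Cohort, gene: str) -> int:
    """Number of codons of ``gene`` mutated (non-silently) in >=8 tumours."""
    samples_by_codon: dict[int, set[str]] = {}
    for m in cohort.mutations:
        if m.gene == gene and m.variant_class.is_nonsilent and m.codon is not None:
            samples_by_codon.setdefault(m.codon, set()).add(m.sample_id)
    return sum(
        1 for s in samples_by_codon.values() if len(s) >= HOTSPOT_MIN_TUMOURS
    )


def detect_smg(
    cohort: Cohort,
    calls: Sequence[DriverCalls],
    z_threshold: float = Z_OUTLIER,
    fit_intercept: bool = True,
) -> list[SmgRow]:
    """Fit the robust background line overall and per MSI stratum.

    Returns one row per gene with an outlier z-score (>= ``z_threshold``)
    in any analysable stratum, sorted by decreasing overall rate.  A
    stratum in which fewer than 30 genes carry mutations is skipped
    with a warning.
    """
    msi_by_sample = {c.sample_id: c.msi_final for c in calls}
    n_samples = cohort.n_samples
    strata = {}
    for stratum in ("overall", "MSI", "MSS"):
        counts = nonsilent_counts(cohort, stratum, msi_by_sample)
        n_mutated_genes = sum(1 for v in counts.values() if v > 0)
        if n_mutated_genes < 30:
            logger.warning(
                "stratum %s has only %d mutated genes; skipped",
                stratum,
                n_mutated_genes,
            )
            continue
        strata[stratum] = (counts, robust_fit(counts, cohort.catalog, fit_intercept))

    if "overall" not in strata:
        return []
    genes = list(strata["overall"][0])
    z_by = {
        s: dict(zip(genes, fit.z)) for s, (counts, fit) in strata.items()
    }
    overall_counts = strata["overall"][0]

    rows = []
    for g in genes:
        zs = {s: z_by[s].get(g) for s in ("overall", "MSI", "MSS")}
        if not any(z is not None and z >= z_threshold for z in zs.values()):
            continue
        n = overall_counts[g]
        rows.append(
            SmgRow(
                gene=g,
                n_nonsilent=n,
                aa_length=cohort.catalog[g],
                rate=mutation_rate(n, cohort.catalog[g], n_samples),
                z_overall=zs["overall"],
                z_msi=zs["MSI"],
                z_mss=zs["MSS"],
                hotspot_codons=_hotspot_codons(cohort, g),
            )
        )
    rows.sort(key=lambda r: -r.rate)
    return rows


def compare_rates_to_reference(
    rows: Sequence[SmgRow],
    mutated_samples: Mapping[str, int],
    n_samples: int,
    reference_counts: Mapping[str, int],
    reference_n: int,
    alpha: float = 1e-4,
) -> dict[str, tuple[Optional[float], Optional[bool]]]:
    """Two-sided Fisher exact test of mutated-sample proportions vs a
    reference cohort; a gene is discordant when p < ``alpha`` (and the
    reference proportion is lower).  Mutates each row's
    ``discordant_vs_reference``; genes absent from the reference stay
    None with a warning.  Returns gene -> (p, discordant).
    """
    out: dict[str, tuple[Optional[float], Optional[bool]]] = {}
    for row in rows:
        if row.gene not in reference_counts:
            logger.warning("gene %s missing from reference cohort", row.gene)
            out[row.gene] = (None, None)
            continue
        a = mutated_samples.get(row.gene, 0)
        c = reference_counts[row.gene]
        table = [[a, n_samples - a], [c, reference_n - c]]
        p = float(stats.fisher_exact(table)[1])
        discordant = bool(p < alpha and c / reference_n < a / n_samples)
        row.discordant_vs_reference = discordant
        out[row.gene] = (p, discordant)
    return out
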