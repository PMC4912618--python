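"""Domain types and table I/O for tumour-cohort data.

The pipeline consumes three tab-separated tables — per-mutation calls,
per-sample clinical data and a gene catalog (gene -> canonical protein
length) — plus an optional samples x genes log2 expression matrix.  This
module defines the validated in-memory records, the native TSV dialect,
a minimal MAF-column mapping, and the join logic that assembles them
into a :class:`Cohort`.

Protein positions are 1-based codons on one declared canonical isoform
per gene; mutations annotated on a different isoform are kept with
``is_canonical_isoform=False`` rather than dropped at ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "Site",
    "MutationRecord",
    "ClinicalRecord",
    "GeneCatalog",
    "ExpressionMatrix",
    "Cohort",
    "read_mutation_table",
    "write_mutation_table",
    "read_mutation_maf",
    "read_clinical_table",
    "write_clinical_table",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_set_file",
    "assemble_cohort",
]


class VariantClass(str, Enum):
    """Consequence class of a somatic variant on the protein."""

    SILENT = "silent"
    MISSENSE = "missense"
    STOPGAIN = "stopgain"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    OTHER_NONSILENT = "other_nonsilent"

    @property
    def is_silent(self) -> bool:
        return self is VariantClass.SILENT

    @property
    def is_nonsilent(self) -> bool:
        return self is not VariantClass.SILENT

    @property
    def is_truncating(self) -> bool:
        """Stopgain or frameshift — the events that shorten the protein."""
        return self in (VariantClass.STOPGAIN, VariantClass.FRAMESHIFT_INDEL)


class Site(str, Enum):
    """Anatomic site of the primary tumour."""

    CAECUM_ASCENDING = "caecum_ascending"
    TRANSVERSE = "transverse"
    DESCENDING = "descending"
    SIGMOID = "sigmoid"
    RECTOSIGMOID = "rectosigmoid"
    RECTUM = "rectum"
    OTHER = "other"


RIGHT_SIDED_SITES = frozenset({Site.CAECUM_ASCENDING, Site.TRANSVERSE})


@dataclass(frozen=True)
class MutationRecord:
    """One annotated somatic variant call in one sample.

    ``homopolymer_run`` is the reference homopolymer length at the locus
    (0 when the site is not in a homopolymer); ``alt_read_fraction`` is
    the variant allele fraction in [0, 1] when depth information was
    available.
    """

    sample_id: str
    gene: str
    variant_class: VariantClass
    codon: Optional[int] = None
    is_canonical_isoform: bool = True
    alt_read_fraction: Optional[float] = None
    homopolymer_run: int = 0
    population_frequency: Optional[float] = None
    normal_panel_hit: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.variant_class, VariantClass):
            object.__setattr__(
                self, "variant_class", VariantClass(self.variant_class)
            )
        if self.codon is not None and self.codon < 1:
            raise ValueError(
                f"codon must be >=1 when present, got {self.codon!r} "
                f"({self.gene} in {self.sample_id})"
            )
        if self.alt_read_fraction is not None and not (
            0.0 <= self.alt_read_fraction <= 1.0
        ):
            raise ValueError(
                f"alt_read_fraction must lie in [0,1], got "
                f"{self.alt_read_fraction!r} ({self.gene} in {self.sample_id})"
            )
        if self.homopolymer_run < 0:
            raise ValueError("homopolymer_run must be >=0")
        if self.population_frequency is not None and not (
            0.0 <= self.population_frequency <= 1.0
        ):
            raise ValueError("population_frequency must lie in [0,1]")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical annotation, including overall survival."""

    sample_id: str
    age: float
    stage: int
    site: Site = Site.OTHER
    specimen: str = "primary"
    msi_label: Optional[str] = None  # "MSI_H" | "MSS" | None (not assayed)
    distant_met: bool = False
    developed_met: bool = False
    os_months: float = 0.0
    os_event: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.site, Site):
            object.__setattr__(self, "site", Site(self.site))
        if self.stage not in (1, 2, 3, 4):
            raise ValueError(f"stage must be 1-4, got {self.stage!r}")
        if self.specimen not in ("primary", "metastatic"):
            raise ValueError(f"unknown specimen {self.specimen!r}")
        if self.msi_label is not None and self.msi_label not in ("MSI_H", "MSS"):
            raise ValueError(f"msi_label must be MSI_H/MSS, got {self.msi_label!r}")
        if self.os_months < 0:
            raise ValueError("os_months must be >=0")
        if self.age < 0:
            raise ValueError("age must be >=0")
        if self.developed_met and self.stage == 4:
            raise ValueError(
                f"developed_met requires a non-stage-4 diagnosis "
                f"(sample {self.sample_id})"
            )


@dataclass(frozen=True)
class GeneCatalog:
    """Map gene symbol -> amino-acid length of the canonical protein."""

    aa_length: Mapping[str, int]

    def __post_init__(self) -> None:
        for gene, length in self.aa_length.items():
            if length < 1:
                raise ValueError(f"aa_length must be >=1 ({gene}: {length})")

    def __contains__(self, gene: str) -> bool:
        return gene in self.aa_length

    def __len__(self) -> int:
        return len(self.aa_length)

    def __getitem__(self, gene: str) -> int:
        return self.aa_length[gene]

    @property
    def genes(self) -> list[str]:
        return list(self.aa_length)


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of log2 expression values."""

    values: pd.DataFrame  # index = sample ids, columns = gene symbols

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Cohort:
    """Joined mutation + clinical (+ optional expression) tables."""

    mutations: list[MutationRecord]
    clinical: list[ClinicalRecord]
    catalog: GeneCatalog
    expression: Optional[ExpressionMatrix] = None

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.clinical]

    def clinical_by_sample(self) -> dict[str, ClinicalRecord]:
        return {c.sample_id: c for c in self.clinical}

    def mutations_by_sample(self) -> dict[str, list[MutationRecord]]:
        out: dict[str, list[MutationRecord]] = {s: [] for s in self.sample_ids}
        for m in self.mutations:
            out[m.sample_id].append(m)
        return out


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

_MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "variant_class",
    "codon",
    "is_canonical_isoform",
    "alt_read_fraction",
    "homopolymer_run",
    "population_frequency",
    "normal_panel_hit",
]

_CLINICAL_COLUMNS = [
    "sample_id",
    "age",
    "stage",
    "site",
    "specimen",
    "msi_label",
    "distant_met",
    "developed_met",
    "os_months",
    "os_event",
]

#: Minimal MAF column mapping (a subset of standard MAF headers).
MAF_CLASS_MAP = {
    "Silent": VariantClass.SILENT,
    "Missense_Mutation": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.STOPGAIN,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INDEL,
    "In_Frame_Del": VariantClass.INFRAME_INDEL,
    "In_Frame_Ins": VariantClass.INFRAME_INDEL,
    "Splice_Site": VariantClass.SPLICE,
    "Nonstop_Mutation": VariantClass.OTHER_NONSILENT,
    "Translation_Start_Site": VariantClass.OTHER_NONSILENT,
}


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing mandatory column(s): {missing}")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    v = _opt_float(value)
    return None if v is None else int(v)


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(int(value))
    s = str(value).strip().lower()
    if s in ("true", "t", "1", "yes"):
        return True
    if s in ("false", "f", "0", "no", ""):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_mutation_table(path, dialect: str = "native") -> list[MutationRecord]:
    """Read a per-mutation TSV.

    ``dialect`` is ``"native"`` (the reference column set written by
    :func:`write_mutation_table`) or ``"maf"`` (see
    :func:`read_mutation_maf`).  Unparsable codon fields become absent
    codons with a logged warning count; an unknown variant class is a
    hard error listing the offending values.
    """
    if dialect == "maf":
        return read_mutation_maf(path)
    if dialect != "native":
        raise ValueError(f"unknown mutation-table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["sample_id", "gene", "variant_class"], "mutation table")
    known = {v.value for v in VariantClass}
    bad = sorted(set(df["variant_class"]) - known)
    if bad:
        raise ValueError(f"unknown variant class value(s): {bad}")

    records: list[MutationRecord] = []
    n_bad_codon = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        codon: Optional[int]
        try:
            codon = _opt_int(d.get("codon"))
        except (ValueError, TypeError):
            codon = None
            n_bad_codon += 1
        records.append(
            MutationRecord(
                sample_id=d["sample_id"],
                gene=d["gene"],
                variant_class=VariantClass(d["variant_class"]),
                codon=codon,
                is_canonical_isoform=_as_bool(d.get("is_canonical_isoform", True)),
                alt_read_fraction=_opt_float(d.get("alt_read_fraction")),
                homopolymer_run=_opt_int(d.get("homopolymer_run")) or 0,
                population_frequency=_opt_float(d.get("population_frequency")),
                normal_panel_hit=_as_bool(d.get("normal_panel_hit", False)),
            )
        )
    if n_bad_codon:
        logger.warning("%d codon field(s) were unparsable and set absent", n_bad_codon)
    return records


def write_mutation_table(records: Sequence[MutationRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "variant_class": r.variant_class.value,
                "codon": "" if r.codon is None else str(r.codon),
                "is_canonical_isoform": str(r.is_canonical_isoform),
                "alt_read_fraction": ""
                if r.alt_read_fraction is None
                else repr(r.alt_read_fraction),
                "homopolymer_run": str(r.homopolymer_run),
                "population_frequency": ""
                if r.population_frequency is None
                else repr(r.population_frequency),
                "normal_panel_hit": str(r.normal_panel_hit),
            }
        )
    pd.DataFrame(rows, columns=_MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_maf(path) -> list[MutationRecord]:
    """Read the minimal MAF column subset.

    Uses Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification,
    Protein_position and (when present) t_alt_count/t_depth for the
    variant allele fraction.  MAF classes outside :data:`MAF_CLASS_MAP`
    are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    _require_columns(
        df,
        ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"],
        "MAF table",
    )
    bad = sorted(set(df["Variant_Classification"]) - set(MAF_CLASS_MAP))
    if bad:
        raise ValueError(f"unknown MAF Variant_Classification value(s): {bad}")
    records = []
    n_bad_codon = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        codon: Optional[int] = None
        raw = str(d.get("Protein_position", "")).strip()
        if raw:
            try:
                # MAF styles: "123", "123/766", "123-125"
                codon = int(raw.split("/")[0].split("-")[0])
            except ValueError:
                n_bad_codon += 1
        vaf = None
        try:
            alt = _opt_float(d.get("t_alt_count"))
            depth = _opt_float(d.get("t_depth"))
            if alt is not None and depth:
                vaf = alt / depth
        except (ValueError, TypeError):
            pass
        records.append(
            MutationRecord(
                sample_id=d["Tumor_Sample_Barcode"],
                gene=d["Hugo_Symbol"],
                variant_class=MAF_CLASS_MAP[d["Variant_Classification"]],
                codon=codon,
                alt_read_fraction=vaf,
            )
        )
    if n_bad_codon:
        logger.warning("%d MAF Protein_position field(s) unparsable", n_bad_codon)
    return records


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["sample_id", "age", "stage", "os_months", "os_event"], "clinical table"
    )
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        msi = str(d.get("msi_label", "")).strip() or None
        records.append(
            ClinicalRecord(
                sample_id=d["sample_id"],
                age=float(d["age"]),
                stage=int(d["stage"]),
                site=Site(d.get("site", "other") or "other"),
                specimen=d.get("specimen", "primary") or "primary",
                msi_label=msi,
                distant_met=_as_bool(d.get("distant_met", False)),
                developed_met=_as_bool(d.get("developed_met", False)),
                os_months=float(d["os_months"]),
                os_event=_as_bool(d["os_event"]),
            )
        )
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    rows = []
    for c in records:
        rows.append(
            {
                "sample_id": c.sample_id,
                "age": repr(float(c.age)),
                "stage": str(c.stage),
                "site": c.site.value,
                "specimen": c.specimen,
                "msi_label": c.msi_label or "",
                "distant_met": str(c.distant_met),
                "developed_met": str(c.developed_met),
                "os_months": repr(float(c.os_months)),
                "os_event": str(c.os_event),
            }
        )
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_catalog(path) -> GeneCatalog:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "aa_length"], "gene catalog")
    if df["gene"].duplicated().any():
        dupes = sorted(df.loc[df["gene"].duplicated(), "gene"])
        raise ValueError(f"duplicate gene(s) in catalog: {dupes}")
    return GeneCatalog(dict(zip(df["gene"], df["aa_length"].astype(int))))


def write_gene_catalog(catalog: GeneCatalog, path) -> None:
    pd.DataFrame(
        {"gene": list(catalog.aa_length), "aa_length": list(catalog.aa_length.values())}
    ).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_gene_set_file(path) -> list[str]:
    """One gene symbol per line; '#' starts a comment."""
    genes = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if sym:
                genes.append(sym)
    return genes


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_cohort(
    mutations: Sequence[MutationRecord],
    clinical: Sequence[ClinicalRecord],
    catalog: GeneCatalog,
    expression: Optional[ExpressionMatrix] = None,
) -> Cohort:
    """Join the tables into a :class:`Cohort`.

    Every mutation's sample must appear in the clinical table (orphans
    are a hard error listing the ids).  Exact-duplicate mutation rows
    collapse to one with a logged count; same-codon different-class
    rows are distinct events and are kept.
    """
    clin_ids = {c.sample_id for c in clinical}
    if len(clin_ids) != len(clinical):
        raise ValueError("duplicate sample_id in clinical table")
    orphans = sorted({m.sample_id for m in mutations} - clin_ids)
    if orphans:
        raise ValueError(f"mutation sample_id(s) absent from clinical table: {orphans}")

    seen: set = set()
    deduped: list[MutationRecord] = []
    for m in mutations:
        key = m  # frozen dataclass: exact-row identity
        if key in seen:
            continue
        seen.add(key)
        deduped.append(m)
    n_dropped = len(mutations) - len(deduped)
    if n_dropped:
        logger.info("collapsed %d exact-duplicate mutation row(s)", n_dropped)

    if expression is not None:
        stray = sorted(set(expression.samples) - clin_ids)
        if stray:
            raise ValueError(
                f"expression sample id(s) absent from clinical table: {stray}"
            )
    return Cohort(
        mutations=deduped,
        clinical=list(clinical),
        catalog=catalog,
        expression=expression,
    )
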