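"""Somatic-alteration profiles for paired intra-/extrathoracic tumors.

A patient presenting with both a lung (T1) and an extrathoracic (T2) tumor
contributes one :class:`TumorProfile` per lesion, each a list of called
somatic alterations from panel sequencing (SNVs, small indels,
rearrangements, splice variants, and copy-number events). Clonality
inference downstream hinges on which alterations the two profiles *share*;
:func:`match_alterations` operationalizes sharing with category-specific
identity rules.

I/O uses a MAF-like tab-separated table (one alteration per row, ``.`` for
missing values) or, optionally, VCF 4.2 with the non-positional fields
carried in INFO keys.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "Category",
    "Site",
    "MSIStatus",
    "Alteration",
    "TumorProfile",
    "CasePair",
    "ProfileFormatError",
    "RecordError",
    "read_profile",
    "read_profile_vcf",
    "write_profile",
    "match_alterations",
]


class ProfileFormatError(ValueError):
    """The input table does not conform to the expected schema."""


class RecordError(ValueError):
    """A single row/record is malformed (carries the offending row index)."""


class Category(str, enum.Enum):
    """Alteration classes reported by targeted panel sequencing."""

    SNV = "SNV"
    SMALL_INDEL = "small_indel"
    REARRANGEMENT = "rearrangement"
    SPLICE_VARIANT = "splice_variant"
    # Copy-number events appear in panel reports; they are accepted and
    # matched on (gene, direction) like any other alteration.
    AMPLIFICATION = "amplification"
    COPY_LOSS = "copy_loss"


class Site(str, enum.Enum):
    """Tumor anatomical sites handled by the pipeline."""

    LUNG = "lung"
    STOMACH = "stomach"
    COLON_RECTUM = "colon_rectum"
    CERVIX = "cervix"


class MSIStatus(str, enum.Enum):
    MSS = "MSS"
    MSI = "MSI"
    UNKNOWN = "unknown"


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_rank(chrom: str) -> int:
    c = chrom.removeprefix("chr")
    return _CHROM_ORDER.get(c, 100)


@dataclass(frozen=True)
class Alteration:
    """One somatic alteration.

    Coordinates are 1-based (MAF/VCF convention). ``ref``/``alt`` are empty
    for rearrangements and copy-number events; ``partner_gene`` is set for
    rearrangements only.
    """

    category: Category
    gene: str
    chrom: str
    pos: int
    ref: str = ""
    alt: str = ""
    partner_gene: Optional[str] = None
    protein_change: Optional[str] = None
    allele_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.category is Category.REARRANGEMENT) != (self.partner_gene is not None):
            raise ValueError(
                "partner_gene must be set if and only if category is rearrangement "
                f"(got category={self.category.value}, partner_gene={self.partner_gene})"
            )
        if self.category is Category.SNV and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError(f"SNV requires single-base ref/alt, got {self.ref!r}>{self.alt!r}")
        if self.allele_fraction is not None and not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele_fraction out of [0,1]: {self.allele_fraction}")
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")

    @property
    def match_key(self) -> tuple:
        """Identity used to decide whether two tumors share this alteration.

        SNVs/indels: exact genomic change (gene, chrom, pos, ref, alt).
        Splice variants: (gene, chrom, pos) — the affected junction.
        Rearrangements: unordered gene pair, breakpoints ignored (panel
        breakpoints of the same fusion vary between samples).
        Copy-number: (gene, direction).
        """
        if self.category is Category.REARRANGEMENT:
            return ("fusion", frozenset((self.gene, self.partner_gene)))
        if self.category is Category.SPLICE_VARIANT:
            return ("splice", self.gene, self.chrom, self.pos)
        if self.category in (Category.AMPLIFICATION, Category.COPY_LOSS):
            return ("cna", self.category.value, self.gene)
        return ("seq", self.gene, self.chrom, self.pos, self.ref, self.alt)

    @property
    def genomic_order(self) -> tuple:
        return (_chrom_rank(self.chrom), self.pos, self.gene)


@dataclass
class TumorProfile:
    """All called alterations of one tumor sample."""

    patient_id: str
    site: Site
    detection_month: int
    alterations: list[Alteration] = field(default_factory=list)
    msi_status: MSIStatus = MSIStatus.UNKNOWN

    def __post_init__(self) -> None:
        self.site = Site(self.site)
        self.msi_status = MSIStatus(self.msi_status)
        if self.detection_month < 0:
            raise ValueError("detection_month must be >= 0")

    def deduplicated(self) -> "TumorProfile":
        """Collapse duplicate rows (one biological event, one record)."""
        seen: dict[tuple, Alteration] = {}
        for a in self.alterations:
            seen.setdefault(a.match_key, a)
        return replace(self, alterations=list(seen.values()))

    def __len__(self) -> int:
        return len(self.alterations)


@dataclass
class CasePair:
    """A paired case: intrathoracic tumor (T1, lung) vs extrathoracic (T2)."""

    patient_id: str
    t1: TumorProfile
    t2: TumorProfile

    def __post_init__(self) -> None:
        if self.t1.site is not Site.LUNG:
            raise ValueError("t1 must be the lung (intrathoracic) tumor")
        if self.t2.site is Site.LUNG:
            raise ValueError("t2 must be extrathoracic (site != lung)")

    @property
    def interval_months(self) -> int:
        return abs(self.t1.detection_month - self.t2.detection_month)


REQUIRED_COLUMNS = [
    "patient_id",
    "site",
    "category",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "partner_gene",
    "protein_change",
    "allele_fraction",
]


def _row_to_alteration(row: pd.Series, idx: int) -> Alteration:
    try:
        category = Category(str(row["category"]))
    except ValueError as exc:
        raise RecordError(f"row {idx}: unknown category token {row['category']!r}") from exc

    def opt(name):
        v = row[name]
        return None if pd.isna(v) or v == "." or v == "" else v

    try:
        return Alteration(
            category=category,
            gene=str(row["gene"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref="" if opt("ref") is None else str(row["ref"]),
            alt="" if opt("alt") is None else str(row["alt"]),
            partner_gene=None if opt("partner_gene") is None else str(row["partner_gene"]),
            protein_change=None if opt("protein_change") is None else str(row["protein_change"]),
            allele_fraction=None if opt("allele_fraction") is None else float(row["allele_fraction"]),
        )
    except ValueError as exc:
        raise RecordError(f"row {idx}: {exc}") from exc


def read_profile(
    path: str | Path,
    patient_id: Optional[str] = None,
    site: Optional[Site | str] = None,
    detection_month: int = 0,
    msi_status: MSIStatus | str = MSIStatus.UNKNOWN,
) -> TumorProfile:
    """Read a MAF-like TSV into a :class:`TumorProfile`.

    ``patient_id``/``site`` default to the (unique) values found in the
    table; pass them explicitly for header-only files.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if patient_id is None or site is None:
        if df.empty:
            raise ProfileFormatError(
                f"{path}: empty table; pass patient_id and site explicitly"
            )
        pids = df["patient_id"].unique()
        sites = df["site"].unique()
        if len(pids) > 1 or len(sites) > 1:
            raise ProfileFormatError(f"{path}: multiple patient_id/site values in one profile")
        patient_id = patient_id or str(pids[0])
        site = site or str(sites[0])
    alterations = [_row_to_alteration(row, i) for i, row in df.iterrows()]
    return TumorProfile(
        patient_id=patient_id,
        site=Site(site),
        detection_month=detection_month,
        alterations=alterations,
        msi_status=MSIStatus(msi_status),
    )


def write_profile(profile: TumorProfile, path: str | Path) -> None:
    """Write a profile as a MAF-like TSV (inverse of :func:`read_profile`)."""
    rows = []
    for a in profile.alterations:
        rows.append(
            {
                "patient_id": profile.patient_id,
                "site": profile.site.value,
                "category": a.category.value,
                "gene": a.gene,
                "chrom": a.chrom,
                "pos": a.pos,
                "ref": a.ref if a.ref else ".",
                "alt": a.alt if a.alt else ".",
                "partner_gene": a.partner_gene if a.partner_gene else ".",
                "protein_change": a.protein_change if a.protein_change else ".",
                "allele_fraction": "." if a.allele_fraction is None else repr(a.allele_fraction),
            }
        )
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_profile_vcf(
    path: str | Path,
    patient_id: str,
    site: Site | str,
    detection_month: int = 0,
    msi_status: MSIStatus | str = MSIStatus.UNKNOWN,
) -> TumorProfile:
    """Read a VCF 4.2 file; INFO/CAT, GENE, PARTNER, HGVSP, AF carry the
    non-positional fields."""
    from cyvcf2 import VCF  # optional dependency

    alterations = []
    for i, variant in enumerate(VCF(str(path))):
        cat_token = variant.INFO.get("CAT")
        if cat_token is None:
            raise RecordError(f"record {i}: missing INFO/CAT")
        try:
            category = Category(cat_token)
        except ValueError as exc:
            raise RecordError(f"record {i}: unknown category token {cat_token!r}") from exc
        seq_like = category in (Category.SNV, Category.SMALL_INDEL, Category.SPLICE_VARIANT)
        af = variant.INFO.get("AF")
        alterations.append(
            Alteration(
                category=category,
                gene=str(variant.INFO.get("GENE")),
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref=str(variant.REF) if seq_like else "",
                alt=str(variant.ALT[0]) if (seq_like and variant.ALT) else "",
                partner_gene=variant.INFO.get("PARTNER"),
                protein_change=variant.INFO.get("HGVSP"),
                allele_fraction=None if af is None else float(af),
            )
        )
    return TumorProfile(
        patient_id=patient_id,
        site=Site(site),
        detection_month=detection_month,
        alterations=alterations,
        msi_status=MSIStatus(msi_status),
    )


def match_alterations(
    t1: TumorProfile | Iterable[Alteration],
    t2: TumorProfile | Iterable[Alteration],
) -> list[tuple[Alteration, Alteration]]:
    """Shared alterations between two tumors.

    Duplicates within each profile are collapsed first, so each alteration
    participates in at most one match. Pairs are returned in genomic order
    of the T1 member.
    """
    def dedup(alts: Iterable[Alteration]) -> list[Alteration]:
        seen: dict[tuple, Alteration] = {}
        for a in alts:
            seen.setdefault(a.match_key, a)
        return list(seen.values())

    a1 = dedup(t1.alterations if isinstance(t1, TumorProfile) else t1)
    a2 = dedup(t2.alterations if isinstance(t2, TumorProfile) else t2)
    index2: dict[tuple, Alteration] = {}
    for a in a2:
        index2.setdefault(a.match_key, a)
    pairs = [(a, index2[a.match_key]) for a in a1 if a.match_key in index2]
    pairs.sort(key=lambda p: p[0].genomic_order)
    return pairs
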