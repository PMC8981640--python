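"""Clonality and tissue-of-origin inference from paired genomic profiles.

The decision cascade, evaluated strictly in order on a lung/extrathoracic
tumor pair:

1. zero shared alterations            -> independent multiple primaries (Class I)
2. shared actionable lung driver      -> metastatic, lung origin (Class I)
   (actionable EGFR mutations or deletions, or ALK/ROS1 rearrangements —
   drivers so lung-specific that sharing one implies a lung-origin clone)
3. clonality criteria not met         -> relationship inconclusive
4. criteria met, interval >= 6 months -> metastatic from the organ of the
   earlier-detected tumor (Class II; the metachronous time-lag rule)
5. criteria met, interval < 6 months  -> metastatic, origin inconclusive (Class III)

Clonality criteria: (i) both tumors harbor >= 5 alterations of which >= 2
are shared, or (ii) either tumor harbors < 5 alterations and >= 1 is shared.

Class I cases are resolved by genomics alone, Class II need the clinical
time lag, Class III (and relationship-inconclusive cases) are routed to the
methylation classifier downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .profiles import (
    Alteration,
    CasePair,
    Category,
    MSIStatus,
    Site,
    match_alterations,
)

__all__ = [
    "Relationship",
    "TOO",
    "ClassLabel",
    "Evidence",
    "DriverWhitelist",
    "CGPInference",
    "CohortSummary",
    "shares_actionable_driver",
    "meets_clonality_criteria",
    "infer_relationship",
    "cgp_lesion_labels",
    "summarize_cohort",
    "METACHRONOUS_THRESHOLD_MONTHS",
]

METACHRONOUS_THRESHOLD_MONTHS = 6


class Relationship(str, enum.Enum):
    MULTIPLE_PRIMARY = "multiple_primary"
    METASTATIC = "metastatic"
    INCONCLUSIVE_RELATIONSHIP = "inconclusive_relationship"


class TOO(str, enum.Enum):
    LUNG = "lung"
    STOMACH = "stomach"
    COLON_RECTUM = "colon_rectum"
    CERVIX = "cervix"
    INCONCLUSIVE = "inconclusive"
    NOT_APPLICABLE = "not_applicable"


class ClassLabel(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    NONE = "none"


class Evidence(str, enum.Enum):
    ZERO_SHARED = "zero_shared"
    SHARED_DRIVER = "shared_driver"
    CLONALITY_CRITERIA_PLUS_TIME_LAG = "clonality_criteria_plus_time_lag"
    CLONALITY_CRITERIA_ONLY = "clonality_criteria_only"
    CRITERIA_NOT_MET = "criteria_not_met"


# Standard actionable EGFR point mutations; exon-19 in-frame deletions and
# exon-20 insertions are covered by accepting any EGFR small indel.
DEFAULT_EGFR_PROTEIN_CHANGES = frozenset(
    {"L858R", "L861Q", "G719A", "G719C", "G719S", "S768I", "T790M"}
)


def _norm_protein(p: Optional[str]) -> Optional[str]:
    if p is None:
        return None
    return p.removeprefix("p.").strip()


@dataclass
class DriverWhitelist:
    """Alterations so specific to lung cancer that sharing one between the
    two lesions implies a lung-origin clonal pair."""

    egfr_protein_changes: frozenset[str] = DEFAULT_EGFR_PROTEIN_CHANGES
    egfr_categories: frozenset[Category] = frozenset({Category.SMALL_INDEL})
    fusion_genes: frozenset[str] = frozenset({"ALK", "ROS1"})

    def is_driver(self, a: Alteration) -> bool:
        if a.category is Category.REARRANGEMENT:
            return bool({a.gene, a.partner_gene} & self.fusion_genes)
        if a.gene == "EGFR":
            if a.category in self.egfr_categories:
                return True
            return _norm_protein(a.protein_change) in self.egfr_protein_changes
        return False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DriverWhitelist":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "egfr_protein_changes" in raw:
            kwargs["egfr_protein_changes"] = frozenset(raw["egfr_protein_changes"])
        if "egfr_categories" in raw:
            kwargs["egfr_categories"] = frozenset(Category(c) for c in raw["egfr_categories"])
        if "fusion_genes" in raw:
            kwargs["fusion_genes"] = frozenset(raw["fusion_genes"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "egfr_protein_changes": sorted(self.egfr_protein_changes),
                    "egfr_categories": sorted(c.value for c in self.egfr_categories),
                    "fusion_genes": sorted(self.fusion_genes),
                },
                fh,
            )


@dataclass
class CGPInference:
    """Outcome of the decision cascade for one patient."""

    patient_id: str
    relationship: Relationship
    too: TOO
    class_label: ClassLabel
    evidence: Evidence
    shared_count: int
    n1: int
    n2: int
    extra_site: Site
    driver: Optional[Alteration] = None
    interval_months: int = 0
    msi_t1: MSIStatus = MSIStatus.UNKNOWN
    msi_t2: MSIStatus = MSIStatus.UNKNOWN
    # criterion (ii) is read as "at least one tumor harbored < 5 alterations"
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "relationship": self.relationship.value,
            "too": self.too.value,
            "class_label": self.class_label.value,
            "evidence": self.evidence.value,
            "shared_count": self.shared_count,
            "n1": self.n1,
            "n2": self.n2,
            "extra_site": self.extra_site.value,
            "driver_gene": None if self.driver is None else self.driver.gene,
            "interval_months": self.interval_months,
            "msi_t1": self.msi_t1.value,
            "msi_t2": self.msi_t2.value,
            "notes": self.notes,
        }


def shares_actionable_driver(
    shared: Sequence[tuple[Alteration, Alteration]],
    wl: Optional[DriverWhitelist] = None,
) -> tuple[bool, Optional[Alteration]]:
    """First whitelist driver (in genomic order) among the shared pairs."""
    wl = wl or DriverWhitelist()
    hits = [a for a, _ in shared if wl.is_driver(a)]
    if not hits:
        return False, None
    return True, min(hits, key=lambda a: a.genomic_order)


def meets_clonality_criteria(n1: int, n2: int, n_shared: int) -> bool:
    """Profile-similarity test applied before the time-lag rule."""
    if not 0 <= n_shared <= min(n1, n2):
        raise ValueError(f"n_shared={n_shared} exceeds min(n1={n1}, n2={n2})")
    return (n1 >= 5 and n2 >= 5 and n_shared >= 2) or ((n1 < 5 or n2 < 5) and n_shared >= 1)


def infer_relationship(
    case: CasePair,
    wl: Optional[DriverWhitelist] = None,
    metachronous_threshold: int = METACHRONOUS_THRESHOLD_MONTHS,
) -> CGPInference:
    """Run the full decision cascade on a paired case."""
    wl = wl or DriverWhitelist()
    t1 = case.t1.deduplicated()
    t2 = case.t2.deduplicated()
    shared = match_alterations(t1, t2)
    n1, n2, n_shared = len(t1), len(t2), len(shared)

    common = dict(
        patient_id=case.patient_id,
        shared_count=n_shared,
        n1=n1,
        n2=n2,
        extra_site=t2.site,
        interval_months=case.interval_months,
        msi_t1=t1.msi_status,
        msi_t2=t2.msi_status,
    )

    if n_shared == 0:
        return CGPInference(
            relationship=Relationship.MULTIPLE_PRIMARY,
            too=TOO.NOT_APPLICABLE,
            class_label=ClassLabel.I,
            evidence=Evidence.ZERO_SHARED,
            **common,
        )

    has_driver, driver = shares_actionable_driver(shared, wl)
    if has_driver:
        return CGPInference(
            relationship=Relationship.METASTATIC,
            too=TOO.LUNG,
            class_label=ClassLabel.I,
            evidence=Evidence.SHARED_DRIVER,
            driver=driver,
            **common,
        )

    if not meets_clonality_criteria(n1, n2, n_shared):
        return CGPInference(
            relationship=Relationship.INCONCLUSIVE_RELATIONSHIP,
            too=TOO.INCONCLUSIVE,
            class_label=ClassLabel.NONE,
            evidence=Evidence.CRITERIA_NOT_MET,
            **common,
        )

    if case.interval_months >= metachronous_threshold:
        earlier = t1 if t1.detection_month < t2.detection_month else t2
        return CGPInference(
            relationship=Relationship.METASTATIC,
            too=TOO(earlier.site.value),
            class_label=ClassLabel.II,
            evidence=Evidence.CLONALITY_CRITERIA_PLUS_TIME_LAG,
            **common,
        )

    return CGPInference(
        relationship=Relationship.METASTATIC,
        too=TOO.INCONCLUSIVE,
        class_label=ClassLabel.III,
        evidence=Evidence.CLONALITY_CRITERIA_ONLY,
        **common,
    )


def cgp_lesion_labels(inf: CGPInference) -> tuple[str, str]:
    """Per-lesion primary (P) / metastasis (M) labels implied by a cascade
    outcome, as printed in per-patient report tables.

    Returns ``(lung_label, extra_label)``; inconclusive origins yield
    ``("Inconclusive", "Inconclusive")``.
    """
    if inf.relationship is Relationship.MULTIPLE_PRIMARY:
        return "P", "P"
    if inf.relationship is Relationship.METASTATIC:
        if inf.too is TOO.LUNG:
            return "P", "M"
        if inf.too is TOO.INCONCLUSIVE:
            return "Inconclusive", "Inconclusive"
        return "M", "P"
    return "Inconclusive", "Inconclusive"


@dataclass
class CohortSummary:
    n: int
    clonality_conclusive: int
    too_cgp_alone: int          # Class I
    too_with_time_lag: int      # Classes I + II
    class_counts: dict[str, int]

    @property
    def clonality_rate(self) -> float:
        return self.clonality_conclusive / self.n

    @property
    def too_cgp_alone_rate(self) -> float:
        return self.too_cgp_alone / self.n

    @property
    def too_with_time_lag_rate(self) -> float:
        return self.too_with_time_lag / self.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "clonality_conclusive": self.clonality_conclusive,
            "too_cgp_alone": self.too_cgp_alone,
            "too_with_time_lag": self.too_with_time_lag,
            "class_counts": self.class_counts,
        }


def summarize_cohort(inferences: Sequence[CGPInference]) -> CohortSummary:
    """Cohort-level conclusiveness rates of the cascade."""
    if not inferences:
        raise ValueError("summarize_cohort requires a non-empty list")
    class_counts = {c.value: 0 for c in ClassLabel}
    clonality = 0
    for inf in inferences:
        class_counts[inf.class_label.value] += 1
        if inf.relationship is not Relationship.INCONCLUSIVE_RELATIONSHIP:
            clonality += 1
    n_i = class_counts[ClassLabel.I.value]
    n_ii = class_counts[ClassLabel.II.value]
    return CohortSummary(
        n=len(inferences),
        clonality_conclusive=clonality,
        too_cgp_alone=n_i,
        too_with_time_lag=n_i + n_ii,
        class_counts=class_counts,
    )
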