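"""Integration of the genomic cascade with methylation-based calls.

Genomic profiling runs first; its Class I/II outcomes are final. Only cases
the cascade leaves unresolved (metastatic with inconclusive origin, or
relationship-inconclusive) fall through to the DNA-methylation classifier.
Cross-method concordance is tallied over patients whose origin both tracks
resolve independently.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .cgp import CGPInference, ClassLabel, Evidence, Relationship, TOO
from .profiles import Site

__all__ = [
    "LesionLabel",
    "EvidenceSource",
    "PatientDiagnosis",
    "integrate",
    "concordance",
]

logger = logging.getLogger(__name__)


class LesionLabel(str, enum.Enum):
    P = "P"
    M = "M"
    UNAVAILABLE = "unavailable"


class EvidenceSource(str, enum.Enum):
    CGP_DRIVER = "cgp_driver"
    CGP_ZERO_SHARED = "cgp_zero_shared"
    CGP_TIME_LAG = "cgp_time_lag"
    METHYLATION = "methylation"
    UNRESOLVED = "unresolved"


class DiagnosisRelationship(str, enum.Enum):
    MULTIPLE_PRIMARY = "multiple_primary"
    METASTATIC = "metastatic"
    INDETERMINATE = "indeterminate"
    NOT_EVALUABLE = "not_evaluable"


@dataclass
class PatientDiagnosis:
    """Final per-patient call: per-lesion P/M labels, clonality and origin."""

    patient_id: str
    lung_label: LesionLabel
    extra_label: LesionLabel
    extra_site: Site
    relationship: DiagnosisRelationship
    too: TOO
    evidence_source: EvidenceSource
    notes: dict = field(default_factory=dict)

    @property
    def lesion_labels(self) -> dict[str, str]:
        return {"lung": self.lung_label.value, self.extra_site.value: self.extra_label.value}

    @property
    def conclusive(self) -> bool:
        """Both clonality and (where applicable) origin are resolved."""
        return self.relationship in (
            DiagnosisRelationship.MULTIPLE_PRIMARY,
            DiagnosisRelationship.METASTATIC,
        ) and self.too is not TOO.INCONCLUSIVE

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "lung_label": self.lung_label.value,
            "extra_label": self.extra_label.value,
            "extra_site": self.extra_site.value,
            "relationship": self.relationship.value,
            "too": self.too.value,
            "evidence_source": self.evidence_source.value,
            "notes": self.notes,
        }


_CGP_EVIDENCE_MAP = {
    Evidence.ZERO_SHARED: EvidenceSource.CGP_ZERO_SHARED,
    Evidence.SHARED_DRIVER: EvidenceSource.CGP_DRIVER,
    Evidence.CLONALITY_CRITERIA_PLUS_TIME_LAG: EvidenceSource.CGP_TIME_LAG,
}


def diagnosis_from_cgp(inf: CGPInference) -> PatientDiagnosis:
    """Translate a conclusive (Class I/II) cascade outcome into a diagnosis."""
    from .cgp import cgp_lesion_labels

    lung, extra = cgp_lesion_labels(inf)
    rel = {
        Relationship.MULTIPLE_PRIMARY: DiagnosisRelationship.MULTIPLE_PRIMARY,
        Relationship.METASTATIC: DiagnosisRelationship.METASTATIC,
        Relationship.INCONCLUSIVE_RELATIONSHIP: DiagnosisRelationship.INDETERMINATE,
    }[inf.relationship]
    return PatientDiagnosis(
        patient_id=inf.patient_id,
        lung_label=LesionLabel(lung) if lung in ("P", "M") else LesionLabel.UNAVAILABLE,
        extra_label=LesionLabel(extra) if extra in ("P", "M") else LesionLabel.UNAVAILABLE,
        extra_site=inf.extra_site,
        relationship=rel,
        too=inf.too,
        evidence_source=_CGP_EVIDENCE_MAP.get(inf.evidence, EvidenceSource.UNRESOLVED),
    )


def integrate(
    cgp: Optional[CGPInference],
    methyl: Optional[PatientDiagnosis],
) -> PatientDiagnosis:
    """Combine the two tracks for one patient.

    Class I/II genomic outcomes are adopted as-is; otherwise the
    methylation diagnosis (when available) decides; otherwise the case is
    left unresolved, carrying through whatever clonality the cascade
    established.
    """
    if cgp is None and methyl is None:
        raise ValueError("integrate requires at least one of cgp, methyl")

    if cgp is not None and cgp.class_label in (ClassLabel.I, ClassLabel.II):
        return diagnosis_from_cgp(cgp)

    if methyl is not None:
        result = replace(methyl, notes=dict(methyl.notes))
        if cgp is not None:
            if (
                cgp.relationship is Relationship.METASTATIC
                and methyl.relationship is DiagnosisRelationship.MULTIPLE_PRIMARY
            ):
                # Methylation overrides the cascade's clonality call, but the
                # disagreement is surfaced rather than silently dropped.
                logger.info(
                    "patient %s: genomic profiles meet clonality criteria but "
                    "methylation labels both lesions primary; methylation wins",
                    methyl.patient_id,
                )
                result.notes["clonality_discordance"] = "cgp_clonal_vs_methyl_independent"
            if methyl.relationship is DiagnosisRelationship.NOT_EVALUABLE:
                # Single-sample methylation: lesion label only; the cascade's
                # relationship (conclusive or not) stands.
                rel = {
                    Relationship.MULTIPLE_PRIMARY: DiagnosisRelationship.MULTIPLE_PRIMARY,
                    Relationship.METASTATIC: DiagnosisRelationship.METASTATIC,
                    Relationship.INCONCLUSIVE_RELATIONSHIP: DiagnosisRelationship.INDETERMINATE,
                }[cgp.relationship]
                result.relationship = rel
        return result

    assert cgp is not None
    rel = {
        Relationship.METASTATIC: DiagnosisRelationship.METASTATIC,
        Relationship.MULTIPLE_PRIMARY: DiagnosisRelationship.MULTIPLE_PRIMARY,
        Relationship.INCONCLUSIVE_RELATIONSHIP: DiagnosisRelationship.INDETERMINATE,
    }[cgp.relationship]
    return PatientDiagnosis(
        patient_id=cgp.patient_id,
        lung_label=LesionLabel.UNAVAILABLE,
        extra_label=LesionLabel.UNAVAILABLE,
        extra_site=cgp.extra_site,
        relationship=rel,
        too=TOO.INCONCLUSIVE,
        evidence_source=EvidenceSource.UNRESOLVED,
    )


def concordance(
    cgp_diagnoses: Mapping[str, CGPInference],
    methyl_diagnoses: Mapping[str, PatientDiagnosis],
) -> tuple[int, int]:
    """(n_comparable, n_concordant) between the two tracks.

    Comparable: patients whose origin is conclusively resolved by the
    genomic track on its own terms (Class I or II) *and* by methylation
    (a non-indeterminate two-sample diagnosis). Concordant: comparable
    patients with equal relationship and equal origin.
    """
    comparable = 0
    concordant = 0
    for pid, inf in cgp_diagnoses.items():
        if inf.class_label not in (ClassLabel.I, ClassLabel.II):
            continue
        methyl = methyl_diagnoses.get(pid)
        if methyl is None or not methyl.conclusive:
            continue
        comparable += 1
        cgp_diag = diagnosis_from_cgp(inf)
        if cgp_diag.relationship is methyl.relationship and cgp_diag.too is methyl.too:
            concordant += 1
    return comparable, concordant
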