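"""The built-in 16-patient reference cohort.

The packaged JSON records, per patient: the inter-tumor time lag
(synchronous vs metachronous), the extrathoracic site, the category of
genomic evidence (zero shared alterations; a shared actionable lung driver;
clonality criteria met), the printed per-lesion Methyl Scores (29 in all —
14 patients with both lesions profiled, one with a single gastric sample,
one with none), and the expected per-lesion labels of each analysis track.

Per-patient alteration *lists* are not part of the record (only their
category is), so :func:`fixture_case_pairs` materializes each patient's
category into a concrete paired profile through the synthetic generator;
the decision cascade is then run on real :class:`~too_integrate.profiles.CasePair`
objects rather than on pre-baked answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .cgp import DriverWhitelist, CGPInference, infer_relationship
from .integrate import PatientDiagnosis
from .methylation import call_from_score, infer_patient_from_scores
from .profiles import CasePair, MSIStatus, Site
from .synthetic import (
    EGFR_EXON19_DEL,
    EGFR_L858R,
    EML4_ALK_FUSION,
    Scenario,
    ScenarioSpec,
    gen_cgp_case,
)

__all__ = [
    "FixturePatient",
    "cohort_fixture",
    "fixture_case_pairs",
    "fixture_methyl_results",
    "fixture_methyl_diagnoses",
]

_DRIVERS = {
    "egfr_snv": EGFR_L858R,
    "egfr_exon19del": EGFR_EXON19_DEL,
    "alk_fusion": EML4_ALK_FUSION,
}

# Alteration-count stubs per evidence category. Per-patient totals are not
# individually recorded in the source table; these satisfy the relevant
# branch of the cascade for every patient of the category.
_COUNT_STUBS = {
    "zero_shared": dict(n1=7, n2=9, n_shared=0),
    "shared_driver": dict(n1=8, n2=6, n_shared=2),
    "criteria_met": dict(n1=9, n2=7, n_shared=3),
}


@dataclass(frozen=True)
class FixturePatient:
    patient_id: str
    time_lag: str                       # "synchronous" | "metachronous"
    interval_months: int
    extra_site: Site
    earlier: Optional[str]              # "lung" | "extra" | None
    cgp_evidence: str                   # key into _COUNT_STUBS
    driver: Optional[str]               # key into _DRIVERS
    msi_extra: MSIStatus
    methyl_lung: Optional[float]
    methyl_extra: Optional[float]
    expected: dict

    @property
    def n_methyl_samples(self) -> int:
        return sum(s is not None for s in (self.methyl_lung, self.methyl_extra))


def cohort_fixture() -> list[FixturePatient]:
    """Load the packaged 16-patient cohort."""
    raw = json.loads(
        resources.files("too_integrate").joinpath("data/reference_cohort.json").read_text()
    )
    patients = []
    for p in raw["patients"]:
        patients.append(
            FixturePatient(
                patient_id=p["id"],
                time_lag=p["time_lag"],
                interval_months=p["interval_months"],
                extra_site=Site(p["extra_site"]),
                earlier=p["earlier"],
                cgp_evidence=p["cgp_evidence"],
                driver=p["driver"],
                msi_extra=MSIStatus(p["msi_extra"]),
                methyl_lung=p["methyl"]["lung"],
                methyl_extra=p["methyl"]["extra"],
                expected=p["expected"],
            )
        )
    return patients


def _patient_spec(p: FixturePatient, seed: int) -> ScenarioSpec:
    counts = _COUNT_STUBS[p.cgp_evidence]
    if p.cgp_evidence == "zero_shared":
        scenario = Scenario.INDEPENDENT
    elif p.cgp_evidence == "shared_driver":
        scenario = Scenario.CLONAL_DRIVER
    elif p.time_lag == "metachronous":
        scenario = Scenario.CLONAL_METACHRONOUS
    else:
        scenario = Scenario.CLONAL_SYNCHRONOUS
    return ScenarioSpec(
        scenario=scenario,
        driver=None if p.driver is None else _DRIVERS[p.driver],
        interval_months=p.interval_months,
        extra_site=p.extra_site,
        earlier_tumor="t2" if p.earlier == "extra" else "t1",
        patient_id=p.patient_id,
        seed=seed,
        **counts,
    )


def fixture_case_pairs(seed: int = 0) -> dict[str, CasePair]:
    """Materialize all 16 paired genomic profiles (deterministic per seed)."""
    pairs = {}
    for i, p in enumerate(cohort_fixture()):
        child = (seed * 131 + i) % 2**31
        pair, _ = gen_cgp_case(
            _patient_spec(p, child), msi_t1=MSIStatus.MSS, msi_t2=p.msi_extra
        )
        pairs[p.patient_id] = pair
    return pairs


def fixture_cgp_inferences(
    seed: int = 0,
    wl: Optional[DriverWhitelist] = None,
    metachronous_threshold: int = 6,
) -> dict[str, CGPInference]:
    """Run the decision cascade on the materialized cohort."""
    return {
        pid: infer_relationship(pair, wl=wl, metachronous_threshold=metachronous_threshold)
        for pid, pair in fixture_case_pairs(seed).items()
    }


def fixture_methyl_results(cutoff: float = 0.5):
    """Per-lesion Methyl Score calls for the 29 profiled samples.

    Returns ``{patient_id: (lung_result_or_None, extra_result_or_None, organ)}``.
    """
    out = {}
    for p in cohort_fixture():
        lung = (
            None
            if p.methyl_lung is None
            else call_from_score(p.methyl_lung, cutoff, sample_id=p.patient_id)
        )
        extra = (
            None
            if p.methyl_extra is None
            else call_from_score(
                p.methyl_extra, cutoff, sample_id=p.patient_id, model_organ=p.extra_site
            )
        )
        out[p.patient_id] = (lung, extra, p.extra_site)
    return out


def fixture_methyl_diagnoses(cutoff: float = 0.5) -> dict[str, PatientDiagnosis]:
    """Patient-level methylation diagnoses (patients with >= 1 scored sample)."""
    out = {}
    for pid, (lung, extra, organ) in fixture_methyl_results(cutoff).items():
        if lung is None and extra is None:
            continue
        out[pid] = infer_patient_from_scores(lung, extra, organ)
    return out
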