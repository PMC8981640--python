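"""Synthetic study-condition generators.

Real paired tumor panels and targeted-bisulfite methylation matrices are
not publicly deposited, so every pipeline stage is exercised on generated
inputs with *planted, recorded ground truth*:

* :func:`gen_cgp_case` builds a paired tumor case under one of four
  scenarios (independent tumors, clonal pair sharing an actionable lung
  driver, clonal metachronous, clonal synchronous) with an exact planted
  number of shared alterations.
* :func:`gen_methylation_cohort` emulates the four-tissue training panel
  (22 lung / 19 stomach / 16 colon / 13 cervix samples by default) as a
  block-level beta matrix: per contrast organ a disjoint set of blocks is
  differentially methylated, organ mean displaced from the lung mean by
  ``delta``, all values Gaussian around the block mean and clipped to
  [0, 1].

Generators are deterministic given their seed and always return the truth
alongside the data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cgp import CGPInference, ClassLabel, Evidence, Relationship, TOO
from .methylation import MBSMatrix, MethylationBlock
from .profiles import Alteration, CasePair, Category, MSIStatus, Site, TumorProfile

__all__ = [
    "Scenario",
    "ScenarioSpec",
    "MethylCohortSpec",
    "gen_cgp_case",
    "random_scenario_spec",
    "gen_methylation_cohort",
    "gen_methylation_sites",
    "EGFR_L858R",
    "EGFR_EXON19_DEL",
    "EML4_ALK_FUSION",
]

# Passenger pool: recurrently altered cancer genes *excluding* the
# actionable lung whitelist (EGFR/ALK/ROS1), so planted passengers can
# never trip the driver rule.
PASSENGER_GENES = (
    "TP53 KRAS PIK3CA APC PTEN RB1 SMAD4 ARID1A KMT2D FBXW7 NF1 ATM BRCA2 "
    "CDKN2A CTNNB1 ERBB2 ERBB3 FGFR1 FGFR2 FGFR3 KEAP1 STK11 NOTCH1 NOTCH2 "
    "MET KIT PDGFRA BRAF NRAS RIT1 RAF1 MAP2K1 AKT1 MTOR TSC1 TSC2 VHL "
    "SETD2 BAP1 PBRM1 SMARCA4 CREBBP EP300 KDM6A ASXL1 DNMT3A TET2 GATA3 "
    "CDH1 RHOA MYC MYCN CCND1 CCNE1 MDM2 CDK4"
).split()

_BASES = "ACGT"

EGFR_L858R = Alteration(
    category=Category.SNV, gene="EGFR", chrom="7", pos=55259515,
    ref="T", alt="G", protein_change="p.L858R",
)
EGFR_EXON19_DEL = Alteration(
    category=Category.SMALL_INDEL, gene="EGFR", chrom="7", pos=55242465,
    ref="GGAATTAAGAGAAGCA", alt="G", protein_change="p.E746_A750del",
)
EML4_ALK_FUSION = Alteration(
    category=Category.REARRANGEMENT, gene="EML4", chrom="2", pos=42522656,
    partner_gene="ALK",
)


class Scenario(str, enum.Enum):
    INDEPENDENT = "independent"
    CLONAL_DRIVER = "clonal_driver"
    CLONAL_METACHRONOUS = "clonal_metachronous"
    CLONAL_SYNCHRONOUS = "clonal_synchronous"


@dataclass
class ScenarioSpec:
    """Recipe for one paired-tumor case with planted truth."""

    scenario: Scenario
    n1: int = 9
    n2: int = 7
    n_shared: int = 2
    driver: Optional[Alteration] = None
    interval_months: int = 0
    extra_site: Site = Site.STOMACH
    earlier_tumor: str = "t1"  # which lesion appeared first: "t1" or "t2"
    patient_id: str = "SYN"
    seed: int = 0

    def __post_init__(self):
        self.scenario = Scenario(self.scenario)
        self.extra_site = Site(self.extra_site)
        if self.extra_site is Site.LUNG:
            raise ValueError("extra_site must be extrathoracic")
        if self.earlier_tumor not in ("t1", "t2"):
            raise ValueError("earlier_tumor must be 't1' or 't2'")
        if self.n_shared > min(self.n1, self.n2):
            raise ValueError(f"n_shared={self.n_shared} exceeds min(n1, n2)")
        if self.scenario is Scenario.INDEPENDENT:
            if self.n_shared != 0:
                raise ValueError("independent scenario requires n_shared == 0")
        elif self.n_shared < 1:
            raise ValueError("clonal scenarios require n_shared >= 1")
        if self.scenario is Scenario.CLONAL_DRIVER and self.driver is None:
            self.driver = EGFR_L858R
        if self.scenario is Scenario.CLONAL_METACHRONOUS and self.interval_months < 6:
            raise ValueError("clonal_metachronous requires interval_months >= 6")
        if self.scenario is Scenario.CLONAL_SYNCHRONOUS and self.interval_months >= 6:
            raise ValueError("clonal_synchronous requires interval_months < 6")


def _random_snv(rng: np.random.Generator, pos: int) -> Alteration:
    gene = PASSENGER_GENES[rng.integers(len(PASSENGER_GENES))]
    chrom = str(rng.integers(1, 23))
    ref, alt = rng.choice(list(_BASES), size=2, replace=False)
    af = float(np.round(rng.uniform(0.02, 0.6), 4))
    return Alteration(
        category=Category.SNV, gene=gene, chrom=chrom, pos=int(pos),
        ref=str(ref), alt=str(alt), allele_fraction=af,
    )


def _scenario_truth(spec: ScenarioSpec) -> CGPInference:
    """Ground-truth inference implied by the planted scenario.

    Deliberately re-derives the expected outcome from the planted counts
    with stand-alone logic so it can serve as an oracle for the cascade.
    """
    common = dict(
        patient_id=spec.patient_id,
        shared_count=spec.n_shared,
        n1=spec.n1,
        n2=spec.n2,
        extra_site=spec.extra_site,
        interval_months=spec.interval_months,
    )
    if spec.scenario is Scenario.INDEPENDENT:
        return CGPInference(
            relationship=Relationship.MULTIPLE_PRIMARY, too=TOO.NOT_APPLICABLE,
            class_label=ClassLabel.I, evidence=Evidence.ZERO_SHARED, **common,
        )
    if spec.scenario is Scenario.CLONAL_DRIVER:
        return CGPInference(
            relationship=Relationship.METASTATIC, too=TOO.LUNG,
            class_label=ClassLabel.I, evidence=Evidence.SHARED_DRIVER,
            driver=spec.driver, **common,
        )
    criteria = (spec.n1 >= 5 and spec.n2 >= 5 and spec.n_shared >= 2) or (
        (spec.n1 < 5 or spec.n2 < 5) and spec.n_shared >= 1
    )
    if not criteria:
        return CGPInference(
            relationship=Relationship.INCONCLUSIVE_RELATIONSHIP, too=TOO.INCONCLUSIVE,
            class_label=ClassLabel.NONE, evidence=Evidence.CRITERIA_NOT_MET, **common,
        )
    if spec.interval_months >= 6:
        earlier_site = Site.LUNG if spec.earlier_tumor == "t1" else spec.extra_site
        return CGPInference(
            relationship=Relationship.METASTATIC, too=TOO(earlier_site.value),
            class_label=ClassLabel.II,
            evidence=Evidence.CLONALITY_CRITERIA_PLUS_TIME_LAG, **common,
        )
    return CGPInference(
        relationship=Relationship.METASTATIC, too=TOO.INCONCLUSIVE,
        class_label=ClassLabel.III, evidence=Evidence.CLONALITY_CRITERIA_ONLY, **common,
    )


def gen_cgp_case(
    spec: ScenarioSpec,
    msi_t1: MSIStatus = MSIStatus.MSS,
    msi_t2: MSIStatus = MSIStatus.MSS,
) -> tuple[CasePair, CGPInference]:
    """Materialize a paired case and its planted ground-truth inference.

    All non-driver alterations are SNVs at globally unique positions, so
    exactly ``n_shared`` alteration identities occur in both profiles.
    """
    rng = np.random.default_rng(spec.seed)
    n_unique = spec.n1 + spec.n2 - spec.n_shared
    positions = rng.choice(200_000_000, size=n_unique, replace=False) + 1

    shared: list[Alteration] = []
    if spec.driver is not None:
        shared.append(spec.driver)
    while len(shared) < spec.n_shared:
        shared.append(_random_snv(rng, positions[len(shared)]))
    off = spec.n_shared
    t1_private = [_random_snv(rng, positions[off + i]) for i in range(spec.n1 - spec.n_shared)]
    off += spec.n1 - spec.n_shared
    t2_private = [_random_snv(rng, positions[off + i]) for i in range(spec.n2 - spec.n_shared)]

    if spec.earlier_tumor == "t1":
        m1, m2 = 0, spec.interval_months
    else:
        m1, m2 = spec.interval_months, 0

    t1 = TumorProfile(
        patient_id=spec.patient_id, site=Site.LUNG, detection_month=m1,
        alterations=shared + t1_private, msi_status=msi_t1,
    )
    t2 = TumorProfile(
        patient_id=spec.patient_id, site=spec.extra_site, detection_month=m2,
        alterations=list(shared) + t2_private, msi_status=msi_t2,
    )
    truth = _scenario_truth(spec)
    truth.msi_t1, truth.msi_t2 = msi_t1, msi_t2
    return CasePair(patient_id=spec.patient_id, t1=t1, t2=t2), truth


def random_scenario_spec(seed: int) -> ScenarioSpec:
    """A random but always-valid scenario, for generator-vs-cascade checks."""
    rng = np.random.default_rng(seed)
    scenario = Scenario(
        str(rng.choice([s.value for s in Scenario]))
    )
    extra = Site(str(rng.choice([Site.STOMACH.value, Site.COLON_RECTUM.value, Site.CERVIX.value])))
    n1 = int(rng.integers(1, 26))
    n2 = int(rng.integers(1, 26))
    if scenario is Scenario.INDEPENDENT:
        n_shared = 0
        interval = int(rng.integers(0, 25))
    else:
        n_shared = int(rng.integers(1, min(n1, n2) + 1))
        if scenario is Scenario.CLONAL_METACHRONOUS:
            interval = int(rng.integers(6, 37))
        elif scenario is Scenario.CLONAL_SYNCHRONOUS:
            interval = int(rng.integers(0, 6))
        else:
            interval = int(rng.integers(0, 25))
    driver = None
    if scenario is Scenario.CLONAL_DRIVER:
        driver = [EGFR_L858R, EGFR_EXON19_DEL, EML4_ALK_FUSION][int(rng.integers(3))]
    return ScenarioSpec(
        scenario=scenario, n1=n1, n2=n2, n_shared=n_shared, driver=driver,
        interval_months=interval, extra_site=extra,
        earlier_tumor="t1" if rng.random() < 0.5 else "t2",
        patient_id=f"SYN{seed}", seed=int(rng.integers(2**31)),
    )


DEFAULT_TRAINING_COUNTS = {
    Site.LUNG: 22,
    Site.STOMACH: 19,
    Site.COLON_RECTUM: 16,
    Site.CERVIX: 13,
}


@dataclass
class MethylCohortSpec:
    """Recipe for the synthetic four-tissue methylation training panel."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_TRAINING_COUNTS))
    n_blocks: int = 2000
    n_differential: int = 200   # per lung-vs-organ contrast
    delta: float = 0.3          # lung/organ mean beta difference at planted blocks
    noise_sd: float = 0.05
    baseline_range: tuple[float, float] = (0.05, 0.95)
    sites_per_block: tuple[int, int] = (3, 8)
    seed: int = 0
    # Sample noise is drawn from its own stream so held-out query cohorts
    # can share one panel structure (same seed) while varying sample_seed.
    sample_seed: Optional[int] = None

    def __post_init__(self):
        self.counts = {Site(k): int(v) for k, v in self.counts.items()}
        organs = [s for s in self.counts if s is not Site.LUNG]
        if len(organs) * self.n_differential > self.n_blocks:
            raise ValueError("n_differential x contrasts exceeds n_blocks")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.baseline_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("invalid baseline_range")


def _make_blocks(spec: MethylCohortSpec, rng: np.random.Generator) -> list[MethylationBlock]:
    blocks = []
    cursors = {str(c): 10_000 for c in range(1, 23)}
    for i in range(spec.n_blocks):
        chrom = str((i % 22) + 1)
        n_sites = int(rng.integers(spec.sites_per_block[0], spec.sites_per_block[1] + 1))
        start = cursors[chrom]
        positions = tuple(start + 100 * j for j in range(n_sites))  # intra-block gap 100 bp
        cursors[chrom] = positions[-1] + 10_000                     # inter-block gap >> max_gap
        blocks.append(
            MethylationBlock(
                block_id=f"B{i:05d}", chrom=chrom, start=positions[0],
                end=positions[-1], member_sites=positions,
            )
        )
    return blocks


def gen_methylation_cohort(
    spec: Optional[MethylCohortSpec] = None,
) -> tuple[MBSMatrix, dict[Site, list[str]]]:
    """Generate the block-level training panel plus planted truth.

    Returns the labeled MBS matrix (labels 0 = lung, 1 = other; tissue
    recorded per sample) and, per contrast organ, the ids of its planted
    differentially methylated blocks.
    """
    spec = spec or MethylCohortSpec()
    rng = np.random.default_rng(spec.seed)
    sample_rng = np.random.default_rng(
        spec.seed if spec.sample_seed is None else spec.sample_seed
    )
    blocks = _make_blocks(spec, rng)
    organs = [s for s in spec.counts if s is not Site.LUNG]

    lo, hi = spec.baseline_range
    baseline = rng.uniform(lo, hi, size=spec.n_blocks)

    # Disjoint differential-block sets, one per organ.
    diff_idx = rng.choice(
        spec.n_blocks, size=spec.n_differential * len(organs), replace=False
    )
    planted: dict[Site, list[str]] = {}
    organ_means = {organ: baseline.copy() for organ in organs}
    for k, organ in enumerate(organs):
        idx = diff_idx[k * spec.n_differential : (k + 1) * spec.n_differential]
        direction = np.where(baseline[idx] <= 0.5, 1.0, -1.0)
        organ_means[organ][idx] = np.clip(
            baseline[idx] + direction * spec.delta, 0.02, 0.98
        )
        planted[organ] = [blocks[i].block_id for i in sorted(idx)]

    sample_ids, tissues, rows = [], [], []
    for site, count in spec.counts.items():
        means = baseline if site is Site.LUNG else organ_means[site]
        for j in range(count):
            sample_ids.append(f"{site.value}_{j + 1:02d}")
            tissues.append(site.value)
            rows.append(np.clip(sample_rng.normal(means, spec.noise_sd), 0.0, 1.0))

    values = pd.DataFrame(
        np.vstack(rows), index=sample_ids, columns=[b.block_id for b in blocks]
    )
    tissue = pd.Series(tissues, index=sample_ids, name="tissue")
    labels = (tissue != Site.LUNG.value).astype(int)
    return MBSMatrix(values=values, blocks=blocks, labels=labels, tissue=tissue), planted


def gen_methylation_sites(
    spec: Optional[MethylCohortSpec] = None,
    jitter_sd: float = 0.01,
) -> tuple[pd.DataFrame, MBSMatrix, dict[Site, list[str]]]:
    """Site-level view of the generated cohort.

    Each block's value is replicated across its member CpGs with small
    Gaussian jitter; the classifier consumes blocks, so site-level realism
    beyond this is not load-bearing. Returns the tidy site table
    (``chrom, pos, sample_id, beta``) plus the block-level matrix and
    planted truth it was expanded from.
    """
    spec = spec or MethylCohortSpec()
    mbs, planted = gen_methylation_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    frames = []
    vals = mbs.values.to_numpy()
    for bi, block in enumerate(mbs.blocks):
        for pos in block.member_sites:
            beta = np.clip(vals[:, bi] + rng.normal(0.0, jitter_sd, size=vals.shape[0]), 0, 1)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": block.chrom,
                        "pos": pos,
                        "sample_id": mbs.sample_ids,
                        "beta": beta,
                    }
                )
            )
    sites = pd.concat(frames, ignore_index=True)
    return sites, mbs, planted
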