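import numpy as np
import pytest

from too_integrate.profiles import Alteration, Category, Site, TumorProfile
from too_integrate.synthetic import MethylCohortSpec, gen_methylation_cohort


def make_snv(gene="TP53", chrom="17", pos=7577120, ref="C", alt="T", **kw):
    return Alteration(category=Category.SNV, gene=gene, chrom=chrom, pos=pos,
                      ref=ref, alt=alt, **kw)


def make_profile(alterations, site=Site.LUNG, patient_id="PX", detection_month=0):
    return TumorProfile(patient_id=patient_id, site=site,
                        detection_month=detection_month, alterations=list(alterations))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic training panel shared by fast classifier tests."""
    spec = MethylCohortSpec(n_blocks=400, n_differential=40, seed=7)
    mbs, planted = gen_methylation_cohort(spec)
    return spec, mbs, planted


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
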