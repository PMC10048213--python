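import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_impl

from drmeta.types import EffectEstimate, EffectSource, PhenotypeGroup, Signal


def make_signal(
    rsid="rs1",
    chrom="1",
    pos=1_000_000,
    p=1e-8,
    study="S1",
    group=PhenotypeGroup.DR,
    **kw,
):
    return Signal(
        rsid=rsid,
        chrom=chrom,
        pos=pos,
        p_value=p,
        study_id=study,
        phenotype_group=group,
        **kw,
    )


def make_estimate(study="S1", beta=0.3, se=0.1, **kw):
    kw.setdefault("source", EffectSource.COUNTS)
    return EffectEstimate(study_id=study, beta=beta, se=se, **kw)


@pytest.fixture
def signal_factory():
    return make_signal


@pytest.fixture
def estimate_factory():
    return make_estimate
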