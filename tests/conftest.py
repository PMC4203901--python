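import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pilecall.error_models import build_error_matrix
from pilecall.model_core import GenotypeCaller, ReferencePrior, build_genotype_prior
from pilecall.pileup_io import PileupColumn, Observation


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def haploid_prior():
    return build_genotype_prior("haploid", 0.001)


@pytest.fixture
def diploid_prior():
    return build_genotype_prior("diploid", 0.001)


def make_column(bases, quals, ref="A", mapq=60, chrom="chr1", pos=100):
    """Hand-build a pileup column from parallel base/quality lists."""
    obs = [
        Observation(b, False, q, mapq, i)
        for i, (b, q) in enumerate(zip(bases, quals))
    ]
    return PileupColumn(
        chrom=chrom, pos=pos, ref=ref, depth=len(obs), observations=obs
    )


@pytest.fixture
def make_caller():
    def _make(ploidy="diploid", tau=0.002, snp_rate=0.001, use_reference=False,
              sub=None, **kwargs):
        sub = sub if sub is not None else build_error_matrix(tau)
        ref_prior = (
            ReferencePrior("observed", np.zeros(4))
            if use_reference
            else ReferencePrior.flat()
        )
        return GenotypeCaller(
            sub, build_genotype_prior(ploidy, snp_rate), ref_prior, **kwargs
        )

    return _make
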