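import numpy as np
import pytest

from mreqtl.fixtures import FixtureConfig, generate_fixture
from mreqtl.postprocess import classify_regions


@pytest.fixture(scope="session")
def default_bundle():
    return generate_fixture(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def default_outcome(default_bundle):
    b = default_bundle
    expr = {}
    for region in b.region_individuals:
        expr[(region, "transcript")] = b.transcript_expression[region]
        expr[(region, "exon")] = b.exon_expression[region]
    return classify_regions(b.genotypes, b.snp_map, b.annotation, expr)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
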