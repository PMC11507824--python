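import numpy as np
import pytest

from qexon import SyntheticConfig, generate_series


GFF3_FIXTURE = """##gff-version 3
T1\tsrc\tgene\t101\t470\t.\t+\t.\tID=gene1
T1\tsrc\texon\t101\t200\t.\t+\t.\tParent=gene1
T1\tsrc\texon\t301\t450\t.\t+\t.\tParent=gene1
T1\tsrc\texon\t460\t470\t.\t+\t.\tParent=gene1
"""


@pytest.fixture()
def gff3_lines():
    return GFF3_FIXTURE.splitlines(keepends=True)


@pytest.fixture(scope="session")
def default_synthetic():
    """One synthetic chromosome at the study conditions (seeded)."""
    cfg = SyntheticConfig(seed=0)
    series, truth = generate_series(cfg)
    return series, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
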