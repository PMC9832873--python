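import numpy as np
import pytest

from polym6a.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by read-only tests."""
    return simulate_all(SimConfig(seed=11, n_genes=40))


GFF_SINGLE_PLUS = """##gff-version 3
chr1\tsim\tgene\t1\t1000\t.\t+\t.\tID=g1
chr1\tsim\tmRNA\t1\t1000\t.\t+\t.\tID=g1.1;Parent=g1
chr1\tsim\texon\t1\t1000\t.\t+\t.\tParent=g1.1
chr1\tsim\tCDS\t201\t800\t.\t+\t0\tParent=g1.1
"""

GFF_SINGLE_MINUS = """##gff-version 3
chr1\tsim\tgene\t1\t1000\t.\t-\t.\tID=g1
chr1\tsim\tmRNA\t1\t1000\t.\t-\t.\tID=g1.1;Parent=g1
chr1\tsim\texon\t1\t1000\t.\t-\t.\tParent=g1.1
chr1\tsim\tCDS\t201\t800\t.\t-\t0\tParent=g1.1
"""

GFF_TWO_ISOFORMS = """##gff-version 3
chr1\tsim\tgene\t1\t2000\t.\t+\t.\tID=g1
chr1\tsim\tmRNA\t1\t1000\t.\t+\t.\tID=g1.a;Parent=g1
chr1\tsim\texon\t1\t1000\t.\t+\t.\tParent=g1.a
chr1\tsim\tCDS\t101\t400\t.\t+\t0\tParent=g1.a
chr1\tsim\tmRNA\t1\t2000\t.\t+\t.\tID=g1.b;Parent=g1
chr1\tsim\texon\t1\t2000\t.\t+\t.\tParent=g1.b
chr1\tsim\tCDS\t101\t700\t.\t+\t0\tParent=g1.b
"""


@pytest.fixture
def gff_file(tmp_path):
    def write(text):
        p = tmp_path / "ann.gff3"
        p.write_text(text)
        return str(p)

    return write


@pytest.fixture
def rng():
    return np.random.default_rng(0)
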