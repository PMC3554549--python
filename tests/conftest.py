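import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=geneA,length=60>
##contig=<ID=geneB,length=30>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
geneA\t1\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
geneA\t10\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t./.\t1/2
geneB\t4\trs3\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t0/0
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture
def tiny_samples():
    from bomp.core import SampleTable

    return SampleTable(["S1", "S2", "S3"], np.array([True, True, False]))


@pytest.fixture
def small_study():
    """A small simulated study with a planted rare-variant signal."""
    from bomp.simulate import Scenario, simulate_study

    scenario = Scenario(
        name="fixture", population=20_000, n_case=150, n_ctrl=150,
        n_genes=2, n_causal=1, etiology="rare",
    )
    return simulate_study(scenario, np.random.default_rng(2024))
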