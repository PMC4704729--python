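import numpy as np
import pytest

from projana.demography import Deme, DemographicModel, SampleGroup


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def one_pop_model(n_panel=10, t_test=0.0, N=5000.0, epochs=None):
    """Single constant-size (or piecewise) deme with a panel and one test lineage."""
    deme = Deme("pop", epochs or ((0.0, N),))
    return DemographicModel(
        (deme,),
        (),
        (
            SampleGroup("pop", 0.0, n_panel, "panel"),
            SampleGroup("pop", t_test, 1, "test"),
        ),
    )


def pair_model(t_second=0.0, N=5000.0, epochs=None):
    """Two panel lineages (possibly serially sampled) — for TMRCA checks."""
    deme = Deme("pop", epochs or ((0.0, N),))
    return DemographicModel(
        (deme,),
        (),
        (
            SampleGroup("pop", 0.0, 1, "panel"),
            SampleGroup("pop", t_second, 1, "panel"),
        ),
    )


TINY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
1\t100\t.\tC\tA\t.\t.\tAA=C\tGT\t0/0\t0/1\t1/1\t0/0
1\t200\t.\tC\tA\t.\t.\tAA=a\tGT\t0/0\t0/1\t0/1\t0/0
1\t300\t.\tA\tG\t.\t.\tAA=A\tGT\t0/1\t0/1\t0/0\t0/0
1\t400\t.\tT\tG\t.\t.\tAA=G\tGT\t1/1\t1/1\t0/1\t0/0
1\t500\t.\tG\tT\t.\t.\tAA=C\tGT\t0/0\t0/1\t0/0\t0/0
1\t600\t.\tA\tC,T\t.\t.\tAA=A\tGT\t0/1\t0/2\t0/0\t0/0
1\t700\t.\tG\tC\t.\t.\t.\tGT\t0/1\t0/0\t./.\t0/0
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "panel.vcf"
    path.write_text(TINY_VCF)
    return path
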