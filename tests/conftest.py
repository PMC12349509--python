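import numpy as np
import pytest

from gburden import AnnotationModel, ExpressionModel, SimConfig, generate_dataset
from gburden.variant_io import VariantSet

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=Gm01>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
Gm01\t100\t.\tA\tG\t50\t.\t.\tGT:DP\t0/1:12\t1/1:30
Gm01\t200\t.\tC\tT,G\t50\t.\t.\tGT:DP\t0/1:12\t0/2:15
Gm01\t300\t.\tC\tT\t15\t.\t.\tGT:DP\t0/1:12\t1/1:25
Gm01\t400\t.\tG\tA\t60\t.\t.\tGT:DP\t0/0:8\t0/1:15
Gm01\t500\t.\tT\tC\t90\t.\t.\tGT:DP\t0/0:14\t1/1:22
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """Five sites: one multiallelic, one low QUAL, one low-DP call, two clean."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


def make_variantset(genotypes, chrom=None, pos=None):
    """VariantSet from a (sites x samples) genotype array of {0,1,2}."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n = geno.shape[0]
    return VariantSet(
        chrom=np.array(chrom if chrom is not None else ["Gm01"] * n,
                       dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n + 1) * 100),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        genotypes=geno,
        samples=[f"S{j + 1}" for j in range(geno.shape[1])])


def small_sim_config(seed=11, **overrides):
    """Desk-scale simulator config used by the fast end-to-end tests."""
    kwargs = dict(
        n_samples=40, l_sites=80, seed=seed,
        annotation_model=AnnotationModel(n_tolerated=40, n_sift_only=10,
                                         n_low_confidence=5, n_other=40),
        expression_model=ExpressionModel(n_genes=30, n_core_genes=15,
                                         count_base=24.0, count_noise_sd=2.5))
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    return generate_dataset(small_sim_config())


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale simulated collection (the study conditions)."""
    return generate_dataset(SimConfig(seed=2024))
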