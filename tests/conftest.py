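import numpy as np
import pytest

from episense import generate_snp_matrix, sample_bd_model, sample_mafs, simulate_phenotypes

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5\tS6
"""


def _vcf_line(pos, vid, ref, alt, gts):
    return (
        f"1\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
    )


@pytest.fixture(scope="session")
def tiny_vcf(tmp_path_factory):
    """A 6-sample VCF with 10 clean biallelic SNPs, one multiallelic record
    and one record with a missing genotype (both should be dropped)."""
    rng = np.random.default_rng(7)
    path = tmp_path_factory.mktemp("vcf") / "tiny.vcf"
    lines = [VCF_HEADER]
    gt_codes = ["0/0", "0/1", "1/1"]
    for k in range(10):
        gts = [gt_codes[rng.integers(3)] for _ in range(6)]
        lines.append(_vcf_line(100 + k, f"rs{k}", "A", "G", gts))
    lines.append(_vcf_line(500, "rs_multi", "A", "G,T", ["0/1"] * 6))
    lines.append(
        _vcf_line(600, "rs_missing", "C", "T", ["0/1", "./.", "0/0", "1/1", "0/1", "0/0"])
    )
    path.write_text("".join(lines))
    return str(path)


@pytest.fixture(scope="session")
def small_gm():
    maf = sample_mafs(300, 10)
    return generate_snp_matrix(600, 300, maf, 11)


@pytest.fixture(scope="session")
def bd_small(small_gm):
    model = sample_bd_model(5, small_gm.p, 12)
    phenos = simulate_phenotypes(model, small_gm, 13)
    return model, phenos
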