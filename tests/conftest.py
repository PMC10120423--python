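import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from varsight import convert_vcf
from varsight.annotation import infer_label_map, load_gff3
from varsight.fixtures import FixtureSpec, generate_gff3, generate_vcf

# Tiny hand-written VCF exercising every dosage case:
#   chr1:100  0/0 0/1 1/1 ./.   -> [0, 1, 2, -1]
#   chr1:250  all reference     -> [0, 0, 0, 0]
#   chr1:400  all missing       -> [-1]*4
#   chr2:50   multi-allelic, phased, half-call
TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=500>
##contig=<ID=chr2,length=100>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
chr1\t100\t.\tA\tT\t10\t.\tMQ=40;ANN=T|missense_variant|MODERATE|GeneX|GENEX|transcript|GENEX.1\tGT\t0/0\t0/1\t1/1\t./.
chr1\t250\t.\tG\tC\t30\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0
chr1\t400\t.\tC\tA\t50\t.\tMQ=20\tGT\t./.\t./.\t./.\t./.
chr2\t50\t.\tT\tG,A\t.\t.\t.\tGT\t0|1\t2/1\t./1\t1/1
"""


@pytest.fixture(scope="session")
def tiny_vcf_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("tiny") / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


@pytest.fixture(scope="session")
def tiny_ds(tiny_vcf_path, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_store") / "tiny.zarr"
    return convert_vcf(tiny_vcf_path, out)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(
        n_samples=30, n_variants=120, chromosomes=("chr1H", "chr2H"),
        ploidy=2, seed=11, missing_rate=0.08, ann_fraction=0.25,
        multiallelic_fraction=0.1, gene_density=5,
        gff_label_style="strip_chr",
    )


@pytest.fixture(scope="session")
def fixture_files(fixture_spec, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    vcf = d / "fixture.vcf"
    gff = d / "fixture.gff3"
    truth = generate_vcf(fixture_spec, vcf)
    gene_truth = generate_gff3(fixture_spec, truth, gff)
    return {"vcf": vcf, "gff3": gff, "truth": truth, "gene_truth": gene_truth}


@pytest.fixture(scope="session")
def fixture_ds(fixture_files, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_store") / "fixture.zarr"
    return convert_vcf(fixture_files["vcf"], out)


@pytest.fixture(scope="session")
def fixture_annotation(fixture_files, fixture_ds):
    label_map = infer_label_map(
        fixture_ds.chromosomes, ["1H", "2H"]
    )
    return load_gff3(fixture_files["gff3"], label_map=label_map)
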