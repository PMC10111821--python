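"""Shared fixtures: hand-written mini-VCFs, annotation files, and a small
simulated complex reused across test modules."""

import textwrap

import pytest

import polyplex as px

MINI_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000>
    ##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
    ##INFO=<ID=QD,Number=1,Type=Float,Description="x">
    ##INFO=<ID=FS,Number=1,Type=Float,Description="x">
    ##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="x">
    ##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="x">
    ##INFO=<ID=SOR,Number=1,Type=Float,Description="x">
    ##INFO=<ID=DP,Number=1,Type=Integer,Description="x">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
    chr1\t10\t.\tA\tT\t900\t.\tMQ=60;QD=20;FS=1;MQRankSum=0;ReadPosRankSum=0;SOR=1;DP=60\tGT:AD:DP\t0/1:15,5:20\t1/1:0,22:22
    chr1\t50\t.\tC\tG\t700\t.\tMQ=60;QD=20;FS=1;MQRankSum=0;ReadPosRankSum=0;SOR=1;DP=55\tGT:AD:DP\t./.:10,10:20\t0/0:30,0:30
    chr1\t99\t.\tG\tA\t800\t.\tMQ=39;QD=20;FS=1;MQRankSum=0;ReadPosRankSum=0;SOR=1;DP=50\tGT:AD:DP\t0/1:10,10:20\t0/1:12,13:25
    """)


@pytest.fixture
def mini_vcf(tmp_path):
    path = tmp_path / "mini.vcf"
    path.write_text(MINI_VCF)
    return str(path)


@pytest.fixture
def mini_sheet():
    return px.SampleSheet([
        px.io_formats.SampleInfo("S1", "grpA", 2),
        px.io_formats.SampleInfo("S2", "grpB", 2),
    ])


@pytest.fixture
def bed_file(tmp_path):
    path = tmp_path / "intervals.bed"
    path.write_text("chr1\t10\t20\trep1\nchr1\t100\t200\trep2\nchr2\t0\t50\trep3\n")
    return str(path)


@pytest.fixture
def gff_file(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t11\t20\t.\t+\t.\tID=geneA\n"
        "chr1\tsrc\tgene\t150\t250\t.\t-\t.\tID=geneB\n"
    )
    return str(path)


@pytest.fixture(scope="session")
def small_complex():
    """One simulated complex with hybrids, shared across tests."""
    cfg = px.SimConfig(seed=42)
    truth, records, reference, sheet = px.simulate_complex(cfg)
    return cfg, truth, records, reference, sheet


def make_record(chrom="chr1", pos=100, ref="A", alts=("T",), qual=900.0,
                info=None, calls=None):
    """Convenience constructor for hand-built VariantRecords."""
    if info is None:
        info = {"MQ": 60.0, "QD": 20.0, "FS": 1.0, "MQRankSum": 0.0,
                "ReadPosRankSum": 0.0, "SOR": 1.0, "DP": 30.0}
    if calls is None:
        calls = {}
    parsed = {}
    for name, gt in calls.items():
        if isinstance(gt, px.io_formats.SampleCall):
            parsed[name] = gt
        else:
            parsed[name] = px.io_formats.SampleCall(
                genotype=None if gt is None else tuple(gt), ad=None)
    return px.VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
                            qual=qual, info=info, calls=parsed)
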