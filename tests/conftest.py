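import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=2000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand score">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read pos rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
1\t100\t.\tA\tG\t50\t.\tQD=20.0;FS=1.0;MQ=58.0;MQRankSum=0.5;ReadPosRankSum=0.2\tGT:AD\t0/1:20,10\t0/1:15,15
1\t200\t.\tC\tT\t50\t.\tQD=25.0;FS=2.0;MQ=59.0\tGT:AD\t0/1:12,14\t1/1:0,22
1\t300\t.\tG\tA,T\t50\t.\tQD=18.0;FS=3.0;MQ=57.0\tGT:AD\t1/2:2,9,8\t0/1:10,11,0
1\t400\t.\tT\tC\t50\t.\tQD=22.0;FS=0.5;MQ=60.0\tGT:AD\t1/1:1,30\t1/1:0,28
1\t500\t.\tA\tAT\t50\t.\tQD=15.0;FS=4.0\tGT:AD\t0/1:12,8\t0/1:9,10
1\t600\t.\tC\tG\t50\t.\tQD=19.0;FS=1.5;MQ=55.0\tGT:AD\t./.:.\t0/0:25,0
1\t700\t.\tG\tC,A\t50\t.\tQD=17.0;FS=2.5;MQ=56.0\tGT:AD\t0/1:8,9,0\t0/2:7,0,6
1\t800\t.\tT\tA\t50\t.\tQD=1.0;FS=5.0;MQ=58.0\tGT:AD\t0/1:11,13\t0/1:10,9
1\t900\t.\tA\tC\t50\t.\tQD=21.0;FS=60.0;MQ=57.0\tGT:AD\t0/1:16,14\t0/0:30,1
1\t1000\t.\tG\tT\t50\t.\tQD=24.0;FS=1.0;MQ=59.0;MQRankSum=-1.0;ReadPosRankSum=0.7\tGT:AD\t0/1:18,20\t0/1:21,17
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """A 10-row VCF: 7 biallelic SNVs, 2 multiallelic rows, 1 indel; samples A, B."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240111)
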