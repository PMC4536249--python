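import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


GFF3_TWO_GENES = """\
##gff-version 3
chr1\ttest\tgene\t1001\t2000\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t1001\t2000\t.\t+\t.\tID=m1;Parent=g1
chr1\ttest\texon\t1001\t1400\t.\t+\t.\tID=e1;Parent=m1
chr1\ttest\texon\t1601\t2000\t.\t+\t.\tID=e2;Parent=m1
chr1\ttest\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tID=u5;Parent=m1
chr1\ttest\tCDS\t1101\t1400\t.\t+\t.\tID=c1;Parent=m1
chr1\ttest\tCDS\t1601\t1900\t.\t+\t.\tID=c2;Parent=m1
chr1\ttest\tthree_prime_UTR\t1901\t2000\t.\t+\t.\tID=u3;Parent=m1
chr1\ttest\tgene\t4001\t5000\t.\t-\t.\tID=g2
chr1\ttest\tmRNA\t4001\t5000\t.\t-\t.\tID=m2;Parent=g2
chr1\ttest\texon\t4001\t5000\t.\t-\t.\tID=e3;Parent=m2
chr1\ttest\tCDS\t4001\t5000\t.\t-\t.\tID=c3;Parent=m2
"""


@pytest.fixture
def gff3_file(tmp_path):
    """Two genes on a 10-kb chr1: plus-strand g1 with UTRs/intron, minus-strand g2."""
    path = tmp_path / "genes.gff3"
    path.write_text(GFF3_TWO_GENES)
    return path


@pytest.fixture
def region_index(gff3_file):
    from indelscout.seqio import build_region_index

    return build_region_index(gff3_file, {"chr1": 10_000, "chr2": 3_000})
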