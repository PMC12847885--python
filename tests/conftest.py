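import pytest
from hypothesis import HealthCheck, settings

import ribostress as rs

settings.register_profile(
    "ribostress",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ribostress")

TOY_GTF = """\
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\tCDS\t51\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\tCDS\t201\t250\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\ttest\texon\t501\t600\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture(scope="session")
def small_sim():
    """One small planted-effect simulation shared across read-only tests."""
    cfg = rs.SimConfig(n_transcripts=400, n_proteins=200,
                       prot_frac_significant=0.5, seed=11)
    return rs.simulate_transcripts(cfg), rs.simulate_proteins(cfg), cfg
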