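import numpy as np
import pytest

from phagedyn.abundance import CoverageRecord
from phagedyn.viral_triage import AniPair, ContigAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_contig(
    contig_id="c1",
    length_bp=10000,
    viral=0,
    host=0,
    score=None,
    hallmarks=0,
    source="WGS",
):
    return ContigAnnotation(
        contig_id=contig_id,
        length_bp=length_bp,
        source_fraction=source,
        viral_gene_count=viral,
        host_gene_count=host,
        vs_score=score,
        hallmark_count=hallmarks,
    )


def make_pair(q, s, ani, af=None):
    return AniPair(query_id=q, subject_id=s, ani_pct=ani, aligned_fraction=af)


def make_record(contig="c1", sample="s1", count=0, breadth=1.0):
    return CoverageRecord(
        contig_id=contig, sample_id=sample, read_count=count, fraction_covered=breadth
    )
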