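import numpy as np
import pytest

from gcfate.transcript_io import TranscriptModel, TranscriptRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_record(utr5="GGAA", cds="ATGAAATAA", utr3="TTTT",
                tid="t1", gid="g1") -> TranscriptRecord:
    seq = utr5 + cds + utr3
    a, b = len(utr5), len(utr5) + len(cds)
    return TranscriptRecord(transcript_id=tid, gene_id=gid, sequence=seq,
                            utr5_span=(0, a), cds_span=(a, b),
                            utr3_span=(b, len(seq)))


def random_transcript_model(rng, tid="tx", gid="gx") -> TranscriptModel:
    """Random multi-exon transcript with a CDS, for liftover round-trips."""
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(10, 200))
    total = sum(e - s for s, e in exons)
    cds_len = int(rng.integers(1, total))
    cds_start = int(rng.integers(0, total - cds_len + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    tx = TranscriptModel(transcript_id=tid, gene_id=gid, chrom="chr1",
                         strand=strand, exons=exons, cds_segments=[])
    tx.cds_segments = tx.genomic_segments(cds_start, cds_start + cds_len)
    return tx, cds_start, cds_len
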