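import numpy as np
import pytest

from lncprofile.io_formats import CountMatrix, TranscriptModel


def make_transcript(tid="t1", chrom="chr1", strand="+", exons=((0, 300),), gene=None):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or f"G{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
    )


def random_transcripts(rng, n, prefix, chroms=("chrA", "chrB"), region=200_000):
    """Densely packed random transcripts so overlaps of every kind occur."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, region))
        n_exons = int(rng.integers(1, 5))
        exons = []
        pos = start
        for k in range(n_exons):
            size = int(rng.integers(100, 2000))
            exons.append((pos, pos + size))
            pos += size + int(rng.integers(100, 2000))
        out.append(
            TranscriptModel(f"{prefix}{i:04d}", f"G{prefix}{i:04d}", chrom, strand, tuple(exons))
        )
    return out


@pytest.fixture
def toy_counts():
    """3 transcripts x 4 samples (2 case, 2 control)."""
    return CountMatrix(
        transcript_ids=["t1", "t2", "t3"],
        sample_ids=["c1", "c2", "k1", "k2"],
        groups=["case", "case", "control", "control"],
        counts=np.array([[10, 20, 5, 5], [100, 80, 120, 90], [0, 0, 0, 1]]),
        sample_totals=np.array([1000, 1000, 1000, 1000]),
        coverage=np.array([2.0, 10.0, 0.1]),
    )
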