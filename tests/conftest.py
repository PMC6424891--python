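import numpy as np
import pytest

from farseq.annotation import GenomeAnnotation, GenomicFeature
from farseq.alignments import AlignmentRecord


@pytest.fixture
def small_annotation() -> GenomeAnnotation:
    """Three CDS, one rRNA and one tRNA on a single reference."""
    return GenomeAnnotation(
        [
            GenomicFeature("gA", "chr", 1001, 2000, "+", "CDS"),
            GenomicFeature("gB", "chr", 3001, 4500, "-", "CDS"),
            GenomicFeature("gC", "chr", 5001, 5300, "+", "CDS"),
            GenomicFeature("rrn1", "chr", 7001, 9900, "+", "rRNA"),
            GenomicFeature("trn1", "chr", 10001, 10080, "+", "tRNA"),
        ]
    )


def make_read(read_id, start, end, unique=True, reference="chr"):
    return AlignmentRecord(read_id, reference, start, end, unique)


def brute_force_counts(records, annotation):
    """Independent all-pairs overlap scan: the counting oracle."""
    counts = {f.feature_id: 0 for f in annotation.protein_coding}
    n_mrna = 0
    for rec in records:
        hit = False
        for feat in annotation.protein_coding:
            if feat.reference == rec.reference and rec.start <= feat.end and rec.end >= feat.start:
                counts[feat.feature_id] += 1
                hit = True
        if hit:
            n_mrna += 1
    return counts, n_mrna


def random_instance(rng, n_orfs=None, n_reads=None, ref_len=100_000):
    """A random annotation + read set for oracle-equivalence checks."""
    n_orfs = n_orfs or int(rng.integers(1, 51))
    n_reads = n_reads or int(rng.integers(1, 5001))
    starts = rng.integers(1, ref_len - 3000, size=n_orfs)
    lengths = rng.integers(100, 3000, size=n_orfs)
    feats = [
        GenomicFeature(f"g{i}", "chr", int(s), int(s + l - 1), "+", "CDS")
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]
    ann = GenomeAnnotation(feats)
    r_starts = rng.integers(1, ref_len - 200, size=n_reads)
    r_lens = rng.integers(30, 150, size=n_reads)
    reads = [
        AlignmentRecord(f"r{i}", "chr", int(s), int(s + l - 1), True)
        for i, (s, l) in enumerate(zip(r_starts, r_lens))
    ]
    return ann, reads
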