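"""ORF-level read counting and the two within/across-sample normalizations.

A read is assigned to every protein-coding feature it overlaps by at least
one nucleotide. Per-ORF counts c_i feed two normalizations:

* relative abundance r_i = c_i / N, where N is the number of distinct
  retained reads overlapping any protein-coding region — the quantity used
  for comparisons of the same gene across samples;
* hits per kilobase h_i = c_i * 1000 / L_i, for comparisons of different
  genes within one sample.

A read overlapping k ORFs increments each of the k counts but contributes
exactly once to N, so sum(r_i) >= 1 with equality when no read straddles
two ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

from .alignments import AlignmentRecord, FilterStats
from .annotation import GenomeAnnotation

MULTI_ORF_POLICIES = ("count-each", "discard")


@dataclass
class CountTable:
    """Per-ORF read counts for one sample.

    Every protein-coding feature of the annotation is present (zero counts
    explicit); ``total_mrna_counts`` is N as defined above.
    """

    sample_id: str
    counts: dict[str, int]
    total_mrna_counts: int
    filter_stats: FilterStats | None = None

    def validate(self) -> None:
        total = sum(self.counts.values())
        if self.total_mrna_counts > total:
            raise ValueError(
                f"sample {self.sample_id!r}: N ({self.total_mrna_counts}) exceeds "
                f"summed per-ORF counts ({total})"
            )
        if (
            self.filter_stats is not None
            and self.total_mrna_counts > self.filter_stats.n_retained
        ):
            raise ValueError(
                f"sample {self.sample_id!r}: N exceeds retained read count"
            )


@dataclass
class AbundanceTable:
    sample_id: str
    relative_abundance: dict[str, float]
    hits_per_kb: dict[str, float]


def _cds_trees(annotation: GenomeAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for feat in annotation.protein_coding:
        trees.setdefault(feat.reference, IntervalTree()).addi(
            feat.start, feat.end + 1, feat
        )
    return trees


def count_reads(
    records: Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    sample_id: str = "sample",
    filter_stats: FilterStats | None = None,
    stranded: bool = False,
    multi_orf: str = "count-each",
) -> CountTable:
    """Count reads per ORF by the >= 1 nt overlap rule.

    ``multi_orf`` controls reads overlapping more than one ORF:
    ``count-each`` (default) increments every overlapped ORF and adds one
    to N; ``discard`` drops such reads entirely.

    Raises ``KeyError`` for a record on a reference the annotation does
    not mention.
    """
    if multi_orf not in MULTI_ORF_POLICIES:
        raise ValueError(f"unknown multi-ORF policy {multi_orf!r}")
    trees = _cds_trees(annotation)
    known_refs = annotation.references()
    counts: dict[str, int] = {f.feature_id: 0 for f in annotation.protein_coding}
    n_mrna = 0
    for rec in records:
        if rec.reference not in known_refs:
            raise KeyError(
                f"read {rec.read_id!r} maps to reference {rec.reference!r} "
                "absent from the annotation"
            )
        tree = trees.get(rec.reference)
        if tree is None:
            continue
        hits = tree.overlap(rec.start, rec.end + 1)
        if stranded:
            hits = {iv for iv in hits if iv.data.strand in (rec.strand, ".")}
        if not hits:
            continue
        if multi_orf == "discard" and len(hits) > 1:
            continue
        for iv in hits:
            counts[iv.data.feature_id] += 1
        n_mrna += 1
    table = CountTable(
        sample_id=sample_id,
        counts=counts,
        total_mrna_counts=n_mrna,
        filter_stats=filter_stats,
    )
    table.validate()
    return table


def relative_abundance(table: CountTable) -> dict[str, float]:
    """r_i = c_i / N. Raises on a sample with no mRNA-mapping reads."""
    if table.total_mrna_counts <= 0:
        raise ValueError(f"no mRNA-mapping reads in sample {table.sample_id!r}")
    n = table.total_mrna_counts
    return {fid: c / n for fid, c in table.counts.items()}


def hits_per_kilobase(
    table: CountTable, annotation: GenomeAnnotation
) -> dict[str, float]:
    """h_i = c_i * 1000 / L_i, the within-sample length normalization."""
    out: dict[str, float] = {}
    for fid, c in table.counts.items():
        if fid not in annotation:
            raise KeyError(f"feature {fid!r} has no length in the annotation")
        out[fid] = c * 1000.0 / annotation[fid].length
    return out


def abundance_table(table: CountTable, annotation: GenomeAnnotation) -> AbundanceTable:
    return AbundanceTable(
        sample_id=table.sample_id,
        relative_abundance=relative_abundance(table),
        hits_per_kb=hits_per_kilobase(table, annotation),
    )


def write_count_tsv(
    table: CountTable,
    annotation: GenomeAnnotation,
    path: str,
) -> None:
    """Serialize counts + both normalizations as TSV.

    Header comments carry the sample id, N and the filter statistics as
    ``#key=value`` lines; rows follow annotation order.
    """
    abund = abundance_table(table, annotation)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#sample_id={table.sample_id}\n")
        fh.write(f"#total_mrna_counts={table.total_mrna_counts}\n")
        if table.filter_stats is not None:
            for key, val in table.filter_stats.to_dict().items():
                fh.write(f"#{key}={val}\n")
        fh.write("feature_id\tcount\trelative_abundance\thits_per_kb\n")
        for fid, c in table.counts.items():
            fh.write(
                f"{fid}\t{c}\t{abund.relative_abundance[fid]:.10g}\t"
                f"{abund.hits_per_kb[fid]:.10g}\n"
            )


def read_count_tsv(path: str) -> CountTable:
    """Read a table written by :func:`write_count_tsv`."""
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            if line.startswith("feature_id") or not line:
                continue
            fid, c, _r, _h = line.split("\t")
            counts[fid] = int(c)
    stats = None
    if "n_input" in meta:
        stats = FilterStats(
            n_input=int(meta["n_input"]),
            n_non_unique_removed=int(meta["n_non_unique_removed"]),
            n_rrna_trna_removed=int(meta["n_rrna_trna_removed"]),
            n_retained=int(meta["n_retained"]),
        )
    return CountTable(
        sample_id=meta.get("sample_id", "sample"),
        counts=counts,
        total_mrna_counts=int(meta["total_mrna_counts"]),
        filter_stats=stats,
    )
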