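"""Alignment records and the read-level filters applied before counting.

Two filters run before any read is assigned to an ORF: reads that do not
map to a unique position are removed, then reads overlapping an annotated
rRNA or tRNA feature by at least one nucleotide are removed. The filter
order is fixed (uniqueness first) so that a non-unique rRNA read is always
accounted as non-unique, making :class:`FilterStats` deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pysam
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation

UNIQUE_POLICIES = ("nh-mapq", "mapq", "flag-only")


class SAMFormatError(ValueError):
    """The SAM input is missing a header or otherwise unparseable."""


class AlignmentValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read: a 1-based inclusive interval on a reference.

    ``unique`` is always definite after parsing — the uniqueness policy is
    resolved at read time, never deferred.
    """

    read_id: str
    reference: str
    start: int
    end: int
    unique: bool
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AlignmentValidationError(
                f"read {self.read_id!r}: end ({self.end}) < start ({self.start})"
            )


@dataclass
class FilterStats:
    """Read accounting for one sample; every input read lands in exactly
    one of the three outcome buckets."""

    n_input: int = 0
    n_non_unique_removed: int = 0
    n_rrna_trna_removed: int = 0
    n_retained: int = 0

    def validate(self) -> None:
        if (
            self.n_input
            != self.n_non_unique_removed + self.n_rrna_trna_removed + self.n_retained
        ):
            raise ValueError(f"filter stats do not conserve reads: {self}")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_non_unique_removed": self.n_non_unique_removed,
            "n_rrna_trna_removed": self.n_rrna_trna_removed,
            "n_retained": self.n_retained,
        }

    def to_json(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _is_unique(rec: pysam.AlignedSegment, policy: str, multi_ids: set[str]) -> bool:
    # Reads with secondary records in the same file are never unique.
    if rec.query_name in multi_ids:
        return False
    if policy == "flag-only":
        return True
    if policy == "mapq":
        return rec.mapping_quality > 0
    # default "nh-mapq": NH absent or 1, and MAPQ > 0
    if rec.has_tag("NH") and rec.get_tag("NH") != 1:
        return False
    return rec.mapping_quality > 0


def read_alignments(
    path: str, unique_policy: str = "nh-mapq"
) -> Iterator[AlignmentRecord]:
    """Yield one :class:`AlignmentRecord` per primary mapped SAM record.

    Unmapped records are skipped. Secondary and supplementary records are
    never yielded as reads; their presence marks the read as non-unique.
    Under the default ``nh-mapq`` policy a read is unique iff its record is
    primary, non-supplementary, carries NH absent or NH=1, and has MAPQ > 0.
    ``mapq`` uses MAPQ > 0 alone; ``flag-only`` trusts the flag field.

    Coordinates are converted to 1-based inclusive; the span is the
    reference-consuming length of the alignment (no soft-clip extension).
    """
    if unique_policy not in UNIQUE_POLICIES:
        raise ValueError(f"unknown uniqueness policy {unique_policy!r}")

    # First pass: read ids with secondary/supplementary records.
    multi_ids: set[str] = set()
    try:
        with pysam.AlignmentFile(path, "r", check_sq=True) as sam:
            for rec in sam:
                if rec.is_secondary or rec.is_supplementary:
                    multi_ids.add(rec.query_name)
    except ValueError as exc:
        raise SAMFormatError(f"{path}: {exc}") from exc

    with pysam.AlignmentFile(path, "r", check_sq=True) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield AlignmentRecord(
                read_id=rec.query_name,
                reference=rec.reference_name,
                start=rec.reference_start + 1,
                end=rec.reference_end,  # pysam end is exclusive 0-based
                unique=_is_unique(rec, unique_policy, multi_ids),
                strand="-" if rec.is_reverse else "+",
            )


def read_alignments_tsv(path: str) -> Iterator[AlignmentRecord]:
    """Read the simplified alignment dialect used for fixtures.

    Tab-separated columns: read_id, reference, start, end, unique (0/1),
    with 1-based inclusive coordinates; an optional sixth column carries
    the strand. Lines starting with ``#`` are skipped.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (5, 6):
                raise SAMFormatError(
                    f"{path}:{lineno}: expected 5 or 6 columns, got {len(cols)}"
                )
            strand = cols[5] if len(cols) == 6 else "."
            yield AlignmentRecord(
                read_id=cols[0],
                reference=cols[1],
                start=int(cols[2]),
                end=int(cols[3]),
                unique=bool(int(cols[4])),
                strand=strand,
            )


def _excluded_trees(annotation: GenomeAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for feat in annotation.excluded_regions:
        trees.setdefault(feat.reference, IntervalTree()).addi(
            feat.start, feat.end + 1, feat
        )
    return trees


def filter_alignments(
    records: Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    stranded: bool = False,
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Apply the pre-counting read filters.

    Removes, in order: reads with ``unique=False``; then reads overlapping
    any rRNA/tRNA feature by >= 1 nt (any strand unless ``stranded``).
    Returns the retained records (input order preserved) and the
    per-outcome accounting.
    """
    trees = _excluded_trees(annotation)
    stats = FilterStats()
    retained: list[AlignmentRecord] = []
    for rec in records:
        stats.n_input += 1
        if not rec.unique:
            stats.n_non_unique_removed += 1
            continue
        hits = trees.get(rec.reference)
        overlapping = hits.overlap(rec.start, rec.end + 1) if hits else ()
        if stranded:
            overlapping = [
                iv for iv in overlapping if iv.data.strand in (rec.strand, ".")
            ]
        if overlapping:
            stats.n_rrna_trna_removed += 1
            continue
        stats.n_retained += 1
        retained.append(rec)
    stats.validate()
    return retained, stats


def write_sam(
    records: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    path: str,
    read_length: int | None = None,
) -> None:
    """Write records as plain-text SAM (ungapped, sequence omitted).

    Non-unique reads are written with MAPQ 0 so they round-trip through
    :func:`read_alignments` under every uniqueness policy.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": int(length)}
            for name, length in reference_lengths.items()
        ],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.flag = 16 if rec.strand == "-" else 0
            seg.reference_id = out.header.get_tid(rec.reference)
            seg.reference_start = rec.start - 1
            span = rec.end - rec.start + 1
            seg.cigarstring = f"{span}M"
            seg.mapping_quality = 30 if rec.unique else 0
            seg.query_sequence = "N" * span
            seg.query_qualities = pysam.qualitystring_to_array("I" * span)
            if not rec.unique:
                seg.set_tag("NH", 2)
            out.write(seg)


def write_alignments_tsv(records: Iterable[AlignmentRecord], path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#read_id\treference\tstart\tend\tunique\tstrand\n")
        for rec in records:
            fh.write(
                f"{rec.read_id}\t{rec.reference}\t{rec.start}\t{rec.end}\t"
                f"{int(rec.unique)}\t{rec.strand}\n"
            )
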