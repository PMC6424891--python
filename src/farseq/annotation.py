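"""Genome annotations for ORF-level read counting.

Features are carried with 1-based inclusive coordinates exactly as they
appear in GFF3. Protein-coding features (CDS) are the counting universe;
rRNA and tRNA features define the regions whose reads are discarded before
quantification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

FEATURE_CLASSES = ("CDS", "rRNA", "tRNA", "other")

#: GFF3 feature-type column -> internal feature class. Types not listed
#: (gene, exon, region, ...) fall through to "other".
DEFAULT_TYPE_ALIASES: Mapping[str, str] = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ribosomal_RNA": "rRNA",
    "transfer_RNA": "tRNA",
}


class GFF3FormatError(ValueError):
    """A line of the annotation file could not be parsed."""


class AnnotationValidationError(ValueError):
    """A parsed feature violates a coordinate or uniqueness invariant."""


@dataclass(frozen=True)
class GenomicFeature:
    """One annotated feature on the reference.

    Coordinates are 1-based and inclusive at both ends, so
    ``length == end - start + 1``.
    """

    feature_id: str
    reference: str
    start: int
    end: int
    strand: str = "."
    feature_class: str = "other"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationValidationError(
                f"feature {self.feature_id!r}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise AnnotationValidationError(
                f"feature {self.feature_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationValidationError(
                f"feature {self.feature_id!r}: unknown feature class "
                f"{self.feature_class!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationValidationError(
                f"feature {self.feature_id!r}: strand must be '+', '-' or '.', "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        """True when [start, end] (1-based inclusive) shares >= 1 nt."""
        return start <= self.end and end >= self.start


class GenomeAnnotation:
    """An indexed collection of :class:`GenomicFeature`.

    ``protein_coding`` (CDS) and ``excluded_regions`` (rRNA + tRNA) views
    preserve input order, which downstream tables inherit.
    """

    def __init__(self, features: Iterable[GenomicFeature]) -> None:
        self.features: list[GenomicFeature] = list(features)
        self._by_id: dict[str, GenomicFeature] = {}
        for feat in self.features:
            if feat.feature_id in self._by_id:
                raise AnnotationValidationError(
                    f"duplicate feature_id {feat.feature_id!r}"
                )
            self._by_id[feat.feature_id] = feat

    @property
    def protein_coding(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.feature_class == "CDS"]

    @property
    def excluded_regions(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.feature_class in ("rRNA", "tRNA")]

    def references(self) -> set[str]:
        return {f.reference for f in self.features}

    def __getitem__(self, feature_id: str) -> GenomicFeature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self.features)


_ATTR_ID_KEYS = ("ID", "locus_tag", "Name", "gene_id")


def _attr_dict(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, val = part.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_annotation(
    path: str,
    type_aliases: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    Feature identifiers come from the ``ID``, ``locus_tag``, ``Name`` or
    ``gene_id`` attribute, in that order of preference; features without
    any of them get a positional identifier. ``type_aliases`` maps GFF3
    type-column values onto the internal classes CDS/rRNA/tRNA; unknown
    types become class ``other``.

    Raises
    ------
    GFF3FormatError
        for a line that is not 9 tab-separated columns or has non-numeric
        coordinates (the message names the line number).
    AnnotationValidationError
        for ``end < start`` or duplicate feature identifiers.
    """
    aliases = dict(DEFAULT_TYPE_ALIASES)
    if type_aliases:
        aliases.update(type_aliases)

    features: list[GenomicFeature] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            ref, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if not re.fullmatch(r"\d+", start_s) or not re.fullmatch(r"\d+", end_s):
                raise GFF3FormatError(
                    f"{path}:{lineno}: non-numeric coordinates "
                    f"{start_s!r}..{end_s!r}"
                )
            start, end = int(start_s), int(end_s)
            attr = _attr_dict(attrs)
            fid = next(
                (attr[k] for k in _ATTR_ID_KEYS if k in attr),
                f"{ftype}:{ref}:{start_s}-{end_s}",
            )
            fclass = aliases.get(ftype, "other")
            if strand not in ("+", "-"):
                strand = "."
            try:
                features.append(
                    GenomicFeature(
                        feature_id=fid,
                        reference=ref,
                        start=start,
                        end=end,
                        strand=strand,
                        feature_class=fclass,
                    )
                )
            except AnnotationValidationError as exc:
                raise AnnotationValidationError(f"{path}:{lineno}: {exc}") from exc
    return GenomeAnnotation(features)


def write_gff3(annotation: GenomeAnnotation, path: str, source: str = "farseq") -> None:
    """Write the annotation back out as GFF3 (round-trippable)."""
    class_to_type = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "other": "region"}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for feat in annotation:
            fh.write(
                "\t".join(
                    [
                        feat.reference,
                        source,
                        class_to_type[feat.feature_class],
                        str(feat.start),
                        str(feat.end),
                        ".",
                        feat.strand if feat.strand in ("+", "-") else ".",
                        ".",
                        f"ID={feat.feature_id}",
                    ]
                )
                + "\n"
            )
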