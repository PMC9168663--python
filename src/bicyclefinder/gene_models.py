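"""Transcript models and GFF3 input/output.

A transcript is represented as an ordered sequence of coding segments
(CDS features) in *translation order*: the first segment contains the
first codon of the open reading frame regardless of strand.  On the plus
strand translation order equals genomic order; on the minus strand it is
reversed.  All coordinates are GFF3-style 1-based inclusive.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

LABELS = ("family", "non_family", "unlabeled")


class GeneModelError(ValueError):
    """Malformed annotation input (bad coordinates, conflicting strands, bad labels)."""


@dataclass(frozen=True)
class CodingSegment:
    """One CDS segment: 1-based inclusive genomic interval on one strand."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GeneModelError(
                f"coding segment with start > end: {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One transcript's coding segments in translation order, with its training label."""

    transcript_id: str
    gene_id: str
    segments: tuple[CodingSegment, ...]
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        if self.label not in LABELS:
            raise GeneModelError(
                f"unknown label {self.label!r} for {self.transcript_id}; expected one of {LABELS}"
            )

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    @property
    def seq_id(self) -> str:
        return self.segments[0].seq_id

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def genomic_span(self) -> tuple[int, int]:
        """(min start, max end) over coding segments -- start codon through stop codon."""
        return min(s.start for s in self.segments), max(s.end for s in self.segments)


@dataclass
class ValidationReport:
    transcript_id: str
    ok: bool
    reasons: list[str] = field(default_factory=list)


def phases_from_lengths(lengths: Sequence[int]) -> list[int]:
    """GFF3 phase of each coding exon from exon lengths in translation order.

    The phase of exon *i* is the number of bases at its start that must be
    skipped to reach the next codon boundary: ``(3 - cum % 3) % 3`` where
    ``cum`` is the total coding length of exons ``1..i-1``.  The first exon
    therefore has phase 0.
    """
    phases = []
    cum = 0
    for length in lengths:
        phases.append((3 - cum % 3) % 3)
        cum += length
    return phases


def validate_transcript(t: TranscriptModel) -> ValidationReport:
    """Check a transcript model for structural consistency.

    Failures are reported, not raised: fragmented assemblies routinely
    produce broken gene models and those must be flagged rather than abort
    a genome-wide scan.
    """
    reasons: list[str] = []
    if not t.segments:
        return ValidationReport(t.transcript_id, False, ["no coding segments"])
    seq_ids = {s.seq_id for s in t.segments}
    strands = {s.strand for s in t.segments}
    if len(seq_ids) > 1:
        reasons.append(f"segments on multiple sequences: {sorted(seq_ids)}")
    if len(strands) > 1:
        reasons.append("segments on conflicting strands")
    if any(s.length < 1 for s in t.segments):
        reasons.append("segment with length < 1")
    # overlap + translation-order monotonicity (only meaningful on one strand)
    if len(strands) == 1 and len(t.segments) > 1:
        by_coord = sorted(t.segments, key=lambda s: s.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if b.start <= a.end:
                reasons.append(f"overlap between {a.start}-{a.end} and {b.start}-{b.end}")
                break
        strand = t.segments[0].strand
        ordered = t.segments if strand == "+" else tuple(reversed(t.segments))
        if any(b.start < a.start for a, b in zip(ordered, ordered[1:])):
            reasons.append("segments not in translation order")
    if t.cds_length % 3 != 0:
        reasons.append("CDS length not multiple of 3")
    return ValidationReport(t.transcript_id, not reasons, reasons)


def _read_label_table(path: str | os.PathLike) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GeneModelError(f"label table line {lineno}: expected 2 tab-separated columns")
            tid, label = parts
            if lineno == 1 and (tid, label) == ("transcript_id", "label"):
                continue  # optional header row
            if label not in ("family", "non_family"):
                raise GeneModelError(
                    f"label table line {lineno}: unknown label {label!r} "
                    "(expected 'family' or 'non_family')"
                )
            labels[tid] = label
    return labels


def read_gff3(
    path: str | os.PathLike,
    label_table: str | os.PathLike | None = None,
) -> list[TranscriptModel]:
    """Read CDS features from a GFF3 file into transcript models.

    CDS features are grouped by their ``Parent`` attribute (falling back to
    ``transcript_id``), sorted into translation order, and labeled from the
    optional two-column ``transcript_id<TAB>label`` table.  Transcripts not
    listed in the table are labeled ``unlabeled``.
    """
    labels = _read_label_table(label_table) if label_table is not None else {}
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=False,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    by_transcript: dict[str, list[gffutils.Feature]] = {}
    tid_to_gene: dict[str, str] = {}
    for feat in db.features_of_type("mRNA"):
        parents = feat.attributes.get("Parent", [])
        tid_to_gene[feat.id] = parents[0] if parents else feat.id
    for feat in db.features_of_type("CDS"):
        if feat.start > feat.end:
            raise GeneModelError(
                f"CDS with start > end at {feat.seqid}:{feat.start}-{feat.end} "
                f"(feature {feat.id or '?'})"
            )
        parents = feat.attributes.get("Parent") or feat.attributes.get("transcript_id")
        if not parents:
            raise GeneModelError(
                f"CDS at {feat.seqid}:{feat.start}-{feat.end} has no Parent/transcript_id attribute"
            )
        by_transcript.setdefault(parents[0], []).append(feat)

    transcripts = []
    for tid in sorted(by_transcript):
        feats = by_transcript[tid]
        strands = {f.strand for f in feats}
        if len(strands) > 1:
            raise GeneModelError(f"transcript {tid}: CDS features on conflicting strands")
        strand = strands.pop()
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        segments = tuple(
            CodingSegment(f.seqid, f.start, f.end, strand) for f in feats
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=tid_to_gene.get(tid, tid),
                segments=segments,
                label=labels.get(tid, "unlabeled"),
            )
        )
    return transcripts


def write_gff3(transcripts: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcripts as gene/mRNA/CDS GFF3 rows.

    The phase column is recomputed from cumulative coding length in
    translation order.  Transcripts must validate; the round trip
    ``read_gff3(write_gff3(x))`` reproduces segments, strands and ids.
    """
    lines = ["##gff-version 3"]
    for t in transcripts:
        report = validate_transcript(t)
        if not report.ok:
            raise GeneModelError(
                f"refusing to write invalid transcript {t.transcript_id}: "
                + "; ".join(report.reasons)
            )
        lo, hi = t.genomic_span
        strand = t.strand
        lines.append(
            f"{t.seq_id}\tbicyclefinder\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID={t.gene_id}"
        )
        lines.append(
            f"{t.seq_id}\tbicyclefinder\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\t"
            f"ID={t.transcript_id};Parent={t.gene_id}"
        )
        phases = phases_from_lengths([s.length for s in t.segments])
        rows = sorted(zip(t.segments, phases), key=lambda sp: sp[0].start)
        for i, (seg, phase) in enumerate(rows, 1):
            lines.append(
                f"{seg.seq_id}\tbicyclefinder\tCDS\t{seg.start}\t{seg.end}\t.\t{strand}\t"
                f"{phase}\tID={t.transcript_id}.cds{i};Parent={t.transcript_id}"
            )
    path = Path(path)
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise GeneModelError(f"cannot write GFF3 to {path}: {exc}") from exc


def longest_cds_per_gene(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Optional isoform collapse: keep the transcript with the longest CDS per gene.

    Off by default everywhere; provided because annotation sets differ in
    whether isoforms are pre-collapsed.  Ties break by transcript_id.
    """
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if cur is None or (t.cds_length, cur.transcript_id) > (cur.cds_length, t.transcript_id):
            best[t.gene_id] = t
    return [best[g] for g in sorted(best)]


def mirror_transcript(t: TranscriptModel, axis: int | None = None) -> TranscriptModel:
    """Reflect a transcript onto the opposite strand around a coordinate axis.

    Utility for strand-symmetry checks: structural features must be
    identical for a transcript and its mirrored copy.
    """
    lo, hi = t.genomic_span
    if axis is None:
        axis = lo + hi
    new_strand = "-" if t.strand == "+" else "+"
    segments = tuple(
        CodingSegment(s.seq_id, axis - s.end, axis - s.start, new_strand) for s in t.segments
    )
    return replace(t, segments=segments)
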