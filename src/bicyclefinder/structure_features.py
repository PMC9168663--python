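"""The eight structural predictors of the classifier, plus descriptive statistics.

For each eligible transcript (at least four coding exons, i.e. at least two
internal exons) the predictors are:

* ``gene_span_len``          genomic span from start codon through stop codon,
                             introns included (bases)
* ``cds_total_len``          summed length of all coding exons (bases)
* ``first_exon_len``         first coding exon (bases)
* ``last_exon_len``          last coding exon (bases)
* ``internal_exon_mean_len`` mean length of coding exons excluding the first
                             and last (bases)
* ``n_phase0/1/2``           counts of internal exons starting in phase 0/1/2

Exon phase follows the GFF3 phase-column convention: the number of bases at
the exon start that must be skipped to reach a codon boundary, i.e.
``(3 - upstream_coding_length % 3) % 3``.  Phases are always recomputed from
coordinates; the file's phase column is never trusted (fragmented
annotations commonly carry wrong phases), though ``strict`` mode errors on
disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bicyclefinder.gene_models import (
    TranscriptModel,
    phases_from_lengths,
    validate_transcript,
)

FEATURE_NAMES = (
    "gene_span_len",
    "cds_total_len",
    "first_exon_len",
    "last_exon_len",
    "internal_exon_mean_len",
    "n_phase0",
    "n_phase1",
    "n_phase2",
)

#: fixed column order of the feature table on disk
TABLE_COLUMNS = ("transcript_id",) + FEATURE_NAMES + ("label",)

MIN_EXONS = 4  # below this, internal-exon statistics cannot be estimated


class MalformedTranscriptError(ValueError):
    """Transcript fails structural validation."""


class IneligibleTranscriptError(ValueError):
    """Transcript is well-formed but has fewer than four coding exons."""


@dataclass(frozen=True)
class StructureFeatures:
    transcript_id: str
    gene_span_len: int
    cds_total_len: int
    first_exon_len: int
    last_exon_len: int
    internal_exon_mean_len: float
    n_phase0: int
    n_phase1: int
    n_phase2: int


@dataclass(frozen=True)
class DistComparison:
    """Two-sample Kolmogorov-Smirnov comparison of exon-count distributions."""

    statistic: float
    p_value: float
    group_sizes: tuple[int, int]


def exon_phases(t: TranscriptModel, strict_phase_column: Sequence[int] | None = None) -> list[int]:
    """GFF3 phase of each coding exon in translation order.

    The first exon has phase 0 by construction.  If ``strict_phase_column``
    is given (phases as read from a file, translation order), any
    disagreement with the recomputed phases raises.
    """
    report = validate_transcript(t)
    if not report.ok:
        raise MalformedTranscriptError(
            f"{t.transcript_id}: " + "; ".join(report.reasons)
        )
    phases = phases_from_lengths([s.length for s in t.segments])
    if strict_phase_column is not None and list(strict_phase_column) != phases:
        raise MalformedTranscriptError(
            f"{t.transcript_id}: annotated phase column {list(strict_phase_column)} "
            f"disagrees with phases recomputed from coordinates {phases}"
        )
    return phases


def extract_features(t: TranscriptModel) -> StructureFeatures:
    """Compute the eight structural predictors for one transcript.

    Raises :class:`MalformedTranscriptError` for invalid models and
    :class:`IneligibleTranscriptError` for well-formed transcripts with
    fewer than four coding exons (internal-exon statistics undefined).
    """
    phases = exon_phases(t)  # validates
    n = len(t.segments)
    if n < MIN_EXONS:
        raise IneligibleTranscriptError(
            f"{t.transcript_id}: {n} coding exon(s); at least {MIN_EXONS} required"
        )
    lengths = [s.length for s in t.segments]
    internal = lengths[1:-1]
    internal_phases = phases[1:-1]
    lo, hi = t.genomic_span
    return StructureFeatures(
        transcript_id=t.transcript_id,
        gene_span_len=hi - lo + 1,
        cds_total_len=sum(lengths),
        first_exon_len=lengths[0],
        last_exon_len=lengths[-1],
        internal_exon_mean_len=sum(internal) / len(internal),
        n_phase0=internal_phases.count(0),
        n_phase1=internal_phases.count(1),
        n_phase2=internal_phases.count(2),
    )


def feature_table(
    transcripts: Iterable[TranscriptModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature rows for all eligible transcripts plus an exclusion report.

    Returns ``(features, excluded)``: one feature row per eligible
    transcript (columns per :data:`TABLE_COLUMNS`), and a two-column
    ``(transcript_id, reason)`` report for invalid or ineligible ones.
    Row counts always add up to the input count.
    """
    rows = []
    excluded = []
    for t in transcripts:
        try:
            feats = extract_features(t)
        except (MalformedTranscriptError, IneligibleTranscriptError) as exc:
            kind = "invalid" if isinstance(exc, MalformedTranscriptError) else "ineligible"
            excluded.append({"transcript_id": t.transcript_id, "reason": f"{kind}: {exc}"})
            continue
        row = asdict(feats)
        row["label"] = t.label
        rows.append(row)
    features = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    report = pd.DataFrame(excluded, columns=["transcript_id", "reason"])
    return features, report


def compare_exon_count_distributions(
    group_a: Sequence[int], group_b: Sequence[int]
) -> DistComparison:
    """Two-sample KS test between two sets of per-transcript exon counts."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return DistComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(a.size, b.size),
    )
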