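import pytest

from bicyclefinder.gene_models import CodingSegment, TranscriptModel
from bicyclefinder import synthetic_data as sd


def make_transcript(
    lengths,
    strand="+",
    seq_id="chr1",
    start=100,
    intron=50,
    transcript_id="t1",
    gene_id="g1",
    label="unlabeled",
):
    """Build a transcript from exon lengths in translation order.

    Exons are laid left-to-right on the genome for '+', right-to-left for
    '-', separated by fixed-size introns, so the translation-order segment
    list always starts with the first codon.
    """
    genomic = list(lengths) if strand == "+" else list(reversed(lengths))
    spans = []
    pos = start
    for ln in genomic:
        spans.append((pos, pos + ln - 1))
        pos += ln + intron
    if strand == "-":
        spans.reverse()
    segments = tuple(CodingSegment(seq_id, s, e, strand) for s, e in spans)
    return TranscriptModel(transcript_id=transcript_id, gene_id=gene_id, segments=segments, label=label)


@pytest.fixture(scope="session")
def small_genome():
    """A small simulated genome reused across read/feature/classify tests."""
    params = sd.GenomeSimParams(n_family=60, n_background=300, seed=11)
    return sd.simulate_genome_annotation(params)


@pytest.fixture(scope="session")
def small_genome_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("genome")
    sd.simulate_genome_annotation(sd.GenomeSimParams(n_family=60, n_background=300, seed=11), out_dir=out)
    return out
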