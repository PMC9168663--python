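"""Intron-position concordance between aligned protein families.

Shared gene structure corroborates homology calls made from structural
features alone: if two families are homologous, their introns tend to fall
at the same columns of a joint protein alignment.  Each intron is assigned
to the alignment column of the residue immediately preceding it; per-column
counts of intron-bearing sequences form an intron profile (a histogram with
bin size 1), and concordance between two families is the Pearson
correlation R of their count profiles across columns.  Significance comes
from a resampling null: either permuting the columns of one profile
(self-contained default) or recomputing R against resampled unrelated
families.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP = "-"


@dataclass
class AlignedFamily:
    """A rectangular gapped protein alignment plus per-sequence intron annotations.

    ``introns[i]`` lists ``(residue_index, phase)`` pairs for sequence
    ``ids[i]``: the intron falls immediately after the 1-based
    ``residue_index`` of the *ungapped* protein, interrupting the codon
    with the given phase.  ``residue_index`` 0 marks an intron before the
    first residue (5' boundary).
    """

    family_id: str
    ids: list[str]
    rows: list[str]
    introns: list[list[tuple[int, int]]]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows} or {0}) > 1:
            raise ValueError(f"family {self.family_id}: alignment is not rectangular")
        if not (len(self.ids) == len(self.rows) == len(self.introns)):
            raise ValueError(f"family {self.family_id}: ids/rows/introns length mismatch")
        for sid, row, anns in zip(self.ids, self.rows, self.introns):
            ungapped = len(row) - row.count(GAP)
            for residue_index, phase in anns:
                if not 0 <= residue_index <= ungapped:
                    raise ValueError(
                        f"family {self.family_id}, sequence {sid}: intron residue index "
                        f"{residue_index} out of range (ungapped length {ungapped})"
                    )
                if phase not in (0, 1, 2):
                    raise ValueError(
                        f"family {self.family_id}, sequence {sid}: invalid phase {phase}"
                    )

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class IntronProfile:
    """Per-column counts of sequences carrying an intron at that column."""

    counts: np.ndarray  # length = alignment width
    n_seqs: int
    n_boundary: int = 0  # introns before residue 1; excluded from correlation

    @property
    def fraction(self) -> np.ndarray:
        return self.counts / self.n_seqs


@dataclass
class ConcordanceResult:
    R: float
    null_R: np.ndarray
    p_empirical: float
    n_resamples: int
    seed: int | None


def read_family(
    fasta_path: str | os.PathLike,
    introns_path: str | os.PathLike,
    family_id: str | None = None,
) -> AlignedFamily:
    """Load an aligned FASTA plus a (sequence_id, residue_index, phase) intron TSV."""
    with open(fasta_path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    table = pd.read_csv(
        introns_path,
        sep="\t",
        comment="#",
        names=["sequence_id", "residue_index", "phase"],
        header=0,
    )
    by_id: dict[str, list[tuple[int, int]]] = {i: [] for i in ids}
    for rec in table.itertuples(index=False):
        if rec.sequence_id not in by_id:
            raise ValueError(f"intron table references unknown sequence {rec.sequence_id!r}")
        by_id[rec.sequence_id].append((int(rec.residue_index), int(rec.phase)))
    return AlignedFamily(
        family_id=family_id or os.path.basename(str(fasta_path)),
        ids=ids,
        rows=rows,
        introns=[by_id[i] for i in ids],
    )


def write_family(fam: AlignedFamily, fasta_path: str | os.PathLike, introns_path: str | os.PathLike) -> None:
    with open(fasta_path, "w") as fh:
        for sid, row in zip(fam.ids, fam.rows):
            fh.write(f">{sid}\n{row}\n")
    with open(introns_path, "w") as fh:
        fh.write("sequence_id\tresidue_index\tphase\n")
        for sid, anns in zip(fam.ids, fam.introns):
            for residue_index, phase in anns:
                fh.write(f"{sid}\t{residue_index}\t{phase}\n")


def residue_columns(row: str) -> np.ndarray:
    """0-based alignment column of each ungapped residue of one aligned row."""
    return np.flatnonzero(np.frombuffer(row.encode(), dtype="S1") != GAP.encode())


def project_introns(fam: AlignedFamily) -> IntronProfile:
    """Aggregate each sequence's introns onto alignment columns.

    An intron after residue *r* lands on the column holding residue *r*
    (the residue immediately preceding it); gap columns never receive
    introns.  Introns before residue 1 are tallied separately in
    ``n_boundary`` and excluded from downstream correlation.
    """
    counts = np.zeros(fam.n_columns, dtype=int)
    n_boundary = 0
    for row, anns in zip(fam.rows, fam.introns):
        cols = residue_columns(row)
        for residue_index, _phase in anns:
            if residue_index == 0:
                n_boundary += 1
            else:
                counts[cols[residue_index - 1]] += 1
    return IntronProfile(counts=counts, n_seqs=fam.n_seqs, n_boundary=n_boundary)


def concordance_R(a: IntronProfile | np.ndarray, b: IntronProfile | np.ndarray) -> float:
    """Pearson correlation of two per-column intron count profiles."""
    va = a.counts if isinstance(a, IntronProfile) else np.asarray(a, dtype=float)
    vb = b.counts if isinstance(b, IntronProfile) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("profiles must cover the same alignment columns")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("undefined correlation: constant intron profile")
    va = va - va.mean()
    vb = vb - vb.mean()
    return float(va @ vb / np.sqrt((va @ va) * (vb @ vb)))


def null_distribution(
    fam_a: AlignedFamily,
    fam_b: AlignedFamily,
    mode: str = "permute_columns",
    n_resamples: int = 200,
    seed: int | None = None,
    unrelated: Sequence[AlignedFamily] | None = None,
) -> np.ndarray:
    """Sample of concordance R values under the no-shared-structure null.

    ``permute_columns`` (default, self-contained): the second family's
    profile columns are randomly permuted before each correlation,
    destroying positional correspondence while preserving both marginal
    histograms.  ``unrelated_families``: each resample bootstrap-samples
    the rows of one of the supplied unrelated families (aligned to the
    same width), re-projects, and correlates against ``fam_a``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    prof_a = project_introns(fam_a)
    if np.ptp(prof_a.counts) == 0:
        raise ValueError("undefined correlation: constant intron profile")
    out = np.empty(n_resamples)
    if mode == "permute_columns":
        prof_b = project_introns(fam_b)
        if np.ptp(prof_b.counts) == 0:
            raise ValueError("undefined correlation: constant intron profile")
        for i in range(n_resamples):
            out[i] = concordance_R(prof_a.counts, rng.permutation(prof_b.counts))
    elif mode == "unrelated_families":
        if not unrelated:
            raise ValueError("unrelated_families mode requires at least one unrelated family")
        for fam in unrelated:
            if fam.n_columns != fam_a.n_columns:
                raise ValueError(
                    f"unrelated family {fam.family_id} has width {fam.n_columns}, "
                    f"expected {fam_a.n_columns}"
                )
        for i in range(n_resamples):
            fam = unrelated[rng.integers(len(unrelated))]
            idx = rng.integers(fam.n_seqs, size=fam.n_seqs)
            boot = AlignedFamily(
                family_id=f"{fam.family_id}:boot",
                ids=[f"s{j}" for j in range(len(idx))],
                rows=[fam.rows[j] for j in idx],
                introns=[fam.introns[j] for j in idx],
            )
            out[i] = concordance_R(prof_a, project_introns(boot))
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    return out


def empirical_p(r_obs: float, null_r: np.ndarray) -> float:
    """One-sided empirical p-value for excess concordance: (1 + #{null >= R}) / (1 + n)."""
    null_r = np.asarray(null_r, dtype=float)
    if null_r.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.sum(null_r >= r_obs)) / (1 + null_r.size))


def concordance_test(
    fam_a: AlignedFamily,
    fam_b: AlignedFamily,
    mode: str = "permute_columns",
    n_resamples: int = 200,
    seed: int | None = None,
    unrelated: Sequence[AlignedFamily] | None = None,
) -> ConcordanceResult:
    """Observed concordance R between two families plus a resampling null and p-value."""
    r_obs = concordance_R(project_introns(fam_a), project_introns(fam_b))
    null = null_distribution(
        fam_a, fam_b, mode=mode, n_resamples=n_resamples, seed=seed, unrelated=unrelated
    )
    return ConcordanceResult(
        R=r_obs,
        null_R=null,
        p_empirical=empirical_p(r_obs, null),
        n_resamples=n_resamples,
        seed=seed,
    )


def plot_profiles(
    profiles: Sequence[IntronProfile],
    labels: Sequence[str],
    path: str | os.PathLike,
) -> None:
    """Bin-size-1 histogram of the fraction of sequences with an intron per column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(profiles), 1, sharex=True, squeeze=False)
    for ax, prof, label in zip(axes[:, 0], profiles, labels):
        ax.bar(np.arange(1, len(prof.counts) + 1), prof.fraction, width=1.0)
        ax.set_ylabel("fraction")
        ax.set_title(label, fontsize=9)
    axes[-1, 0].set_xlabel("alignment column")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
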