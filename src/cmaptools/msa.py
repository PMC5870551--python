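"""Alignment quality statistics: identity, effective depth, coverage, trimming.

The depth of a multiple sequence alignment is the main determinant of
co-evolution-based contact prediction quality, but raw sequence counts
overstate it when the alignment is redundant.  The number of effective
sequences (Neff) corrects for redundancy by the standard reweighting
formula

    Neff = sum_i 1 / |{ j : identity(i, j) >= t }|,

where the neighbourhood of sequence i includes i itself (so every term is
well defined) and t is the identity threshold, 0.8 by default.  Pairwise
identity is the fraction of alignment columns where both sequences carry
the same non-gap residue, with the full alignment length as denominator:
gaps never match, and heavily gapped sequences are therefore down-weighted
less aggressively than their neighbours.

Identity computation is exact O(N^2 L) over the full alignment; these are
desk-scale inputs and correctness beats approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List

import numpy as np

from .core import Sequence, SequenceFile

__all__ = [
    "AlignmentStats",
    "pairwise_identity",
    "effective_sequences",
    "per_column_depth",
    "per_sequence_coverage",
    "trim_by_coverage",
    "alignment_stats",
    "DEFAULT_IDENTITY_THRESHOLD",
]

DEFAULT_IDENTITY_THRESHOLD = 0.8

_GAP = ord("-")


def _as_matrix(aln: SequenceFile) -> np.ndarray:
    """The alignment as an (N, L) uint8 character matrix."""
    if len(aln) == 0:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aln}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    joined = "".join(s.seq for s in aln)
    return np.frombuffer(joined.encode("ascii"), dtype=np.uint8).reshape(
        len(aln), -1
    )


def pairwise_identity(a: Sequence, b: Sequence) -> float:
    """Fraction of columns where both sequences carry the same non-gap residue.

    The denominator is the full alignment length, so gap columns count
    against identity.  Symmetric and deterministic.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequence lengths differ ({len(a)} vs {len(b)}); "
            "identity is defined for alignment members only"
        )
    matches = sum(
        1 for x, y in zip(a.seq, b.seq) if x == y and x != Sequence.GAP
    )
    return matches / len(a)


def effective_sequences(
    aln: SequenceFile, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> float:
    """Number of effective sequences (Neff) at the given identity threshold.

    Sum over sequences of the inverse size of their neighbourhood, a
    neighbour being any sequence (self included) at identity >= threshold.
    Bounded by 1 (fully redundant) and N (no two sequences similar).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    mat = _as_matrix(aln)
    n, length = mat.shape
    nongap = mat != _GAP
    # integer match counts compared against t*L avoids float-division jitter;
    # exact rational accumulation keeps N identical sequences at Neff == 1.0
    cut = identity_threshold * length - 1e-9
    neff = Fraction(0)
    for i in range(n):
        eq = (mat == mat[i]) & nongap & nongap[i]
        above = eq.sum(axis=1) >= cut
        # the sequence itself is always its own neighbour, even when gaps
        # push its full-length self-identity below the threshold
        above[i] = True
        neff += Fraction(1, int(np.count_nonzero(above)))
    return float(neff)


def per_column_depth(aln: SequenceFile) -> List[int]:
    """Count of sequences with a non-gap character, per alignment column."""
    mat = _as_matrix(aln)
    return (mat != _GAP).sum(axis=0).astype(int).tolist()


def per_sequence_coverage(aln: SequenceFile) -> List[float]:
    """Fraction of non-gap positions, per sequence."""
    mat = _as_matrix(aln)
    return ((mat != _GAP).sum(axis=1) / mat.shape[1]).tolist()


def trim_by_coverage(
    aln: SequenceFile,
    min_sequence_coverage: float = 0.0,
    min_column_depth_fraction: float = 0.0,
) -> SequenceFile:
    """Trim an alignment to its well-covered core.

    Sequences below ``min_sequence_coverage`` are dropped first (the first
    sequence — the query the contact indices refer to — is never dropped),
    then columns whose depth among the remaining sequences falls below
    ``min_column_depth_fraction``.  Original order is preserved.
    """
    for name, value in (
        ("min_sequence_coverage", min_sequence_coverage),
        ("min_column_depth_fraction", min_column_depth_fraction),
    ):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    coverage = per_sequence_coverage(aln)
    keep_rows = [
        i
        for i, cov in enumerate(coverage)
        if i == 0 or cov >= min_sequence_coverage - 1e-12
    ]
    if not keep_rows:
        raise ValueError(
            "sequence-coverage filter removed every sequence; lower "
            f"min_sequence_coverage={min_sequence_coverage}"
        )
    mat = _as_matrix(aln)[keep_rows]
    depth = (mat != _GAP).sum(axis=0) / mat.shape[0]
    keep_cols = np.nonzero(depth >= min_column_depth_fraction - 1e-12)[0]
    if keep_cols.size == 0:
        raise ValueError(
            "column-depth filter removed every column; lower "
            f"min_column_depth_fraction={min_column_depth_fraction}"
        )
    trimmed = mat[:, keep_cols]
    sequences = [
        Sequence(id=aln[i].id, seq=trimmed[k].tobytes().decode("ascii"))
        for k, i in enumerate(keep_rows)
    ]
    return SequenceFile(id=aln.id, sequences=sequences, is_alignment=True)


@dataclass(frozen=True)
class AlignmentStats:
    """Summary statistics of one alignment at a fixed identity threshold."""

    n_sequences: int
    length: int
    neff: float
    identity_threshold: float
    per_column_depth: List[int]
    per_sequence_coverage: List[float]


def alignment_stats(
    aln: SequenceFile, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> AlignmentStats:
    """Compute all alignment statistics in one pass."""
    mat = _as_matrix(aln)
    return AlignmentStats(
        n_sequences=mat.shape[0],
        length=mat.shape[1],
        neff=effective_sequences(aln, identity_threshold),
        identity_threshold=identity_threshold,
        per_column_depth=per_column_depth(aln),
        per_sequence_coverage=per_sequence_coverage(aln),
    )
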