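"""Pairwise protein alignment and homolog retention filtering.

Candidate homologs of a query protein (e.g. the plasmid CopA variants) are
retained when they are more than 45% similar at the amino-acid level and
between 40% and 150% of the query length.  Similarity is the fraction of
alignment columns (gap columns included) whose residue pair has a positive
substitution-matrix score, computed on an optimal global alignment with
affine gap penalties (BLOSUM62; a gap of length k costs open + k*extend,
default 11 + k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class PairwiseAlignment:
    query_id: str
    subject_id: str
    columns: list[tuple[str, str]]  # (query char, subject char), '-' for gaps
    score: float
    similarity: float
    length_ratio: float  # subject length / query length

    def __post_init__(self) -> None:
        if any(q == "-" and s == "-" for q, s in self.columns):
            raise ValueError("alignment contains a gap-on-both-sides column")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must lie in [0, 1]")


def _make_aligner(substitution_matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrix
    # our convention: gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    substitution_matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Affine gaps: a gap of length k costs ``gap_open + k * gap_extend``
    (BLAST-style; defaults BLOSUM62, 11, 1).  The first optimal traceback
    reported by the aligner is used, which is deterministic for fixed
    inputs.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matrix = substitution_matrix if substitution_matrix is not None else _BLOSUM62
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    qrow, srow = str(alignment[0]), str(alignment[1])
    columns = list(zip(qrow, srow))
    sim = _similarity_from_columns(columns, matrix)
    return PairwiseAlignment(
        query_id=query_id,
        subject_id=subject_id,
        columns=columns,
        score=float(alignment.score),
        similarity=sim,
        length_ratio=len(b) / len(a),
    )


def _similarity_from_columns(columns, matrix) -> float:
    positive = 0
    for q, s in columns:
        if q != "-" and s != "-" and matrix[q, s] > 0:
            positive += 1
    return positive / len(columns)


def percent_similarity(alignment: PairwiseAlignment, substitution_matrix=None) -> float:
    """Fraction of columns with a positive-scoring residue pair (gaps count
    in the denominator)."""
    matrix = substitution_matrix if substitution_matrix is not None else _BLOSUM62
    return _similarity_from_columns(alignment.columns, matrix)


def filter_homologs(
    query: tuple[str, str],
    candidates: Sequence[tuple[str, str]],
    min_similarity: float = 0.45,
    min_length_ratio: float = 0.40,
    max_length_ratio: float = 1.50,
    **align_kwargs,
) -> list[PairwiseAlignment]:
    """Retain candidates >45% similar and 40-150% of the query length.

    The similarity bound is strict (similarity must exceed it); the length
    bounds are inclusive.  ``query`` and each candidate are ``(id, sequence)``
    pairs; each retained record carries its similarity and length ratio.
    """
    query_id, query_seq = query
    if not query_seq:
        raise ValueError("query sequence must be non-empty")
    retained = []
    for cand_id, cand_seq in candidates:
        ratio = len(cand_seq) / len(query_seq)
        if not (min_length_ratio <= ratio <= max_length_ratio):
            continue
        aln = global_align(query_seq, cand_seq, query_id=query_id, subject_id=cand_id, **align_kwargs)
        if aln.similarity > min_similarity:
            retained.append(aln)
    return retained
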