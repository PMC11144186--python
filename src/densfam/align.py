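"""Desk-scale local pairwise alignment with affine gaps.

A Gotoh-style Smith–Waterman kernel (numba-compiled) provides the
all-versus-all alignment table that the clustering stages consume, standing
in for an external aligner on synthetic data. Multiple high-scoring pairs
per sequence pair are found by iterated masking: after an alignment is
reported, its query rows and subject columns are excluded and the matrix is
rescanned.

Gap convention: a gap of length k costs ``gap_open + k * gap_extend``.
"""
from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .model import AlignmentHit, ProteinSet, Region

_NEG = np.int64(-(10**9))

# Karlin-Altschul-style constants for crude bit scores / E-values on the
# default scoring; only used for reporting, never for clustering decisions.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties (positive costs)."""

    alphabet: str
    matrix: np.ndarray  # int64, len(alphabet) x len(alphabet)
    gap_open: int = 11
    gap_extend: int = 1

    def encode(self, seq: str) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.alphabet)}
        x = idx.get("X", 0)
        return np.array([idx.get(c, x) for c in seq.upper()], dtype=np.int64)


def blosum62_scoring(gap_open: int = 11, gap_extend: int = 1) -> Scoring:
    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    return Scoring(alphabet, np.asarray(m, dtype=np.int64), gap_open, gap_extend)


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    a_start: int  # 1-based inclusive; 0 when score == 0 (empty alignment)
    a_end: int
    b_start: int
    b_end: int
    matches: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    length: int = 0

    @property
    def is_empty(self) -> bool:
        return self.score == 0

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.length if self.length else 0.0


@njit(cache=True)
def _gotoh_fill(a, b, sub, open_cost, ext_cost, row_mask, col_mask):  # pragma: no cover
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    best = np.int64(0)
    bi = 0
    bj = 0
    first_gap = open_cost + ext_cost
    for i in range(1, n + 1):
        ri = row_mask[i - 1]
        for j in range(1, m + 1):
            if ri or col_mask[j - 1]:
                H[i, j] = 0
                E[i, j] = _NEG
                F[i, j] = _NEG
                continue
            e = H[i - 1, j] - first_gap
            if E[i - 1, j] - ext_cost > e:
                e = E[i - 1, j] - ext_cost
            E[i, j] = e
            f = H[i, j - 1] - first_gap
            if F[i, j - 1] - ext_cost > f:
                f = F[i, j - 1] - ext_cost
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(H, E, F, a, b, sub, open_cost, ext_cost, bi, bj) -> LocalAlignment:
    first_gap = open_cost + ext_cost
    i, j = bi, bj
    state = "H"
    matches = mismatches = gap_opens = length = 0
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = sub[a[i - 1], b[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + s:
                length += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # defensive; recurrences make this unreachable
                break
        elif state == "E":
            length += 1
            if E[i, j] == H[i - 1, j] - first_gap:
                gap_opens += 1
                state = "H"
            i -= 1
        else:  # "F"
            length += 1
            if F[i, j] == H[i, j - 1] - first_gap:
                gap_opens += 1
                state = "H"
            j -= 1
    return LocalAlignment(
        score=int(H[bi, bj]),
        a_start=i + 1,
        a_end=bi,
        b_start=j + 1,
        b_end=bj,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        length=length,
    )


def smith_waterman(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    row_mask: np.ndarray | None = None,
    col_mask: np.ndarray | None = None,
) -> LocalAlignment:
    """Optimal local alignment of two sequences.

    Returns an empty alignment (score 0, no regions) when nothing scores
    positively.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or blosum62_scoring()
    ca, cb = scoring.encode(a), scoring.encode(b)
    if row_mask is None:
        row_mask = np.zeros(len(ca), dtype=np.bool_)
    if col_mask is None:
        col_mask = np.zeros(len(cb), dtype=np.bool_)
    H, E, F, best, bi, bj = _gotoh_fill(
        ca, cb, scoring.matrix,
        np.int64(scoring.gap_open), np.int64(scoring.gap_extend),
        row_mask, col_mask,
    )
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, 0)
    return _traceback(
        H, E, F, ca, cb, scoring.matrix, scoring.gap_open, scoring.gap_extend, bi, bj
    )


def _evalue_and_bits(score: int, m: int, n: int) -> tuple[float, float]:
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
    evalue = m * n * 2.0 ** (-bits)
    return evalue, bits


def align_pair_hsps(
    query_id: str,
    query_seq: str,
    subject_id: str,
    subject_seq: str,
    scoring: Scoring,
    score_min: float,
    max_hsps: int = 5,
) -> list[AlignmentHit]:
    """Up to ``max_hsps`` non-overlapping local alignments for one pair.

    After each reported alignment its query rows and subject columns are
    masked, so successive alignments come from different sequence stretches.
    """
    ca, cb = scoring.encode(query_seq), scoring.encode(subject_seq)
    row_mask = np.zeros(len(ca), dtype=np.bool_)
    col_mask = np.zeros(len(cb), dtype=np.bool_)
    hits: list[AlignmentHit] = []
    for _ in range(max_hsps):
        H, E, F, best, bi, bj = _gotoh_fill(
            ca, cb, scoring.matrix,
            np.int64(scoring.gap_open), np.int64(scoring.gap_extend),
            row_mask, col_mask,
        )
        if best < score_min or best <= 0:
            break
        aln = _traceback(
            H, E, F, ca, cb, scoring.matrix, scoring.gap_open, scoring.gap_extend, bi, bj
        )
        evalue, bits = _evalue_and_bits(aln.score, len(ca), len(cb))
        hits.append(
            AlignmentHit(
                query_id,
                subject_id,
                Region(query_id, aln.a_start, aln.a_end),
                Region(subject_id, aln.b_start, aln.b_end),
                aln.percent_identity,
                evalue,
                bits,
            )
        )
        row_mask[aln.a_start - 1 : aln.a_end] = True
        col_mask[aln.b_start - 1 : aln.b_end] = True
    return hits


def all_vs_all(
    proteins: ProteinSet,
    scoring: Scoring | None = None,
    score_min: float = 60.0,
    max_hsps: int = 5,
    query_ids: Iterable[str] | None = None,
) -> list[AlignmentHit]:
    """Directional all-versus-all alignment over every ordered pair.

    Self pairs are skipped. ``query_ids`` restricts the query side (the
    subject side always spans the full set).
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    scoring = scoring or blosum62_scoring()
    queries = sorted(query_ids) if query_ids is not None else sorted(proteins)
    subjects = sorted(proteins)
    hits: list[AlignmentHit] = []
    for qid in queries:
        qseq = proteins[qid]
        for sid in subjects:
            if sid == qid:
                continue
            hits.extend(
                align_pair_hsps(
                    qid, qseq, sid, proteins[sid], scoring, score_min, max_hsps
                )
            )
    return hits
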