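"""Pairwise and multiple protein alignment.

Local alignment is exact Smith–Waterman with affine gaps under a named
substitution matrix (default BLOSUM62, gap open 11 / extend 1 — a gap of
length k costs ``gap_open + k * gap_extend``).  Expectation values follow the
Karlin–Altschul formula ``E = kappa * m * n * exp(-lambda * S)`` with gapped
constants lambda=0.267, kappa=0.041.  Exact alignment is a conservative
stand-in for heuristic database search: it never misses the optimal local
alignment, so identity/E-value gates behave at least as permissively.

The multiple aligner is a plain guide-tree progressive method: UPGMA on
pairwise-identity distances, profiles merged by semi-global (end-gaps free)
affine dynamic programming on expected column scores.  No iterative
refinement — downstream motif discovery operates within low-divergence
subfamilies where progressive alignment is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import exp

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .family_model import AMINO_ACIDS, ProteinRecord

_NEG = -1e30


@dataclass
class AlignmentParams:
    """Scoring parameters for local alignment and E-value statistics."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    kappa: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    @property
    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix)


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    target_id: str
    raw_score: int
    evalue: float
    identity: float
    #: ((query_start, query_end), (target_start, target_end)), 1-based
    #: inclusive; ((0, 0), (0, 0)) for an empty alignment.
    aligned_span: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.raw_score < 0 or self.evalue < 0:
            raise ValueError("raw_score and evalue must be >= 0")


@dataclass
class MultipleAlignment:
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) > 1:
            raise ValueError("gapped rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def degapped(self, row: int) -> str:
        return self.rows[row][1].replace("-", "")

    def column(self, j: int) -> str:
        return "".join(seq[j] for _, seq in self.rows)


@lru_cache(maxsize=8)
def _cached_aligner(
    matrix_name: str, gap_open: int, gap_extend: int, mode: str
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython charges open_gap_score at the first gapped position; the
    # open + k*extend convention therefore maps to open+extend / extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = mode
    return aligner


def _make_aligner(params: AlignmentParams, mode: str = "local") -> Align.PairwiseAligner:
    return _cached_aligner(
        params.substitution_matrix, params.gap_open, params.gap_extend, mode
    )


def local_score(
    a: ProteinRecord, b: ProteinRecord, params: AlignmentParams | None = None
) -> int:
    """Optimal local alignment score only (no traceback); cheaper than
    :func:`align_local` when identity and span are not needed."""
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    return max(0, int(round(aligner.score(a.sequence, b.sequence))))


def align_local(
    a: ProteinRecord, b: ProteinRecord, params: AlignmentParams | None = None
) -> PairwiseHit:
    """Optimal Smith–Waterman local alignment of two proteins.

    Identity is matches / aligned columns, gap columns counted in the
    denominator.  A pair with no positive-scoring alignment yields a hit of
    score 0 with an empty span.
    """
    params = params or AlignmentParams()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params)
    score = aligner.score(a.sequence, b.sequence)
    if score <= 0:
        ev0 = evalue(0, len(a.sequence), len(b.sequence), params)
        return PairwiseHit(a.id, b.id, 0, ev0, 0.0, ((0, 0), (0, 0)))
    aln = aligner.align(a.sequence, b.sequence)[0]
    qg, tg = str(aln[0]), str(aln[1])
    # restrict to the locally aligned region (local alignments from Biopython
    # are already trimmed to the aligned blocks)
    ncols = len(qg)
    matches = sum(1 for x, y in zip(qg, tg) if x == y and x != "-")
    identity = matches / ncols if ncols else 0.0
    blocks_q, blocks_t = aln.aligned
    span = (
        (int(blocks_q[0][0]) + 1, int(blocks_q[-1][1])),
        (int(blocks_t[0][0]) + 1, int(blocks_t[-1][1])),
    )
    raw = int(round(score))
    ev = evalue(raw, len(a.sequence), len(b.sequence), params)
    return PairwiseHit(a.id, b.id, raw, ev, identity, span)


def evalue(
    score: int, query_len: int, db_residues: int, params: AlignmentParams | None = None
) -> float:
    """Karlin–Altschul expectation E = kappa * m * n * exp(-lambda * S)."""
    params = params or AlignmentParams()
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    return params.kappa * query_len * db_residues * exp(-params.lam * score)


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

_ALPHA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}


def _score_table(params: AlignmentParams) -> np.ndarray:
    mat = params.matrix
    n = len(AMINO_ACIDS)
    table = np.zeros((n, n))
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            table[i, j] = mat[x, y]
    return table


def _profile(rows: list[str]) -> np.ndarray:
    """Column residue-frequency profile (gaps carry zero weight)."""
    n = len(AMINO_ACIDS)
    length = len(rows[0])
    prof = np.zeros((length, n))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                prof[j, _ALPHA_INDEX[c]] += 1.0
    prof /= len(rows)
    return prof


def _profile_align(
    rows_a: list[str], rows_b: list[str], params: AlignmentParams
) -> tuple[list[str], list[str]]:
    """Semi-global affine alignment of two gapped-row groups.

    End gaps are free; internal gaps cost open + k*extend per the pairwise
    convention.  Returns both groups re-gapped to a common length.
    """
    table = _score_table(params)
    pa, pb = _profile(rows_a), _profile(rows_b)
    m, n = len(pa), len(pb)
    S = pa @ table @ pb.T  # expected column-pair score
    go = float(params.gap_open + params.gap_extend)
    ge = float(params.gap_extend)

    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # gap in b (consumes a)
    Iy = np.full((m + 1, n + 1), _NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    Ix[1:, 0] = 0.0  # free leading end gaps
    Iy[0, 1:] = 0.0
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1, :] + prev_best[:-1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge)
        Ix[i, 0] = 0.0
        # Iy has a within-row dependency; plain-float loop keeps it fast
        row_m = M[i].tolist()
        row_iy = Iy[i].tolist()
        prev = row_iy[0]
        for j in range(1, n + 1):
            prev = max(row_m[j - 1] - go, prev - ge)
            row_iy[j] = prev
        Iy[i] = row_iy
    # free trailing gaps: best over the last row and last column
    best, bi, bj, state = _NEG, m, n, "M"
    for st, mat in (("M", M), ("X", Ix), ("Y", Iy)):
        j = int(np.argmax(mat[m, :]))
        if mat[m, j] > best:
            best, bi, bj, state = mat[m, j], m, j, st
        i = int(np.argmax(mat[:, n]))
        if mat[i, n] > best:
            best, bi, bj, state = mat[i, n], i, n, st

    # traceback from (bi, bj); pad the tail as free end gaps
    ops: list[str] = []
    ops.extend("Y" * (n - bj))
    ops.extend("X" * (m - bi))
    i, j = bi, bj
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                state = "X" if i > 0 else "Y"
                continue
            ops.append("M")
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if prev == M[i - 1, j - 1]:
                state = "M"
            elif prev == Ix[i - 1, j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            if j == 0:  # free leading gap region
                ops.extend("X" * i)
                break
            ops.append("X")
            state = "M" if Ix[i, j] == M[i - 1, j] - go else "X"
            i -= 1
        else:
            if i == 0:
                ops.extend("Y" * j)
                break
            ops.append("Y")
            state = "M" if Iy[i, j] == M[i, j - 1] - go else "Y"
            j -= 1
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == "M":
            for k, row in enumerate(rows_a):
                out_a[k] += row[i]
            for k, row in enumerate(rows_b):
                out_b[k] += row[j]
            i += 1
            j += 1
        elif op == "X":
            for k, row in enumerate(rows_a):
                out_a[k] += row[i]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, row in enumerate(rows_b):
                out_b[k] += row[j]
            j += 1
    return out_a, out_b


def progressive_msa(
    records: list[ProteinRecord], params: AlignmentParams | None = None
) -> MultipleAlignment:
    """Guide-tree progressive multiple alignment.

    The guide tree is UPGMA on (1 - pairwise local identity); groups are
    merged in tree order by profile dynamic programming.
    """
    params = params or AlignmentParams()
    if len(records) < 2:
        raise ValueError("progressive_msa needs at least 2 records")
    n = len(records)
    if n == 2:
        a, b = _profile_align([records[0].sequence], [records[1].sequence], params)
        return MultipleAlignment(
            rows=[(records[0].id, a[0]), (records[1].id, b[0])]
        )
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            hit = align_local(records[i], records[j], params)
            dist[i, j] = dist[j, i] = 1.0 - hit.identity
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].sequence]) for i in range(n)
    }
    for k, (a_idx, b_idx, _, _) in enumerate(Z):
        ia, ib = clusters.pop(int(a_idx)), clusters.pop(int(b_idx))
        rows_a, rows_b = _profile_align(ia[1], ib[1], params)
        clusters[n + k] = (ia[0] + ib[0], rows_a + rows_b)
    order, rows = clusters.popitem()[1]
    aligned = {idx: row for idx, row in zip(order, rows)}
    return MultipleAlignment(
        rows=[(records[i].id, aligned[i]) for i in range(n)]
    )


def write_hits_tsv(hits: list[PairwiseHit], path) -> None:
    """Tab-separated hit table (query, target, identity %, E-value, score)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            (qs, qe), (ts, te) = h.aligned_span
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{100.0 * h.identity:.2f}\t"
                f"{qs}\t{qe}\t{ts}\t{te}\t{h.evalue:.3g}\t{h.raw_score}\n"
            )
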