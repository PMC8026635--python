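"""Pairwise sequence alignment with affine gaps and Karlin-Altschul statistics.

Exact Needleman-Wunsch (global) and Smith-Waterman (local) alignment backed by
:class:`Bio.Align.PairwiseAligner`, plus a banded global aligner for
genome-scale nucleotide comparisons where a dense DP matrix would not fit in
memory.  Raw scores are converted to bit scores and E-values with gapped
Karlin-Altschul parameters, which is what the downstream homology thresholds
(E-value, query coverage) are expressed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

LN2 = math.log(2.0)

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_ALPHABET = "ACGTN"


def _nucleotide_matrix(match: int, mismatch: int) -> substitution_matrices.Array:
    mat = substitution_matrices.Array(NUCLEOTIDE_ALPHABET, dims=2)
    for a in NUCLEOTIDE_ALPHABET:
        for b in NUCLEOTIDE_ALPHABET:
            mat[a, b] = match if (a == b and a != "N") else mismatch
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul parameters.

    ``gap_open`` is the score of the *first* gap column; a gap of length g
    scores ``gap_open + (g - 1) * gap_extend``.
    """

    matrix: substitution_matrices.Array
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    @property
    def alphabet(self) -> str:
        return str(self.matrix.alphabet)

    def check_sequence(self, seq: str) -> None:
        if not seq:
            raise ValueError("empty sequence")
        alphabet = set(self.alphabet)
        for ch in seq:
            if ch not in alphabet:
                raise ValueError(f"symbol {ch!r} absent from substitution matrix")


def protein_scheme(gap_open: int = -11, gap_extend: int = -1) -> ScoringScheme:
    """Default protein scheme: BLOSUM62, -11/-1 gaps, gapped KA statistics."""
    mat = substitution_matrices.load("BLOSUM62")
    return ScoringScheme(matrix=mat, gap_open=gap_open, gap_extend=gap_extend,
                         lambda_=0.267, K=0.041)


def nucleotide_scheme(match: int = 1, mismatch: int = -2,
                      gap_open: int = -5, gap_extend: int = -2) -> ScoringScheme:
    # lambda/K for gapped +1/-2 scoring (BLAST defaults for this scheme)
    return ScoringScheme(matrix=_nucleotide_matrix(match, mismatch),
                         gap_open=gap_open, gap_extend=gap_extend,
                         lambda_=1.28, K=0.46)


def infer_scheme(seq: str) -> ScoringScheme:
    """Pick the nucleotide scheme if the sequence looks like DNA."""
    if set(seq.upper()) <= set(NUCLEOTIDE_ALPHABET):
        return nucleotide_scheme()
    return protein_scheme()


@dataclass
class PairwiseAlignment:
    """One pairwise alignment with identity/coverage and KA statistics.

    ``identity`` is identical columns over all alignment columns including
    gap columns; coverages are the aligned span over the full sequence
    length, computed separately for query and target.
    """

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    query_coverage: float
    target_coverage: float
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    return (scheme.lambda_ * raw_score - math.log(scheme.K)) / LN2


def evalue(bits: float, m: int, n: int) -> float:
    try:
        return m * n * math.pow(2.0, -bits)
    except OverflowError:
        return math.inf


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _empty_alignment(a: str, b: str, scheme: ScoringScheme,
                     query_id: str, target_id: str) -> PairwiseAlignment:
    bits = bit_score(0, scheme)
    return PairwiseAlignment(query_id, target_id, 0, bits,
                             evalue(bits, len(a), len(b)),
                             0.0, 0.0, 0.0, [])


def _stats_from_blocks(a: str, b: str, blocks_q, blocks_t, raw: int,
                       mode: str, scheme: ScoringScheme,
                       query_id: str, target_id: str) -> PairwiseAlignment:
    aligned_pairs: list[tuple[int, int]] = []
    ident = 0
    cols = 0
    prev_qe: Optional[int] = None
    prev_te: Optional[int] = None
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if prev_qe is not None:
            cols += (qs - prev_qe) + (ts - prev_te)
        for off in range(qe - qs):
            qi, ti = qs + off, ts + off
            aligned_pairs.append((qi, ti))
            if a[qi] == b[ti]:
                ident += 1
        cols += qe - qs
        prev_qe, prev_te = qe, te
    if not aligned_pairs:
        return _empty_alignment(a, b, scheme, query_id, target_id)
    q_first, t_first = blocks_q[0][0], blocks_t[0][0]
    q_last, t_last = blocks_q[-1][1], blocks_t[-1][1]
    if mode == "global":
        # end gaps are alignment columns too
        cols += q_first + t_first + (len(a) - q_last) + (len(b) - t_last)
    q_span = q_last - q_first
    t_span = t_last - t_first
    bits = bit_score(raw, scheme)
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        raw_score=raw,
        bit_score=bits,
        evalue=evalue(bits, len(a), len(b)),
        identity=ident / cols if cols else 0.0,
        query_coverage=q_span / len(a),
        target_coverage=t_span / len(b),
        aligned_pairs=aligned_pairs,
    )


def _align(a: str, b: str, scheme: ScoringScheme, mode: str,
           query_id: str, target_id: str) -> PairwiseAlignment:
    scheme.check_sequence(a)
    scheme.check_sequence(b)
    aligner = _make_aligner(scheme, mode)
    score = aligner.score(a, b)
    if mode == "local" and score <= 0:
        return _empty_alignment(a, b, scheme, query_id, target_id)
    aln = next(iter(aligner.align(a, b)))
    blocks_q, blocks_t = aln.aligned
    return _stats_from_blocks(a, b, blocks_q, blocks_t, int(round(score)),
                              mode, scheme, query_id, target_id)


def align_global(a: str, b: str, scheme: Optional[ScoringScheme] = None,
                 query_id: str = "query", target_id: str = "target") -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment with affine gaps."""
    scheme = scheme or infer_scheme(a + b)
    return _align(a, b, scheme, "global", query_id, target_id)


def align_local(a: str, b: str, scheme: Optional[ScoringScheme] = None,
                query_id: str = "query", target_id: str = "target") -> PairwiseAlignment:
    """Optimal local (Smith-Waterman) alignment with affine gaps.

    If no alignment scores above zero the empty alignment (raw score 0) is
    returned.
    """
    scheme = scheme or infer_scheme(a + b)
    return _align(a, b, scheme, "local", query_id, target_id)


# ---------------------------------------------------------------------------
# Banded global alignment for genome-scale sequences.
# ---------------------------------------------------------------------------

_NEG = -1.0e18


def align_global_banded(a: str, b: str, scheme: Optional[ScoringScheme] = None,
                        band: Optional[int] = None,
                        query_id: str = "query",
                        target_id: str = "target") -> PairwiseAlignment:
    """Global affine-gap alignment restricted to a diagonal band.

    Exact whenever the optimal path stays within ``band`` offsets of the
    straight line between the matrix corners — in particular for
    near-identical sequences whose divergence is dominated by substitutions,
    which is the genome-deduplication use case.  Memory is O(len(a) * band).
    """
    scheme = scheme or infer_scheme(a + b)
    scheme.check_sequence(a)
    scheme.check_sequence(b)
    m, n = len(a), len(b)
    if band is None:
        band = 2 * abs(m - n) + 32
    W = band
    width = 2 * W + 1

    alpha = scheme.alphabet
    code = {c: i for i, c in enumerate(alpha)}
    S = np.asarray(scheme.matrix, dtype=np.float64)
    ac = np.fromiter((code[c] for c in a), dtype=np.int64, count=m)
    bc = np.fromiter((code[c] for c in b), dtype=np.int64, count=n)

    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    karr = np.arange(-W, W + 1)

    def center(i: int) -> int:
        return round(i * n / m) if m else 0

    # per-row state
    H = np.full(width, _NEG)
    F = np.full(width, _NEG)
    # traceback stores: ptrH 0=G,1=E ; ptrG 0=diag,1=F ; ptrF 0=open,1=extend
    ptrH = np.zeros((m + 1, width), dtype=np.uint8)
    ptrG = np.zeros((m + 1, width), dtype=np.uint8)
    ptrF = np.zeros((m + 1, width), dtype=np.uint8)
    estart = np.zeros((m + 1, width), dtype=np.int32)  # band offset of gap start

    # row 0: j = k (center 0); H[0][j] = gap of length j
    j0 = karr.copy()
    valid0 = (j0 >= 0) & (j0 <= n)
    H[valid0] = np.where(j0[valid0] == 0, 0.0,
                         go + (j0[valid0] - 1) * ge)
    ptrH[0, :] = 1  # E (leading gap); traceback handles row 0 specially

    def shift(x: np.ndarray, s: int) -> np.ndarray:
        """y[k] = x[k + s] with out-of-band = -inf."""
        y = np.full(width, _NEG)
        if s >= 0:
            if s < width:
                y[: width - s] = x[s:]
        else:
            if -s < width:
                y[-s:] = x[:width + s]
        return y

    c_prev = 0
    for i in range(1, m + 1):
        c_i = center(i)
        d = c_i - c_prev
        jv = c_i + karr
        valid = (jv >= 0) & (jv <= n)

        H_up = shift(H, d)        # (i-1, j)
        H_diag = shift(H, d - 1)  # (i-1, j-1)
        F_up = shift(F, d)

        # F: gap in b, consume a[i-1]
        f_open = H_up + go
        f_ext = F_up + ge
        F_new = np.maximum(f_open, f_ext)
        ptrF[i] = (f_ext > f_open).astype(np.uint8)

        # diagonal candidate
        diag = np.full(width, _NEG)
        dmask = valid & (jv >= 1)
        diag[dmask] = H_diag[dmask] + S[ac[i - 1], bc[jv[dmask] - 1]]

        G = np.maximum(diag, F_new)
        ptrG[i] = (F_new > diag).astype(np.uint8)

        # E: gap in a within the row; E[k] = go + ge*(k-1) + max_{k'<k}(G[k'] - ge*k')
        base = G - ge * karr
        run = np.maximum.accumulate(base)
        argrun = np.maximum.accumulate(
            np.where(base >= run, np.arange(width), -1))
        E = np.full(width, _NEG)
        if width > 1:
            E[1:] = go + ge * (karr[1:] - 1) + run[:-1]
            estart[i, 1:] = argrun[:-1]
        # j must be >= 1 for E (a gap consumed at least one b residue)
        E[~valid | (jv < 1)] = _NEG

        H_new = np.maximum(G, E)
        ptrH[i] = (E > G).astype(np.uint8)
        H_new[~valid] = _NEG
        F_new[~valid] = _NEG

        H, F = H_new, F_new
        c_prev = c_i

    k_final = n - center(m)
    if abs(k_final) > W:  # pragma: no cover - band always contains the corner
        raise ValueError("band does not reach the alignment end")
    raw = H[k_final + W]
    if raw <= _NEG / 2:
        raise ValueError("no alignment within band; increase band width")

    # traceback
    ident = 0
    cols = 0
    aligned_pairs: list[tuple[int, int]] = []
    q_first = q_last = t_first = t_last = None
    i, k = m, k_final
    state = "H"
    while True:
        j = center(i) + k
        if i == 0:
            cols += j  # leading gap in a
            break
        if j == 0:
            cols += i  # leading gap in b
            break
        if state == "H":
            state = "E" if ptrH[i, k + W] else "G"
            continue
        if state == "G":
            if ptrG[i, k + W]:
                state = "F"
                continue
            # diagonal
            aligned_pairs.append((i - 1, j - 1))
            if a[i - 1] == b[j - 1]:
                ident += 1
            cols += 1
            if q_last is None:
                q_last, t_last = i, j
            q_first, t_first = i - 1, j - 1
            d = center(i) - center(i - 1)
            i -= 1
            k = k + d - 1
            state = "H"
            continue
        if state == "F":
            via_ext = ptrF[i, k + W]
            cols += 1
            d = center(i) - center(i - 1)
            i -= 1
            k = k + d
            state = "F" if via_ext else "H"
            continue
        if state == "E":
            k_src = int(estart[i, k + W]) - W  # stored as array index
            cols += (k - k_src)
            k = k_src
            state = "G"
            continue

    aligned_pairs.reverse()
    bits = bit_score(raw, scheme)
    if q_first is None:
        return _empty_alignment(a, b, scheme, query_id, target_id)
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        raw_score=int(round(raw)),
        bit_score=bits,
        evalue=evalue(bits, m, n),
        identity=ident / cols if cols else 0.0,
        query_coverage=(q_last - q_first) / m,
        target_coverage=(t_last - t_first) / n,
        aligned_pairs=aligned_pairs,
    )
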