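"""Global and local alignment of a DNA sequence against a dinucleotide PWM.

The alignment is between the sequence's dinucleotide positions t = 2..len
(each encoding the ordered pair of bases t-1, t) and the PWM's informative
columns (alignment columns 2..L1). Aligning position t to column l scores
``pwm(s(t), l)`` where s(t) is computed from the *actual* sequence bases, so
the score of a position is unaffected by gaps placed around it. Gaps are
linear with penalty ``d_seq`` per gapped position; positions whose
dinucleotide is undefined (an N base) score 0.

Global alignment spans both the whole sequence and the whole matrix and its
terminal score F_max is the class-membership statistic; local alignment is
Smith-Waterman-style with a floor at zero and yields E_max, the genome-scan
statistic, plus the matched intervals in sequence and matrix coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .pwm_core import PWM, dinucleotide_codes

DEFAULT_GAP = 20.0

# trace codes
_M, _I, _D = 0, 1, 2  # match, insertion in sequence, deletion (matrix column skipped)


@dataclass
class GapParams:
    """Linear gap model: ``d_seq`` is charged per gapped position."""

    d_seq: float = DEFAULT_GAP

    def __post_init__(self) -> None:
        if self.d_seq < 0:
            raise ValueError("gap penalty must be >= 0")


@dataclass
class AlignmentResult:
    """Score plus the aligned intervals and trace.

    ``seq_interval`` is 1-based inclusive over sequence *positions* (the
    dinucleotide ending at base t has position t, so the first alignable
    position is 2); ``pwm_interval`` is over matrix columns 2..L1. ``cigar``
    is a run-length M/I/D string (I consumes sequence, D consumes columns).
    Empty local alignments have score 0 and empty intervals.
    """

    score: float
    seq_interval: tuple[int, int] | None
    pwm_interval: tuple[int, int] | None
    cigar: str


def _codes(seq: str | np.ndarray) -> np.ndarray:
    codes = dinucleotide_codes(seq) if isinstance(seq, str) else np.asarray(seq, np.int8)
    if codes.shape[0] < 1:
        raise ValueError("sequence shorter than 2 bases cannot be aligned")
    return codes


@njit(cache=True)
def global_score(codes, weights, gap):  # pragma: no cover - exercised via wrapper
    n = codes.shape[0]
    m = weights.shape[1]
    prev = np.empty(m + 1, np.float64)
    cur = np.empty(m + 1, np.float64)
    for j in range(m + 1):
        prev[j] = -gap * j
    for i in range(1, n + 1):
        cur[0] = -gap * i
        ci = codes[i - 1]
        for j in range(1, m + 1):
            w = weights[ci, j - 1] if ci >= 0 else 0.0
            best = prev[j - 1] + w
            up = prev[j] - gap
            if up > best:
                best = up
            left = cur[j - 1] - gap
            if left > best:
                best = left
            cur[j] = best
        for j in range(m + 1):
            prev[j] = cur[j]
    return prev[m]


@njit(cache=True)
def _global_fill(codes, weights, gap, h):  # pragma: no cover
    n = codes.shape[0]
    m = weights.shape[1]
    for j in range(m + 1):
        h[0, j] = -gap * j
    for i in range(1, n + 1):
        h[i, 0] = -gap * i
        ci = codes[i - 1]
        for j in range(1, m + 1):
            w = weights[ci, j - 1] if ci >= 0 else 0.0
            best = h[i - 1, j - 1] + w
            up = h[i - 1, j] - gap
            if up > best:
                best = up
            left = h[i, j - 1] - gap
            if left > best:
                best = left
            h[i, j] = best
    return h[n, m]


@njit(cache=True)
def global_matches(codes, weights, gap, t_out, l_out):  # pragma: no cover
    """Fill + traceback; writes matched (position, column) pairs, returns
    (score, n_matches). t_out/l_out must have length >= min(n, m)."""
    n = codes.shape[0]
    m = weights.shape[1]
    h = np.empty((n + 1, m + 1), np.float64)
    score = _global_fill(codes, weights, gap, h)
    i, j = n, m
    k = 0
    while i > 0 and j > 0:
        ci = codes[i - 1]
        w = weights[ci, j - 1] if ci >= 0 else 0.0
        v = h[i, j]
        if v == h[i - 1, j - 1] + w:
            t_out[k] = i
            l_out[k] = j
            k += 1
            i -= 1
            j -= 1
        elif v == h[i - 1, j] - gap:
            i -= 1
        else:
            j -= 1
    # reverse in place to ascending order
    for a in range(k // 2):
        t_out[a], t_out[k - 1 - a] = t_out[k - 1 - a], t_out[a]
        l_out[a], l_out[k - 1 - a] = l_out[k - 1 - a], l_out[a]
    return score, k


@njit(cache=True)
def local_best(codes, weights, gap):  # pragma: no cover
    """Best local score and its endpoints without a full traceback.

    Returns (E, i0, imax, l0, lmax) with 1-based indices over sequence
    positions / matrix columns of this DP (0s when E == 0). Start
    coordinates are propagated through the recurrence.
    """
    n = codes.shape[0]
    m = weights.shape[1]
    prev = np.zeros(m + 1, np.float64)
    cur = np.zeros(m + 1, np.float64)
    psi = np.zeros(m + 1, np.int64)
    psj = np.zeros(m + 1, np.int64)
    csi = np.zeros(m + 1, np.int64)
    csj = np.zeros(m + 1, np.int64)
    best = 0.0
    bi = bj = bsi = bsj = 0
    for i in range(1, n + 1):
        ci = codes[i - 1]
        cur[0] = 0.0
        csi[0] = 0
        csj[0] = 0
        for j in range(1, m + 1):
            w = weights[ci, j - 1] if ci >= 0 else 0.0
            diag = prev[j - 1] + w
            up = prev[j] - gap
            left = cur[j - 1] - gap
            v = diag
            si = psi[j - 1] if prev[j - 1] > 0.0 else i
            sj = psj[j - 1] if prev[j - 1] > 0.0 else j
            if up > v:
                v = up
                si = psi[j]
                sj = psj[j]
            if left > v:
                v = left
                si = csi[j - 1]
                sj = csj[j - 1]
            if v <= 0.0:
                v = 0.0
                si = 0
                sj = 0
            cur[j] = v
            csi[j] = si
            csj[j] = sj
            if v > best:
                best = v
                bi = i
                bj = j
                bsi = si
                bsj = sj
        for j in range(m + 1):
            prev[j] = cur[j]
            psi[j] = csi[j]
            psj[j] = csj[j]
    return best, bsi, bi, bsj, bj


@njit(cache=True)
def _local_fill(codes, weights, gap, h):  # pragma: no cover
    n = codes.shape[0]
    m = weights.shape[1]
    best = 0.0
    bi = bj = 0
    for j in range(m + 1):
        h[0, j] = 0.0
    for i in range(1, n + 1):
        h[i, 0] = 0.0
        ci = codes[i - 1]
        for j in range(1, m + 1):
            w = weights[ci, j - 1] if ci >= 0 else 0.0
            v = h[i - 1, j - 1] + w
            up = h[i - 1, j] - gap
            if up > v:
                v = up
            left = h[i, j - 1] - gap
            if left > v:
                v = left
            if v < 0.0:
                v = 0.0
            h[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj


def _cigar(ops: list[int]) -> str:
    if not ops:
        return "."
    out = []
    run_op, run_len = ops[0], 1
    for op in ops[1:]:
        if op == run_op:
            run_len += 1
        else:
            out.append(f"{run_len}{'MID'[run_op]}")
            run_op, run_len = op, 1
    out.append(f"{run_len}{'MID'[run_op]}")
    return "".join(out)


def global_align(
    seq: str | np.ndarray, pwm: PWM, gaps: GapParams | float = DEFAULT_GAP
) -> AlignmentResult:
    """Full-length alignment of a sequence against all matrix columns.

    The score F_max is the terminal DP cell, i.e. both the sequence and the
    matrix are consumed end to end (a 600-nt sequence has 599 dinucleotide
    positions aligned against the L1-1 informative columns).
    """
    gap = gaps.d_seq if isinstance(gaps, GapParams) else float(gaps)
    codes = _codes(seq)
    n, m = codes.shape[0], pwm.n_columns
    h = np.empty((n + 1, m + 1), np.float64)
    score = _global_fill(codes, pwm.weights, gap, h)
    ops: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            ci = codes[i - 1]
            w = pwm.weights[ci, j - 1] if ci >= 0 else 0.0
            if h[i, j] == h[i - 1, j - 1] + w:
                ops.append(_M)
                i -= 1
                j -= 1
                continue
        if i > 0 and h[i, j] == h[i - 1, j] - gap:
            ops.append(_I)
            i -= 1
        else:
            ops.append(_D)
            j -= 1
    ops.reverse()
    return AlignmentResult(
        score=float(score),
        seq_interval=(2, n + 1) if n else None,
        pwm_interval=(2, m + 1) if m else None,
        cigar=_cigar(ops),
    )


def local_align(
    window: str | np.ndarray, pwm: PWM, gaps: GapParams | float = DEFAULT_GAP
) -> AlignmentResult:
    """Best-scoring local segment of a window against the matrix (E_max >= 0).

    Intended for genome-scan windows of length L1 + 50 but accepts any
    length >= 2. Intervals are reported 1-based: sequence positions t in
    2..len(window) and matrix columns l in 2..L1.
    """
    gap = gaps.d_seq if isinstance(gaps, GapParams) else float(gaps)
    codes = _codes(window)
    n, m = codes.shape[0], pwm.n_columns
    h = np.empty((n + 1, m + 1), np.float64)
    best, bi, bj = _local_fill(codes, pwm.weights, gap, h)
    if best <= 0.0:
        return AlignmentResult(score=0.0, seq_interval=None, pwm_interval=None, cigar=".")
    ops: list[int] = []
    i, j = bi, bj
    while i > 0 and j > 0 and h[i, j] > 0.0:
        ci = codes[i - 1]
        w = pwm.weights[ci, j - 1] if ci >= 0 else 0.0
        if h[i, j] == h[i - 1, j - 1] + w:
            ops.append(_M)
            i -= 1
            j -= 1
        elif h[i, j] == h[i - 1, j] - gap:
            ops.append(_I)
            i -= 1
        else:
            ops.append(_D)
            j -= 1
    ops.reverse()
    # +1: dinucleotide position t corresponds to codes index t-1; +1 again for
    # the DP's first consumed cell being i0.
    return AlignmentResult(
        score=float(best),
        seq_interval=(i + 2, bi + 1),
        pwm_interval=(j + 2, bj + 1),
        cigar=_cigar(ops),
    )


def local_align_best(
    window: str | np.ndarray, pwm: PWM, gaps: GapParams | float = DEFAULT_GAP
) -> tuple[float, int, int, int, int]:
    """(E_max, i0, imax, l0, lmax) without trace; indices as in local_align."""
    gap = gaps.d_seq if isinstance(gaps, GapParams) else float(gaps)
    codes = _codes(window)
    e, si, bi, sj, bj = local_best(codes, pwm.weights, gap)
    if e <= 0.0:
        return 0.0, 0, 0, 0, 0
    return float(e), si + 1, bi + 1, sj + 1, bj + 1
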