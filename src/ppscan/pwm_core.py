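"""Dinucleotide position-weight matrices.

Promoter classes are modelled with 16-row position-weight matrices indexed by
ordered dinucleotides, which capture the correlation of adjacent DNA bases.
A multiple alignment of promoter sequences is first condensed into a frequency
matrix ``M(16, L1)`` whose column *j* counts the dinucleotide formed by
alignment columns *(j-1, j)*; the raw weight matrix standardizes each count
against a background dinucleotide distribution; a final linear transform fixes
two global statistics of the matrix (``K_d = 0`` and ``R^2 = 75 * L1``) so
that matrices from different classes are on a common scale.

Base codes are ``{A: 1, T: 2, C: 3, G: 4}`` and the dinucleotide index of the
pair (prev, cur) is ``s = v(prev) + 4 * (v(cur) - 1)`` in ``1..16``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Base order {A, T, C, G}; internal codes are 0-based, -1 marks N/unknown.
BASES = "ATCG"
BASE_CODE = {"A": 0, "T": 1, "C": 2, "G": 3}
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _c in BASE_CODE.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c

#: Dinucleotide labels in index order (s = 1..16): first base varies fastest.
DINUCLEOTIDES = [BASES[i % 4] + BASES[i // 4] for i in range(16)]

#: Degrees of freedom of the per-column chi-square in the conservation profile.
PROFILE_DF = 9


def base_codes(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} to 0-based codes (-1 for N)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_dinucleotides(seq: str) -> np.ndarray:
    """Dinucleotide indices ``s`` in 1..16 for positions 2..len(seq).

    Position *t* (1-based) encodes the ordered pair (base t-1, base t);
    entries where either base is N are 0 (missing).

    >>> list(encode_dinucleotides("AAGG"))
    [1, 13, 16]
    """
    s0 = dinucleotide_codes(seq)
    return np.where(s0 >= 0, s0 + 1, 0)


def dinucleotide_codes(seq: str | np.ndarray) -> np.ndarray:
    """0-based dinucleotide codes (0..15, -1 where undefined), length len-1."""
    v = base_codes(seq) if isinstance(seq, str) else seq
    if v.shape[0] < 2:
        return np.empty(0, dtype=np.int8)
    prev, cur = v[:-1], v[1:]
    s = prev + 4 * cur
    return np.where((prev < 0) | (cur < 0), -1, s).astype(np.int8)


def decode_dinucleotide(s: int) -> str:
    """Inverse of the 1-based dinucleotide index (2-letter string)."""
    if not 1 <= s <= 16:
        raise ValueError(f"dinucleotide index out of range: {s}")
    return DINUCLEOTIDES[s - 1]


@dataclass
class FrequencyMatrix:
    """Dinucleotide counts per alignment column.

    ``counts`` has shape (16, L1 - 1); column index 0 corresponds to alignment
    column 2 (the pair of columns 1 and 2), the last to column L1.
    """

    counts: np.ndarray
    l1: int
    n_seq: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (16, self.l1 - 1):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with L1={self.l1}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative dinucleotide counts")

    @property
    def n_columns(self) -> int:
        return self.l1 - 1


# Gap mark inside integer alignment arrays (base codes 0..3, N = -1).
GAP = -2


def build_frequency_matrix(alignment: np.ndarray | list[str]) -> FrequencyMatrix:
    """Count dinucleotides per column pair of a multiple alignment.

    ``alignment`` is either a list of equal-length gapped strings (gap "-")
    or an int array (n_seq, L1) of base codes with ``GAP``/-1 marks. A pair
    is counted at column j only when both columns j-1 and j hold real bases.
    """
    if isinstance(alignment, (list, tuple)):
        lengths = {len(s) for s in alignment}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: unequal row lengths")
        arr = np.full((len(alignment), lengths.pop() if lengths else 0), GAP, np.int8)
        for i, row in enumerate(alignment):
            codes = _CODE_LUT[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
            codes[np.frombuffer(row.encode("ascii"), dtype=np.uint8) == ord("-")] = GAP
            arr[i] = codes
    else:
        arr = np.asarray(alignment, dtype=np.int8)
        if arr.ndim != 2:
            raise ValueError("alignment must be 2-D")
    n_seq, l1 = arr.shape
    if l1 < 2:
        raise ValueError("alignment must have at least 2 columns")
    prev, cur = arr[:, :-1], arr[:, 1:]
    ok = (prev >= 0) & (cur >= 0)
    s = prev.astype(np.int32) + 4 * cur.astype(np.int32)
    counts = np.zeros((16, l1 - 1), dtype=np.float64)
    cols = np.broadcast_to(np.arange(l1 - 1), s.shape)
    np.add.at(counts, (s[ok], cols[ok]), 1.0)
    return FrequencyMatrix(counts=counts, l1=l1, n_seq=n_seq)


@dataclass
class PWM:
    """A 16 x (L1-1) weight matrix with its background and normalization record."""

    weights: np.ndarray
    background: np.ndarray  # p(i), 16 values
    l1: int
    normalization: dict = field(default_factory=dict)
    class_id: int | None = None
    empty_columns: np.ndarray | None = None  # columns with N(j) == 0, weight 0

    @property
    def n_columns(self) -> int:
        return self.weights.shape[1]


def compute_pwm(freq: FrequencyMatrix) -> PWM:
    """Raw standardized weight matrix from dinucleotide counts.

    Each cell is the count's deviation from its binomial expectation under the
    pooled background ``p(i) = Y(i)/K``, divided by the binomial standard
    deviation ``sqrt(N(j) p(i) (1 - p(i)))``. Columns with no counts get
    weight 0 and are flagged. If any dinucleotide never occurs, add-one
    smoothing is applied to the marginals Y(i) so every p(i) stays in (0, 1).
    """
    m = freq.counts
    n_j = m.sum(axis=0)
    y = m.sum(axis=1)
    k = y.sum()
    if k <= 0:
        raise ValueError("empty frequency matrix (K = 0)")
    if (y == 0).any():
        y = y + 1.0
    p = y / y.sum()
    empty = n_j == 0
    denom = np.sqrt(np.outer(p * (1.0 - p), np.where(empty, 1.0, n_j)))
    w = (m - np.outer(p, n_j)) / denom
    w[:, empty] = 0.0
    return PWM(
        weights=w,
        background=p,
        l1=freq.l1,
        empty_columns=np.flatnonzero(empty) if empty.any() else None,
    )


def pwm_r2(weights: np.ndarray) -> float:
    """Sum of squared weights over all cells (columns 2..L1)."""
    return float(np.sum(np.asarray(weights, dtype=np.float64) ** 2))


def pwm_kd(weights: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Doubly weighted mean of the matrix: sum_ik W(i,k) p1(i) p2(k)."""
    w = np.asarray(weights, dtype=np.float64)
    return float(p1 @ w @ p2)


def default_p1_p2(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Row/column probability vectors used in the K_d statistic.

    p1 is the background dinucleotide distribution of the matrix; p2 is
    uniform over the informative columns. Both sum to 1, which is what makes
    centering by K_d exact.
    """
    n_cols = pwm.n_columns
    return pwm.background, np.full(n_cols, 1.0 / n_cols)


def normalize_pwm(
    pwm: PWM, p1: np.ndarray | None = None, p2: np.ndarray | None = None
) -> PWM:
    """Center and rescale so that K_d = 0 and R^2 = 75 * L1.

    The transform is W = alpha * (W' - kappa) with kappa = K_d(W') and alpha
    chosen to hit the target sum of squares. Because p1 and p2 each sum to 1,
    subtracting kappa zeroes K_d exactly; the scale factor leaves it zero.
    A constant input matrix has no spread to rescale and is rejected.
    """
    if p1 is None or p2 is None:
        d1, d2 = default_p1_p2(pwm)
        p1 = d1 if p1 is None else p1
        p2 = d2 if p2 is None else p2
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if not (np.isclose(p1.sum(), 1.0) and np.isclose(p2.sum(), 1.0)):
        raise ValueError("p1 and p2 must each sum to 1")
    w = pwm.weights
    kd_before = pwm_kd(w, p1, p2)
    r2_before = pwm_r2(w)
    centered = w - kd_before
    r2_centered = pwm_r2(centered)
    # relative floor so an exactly-constant matrix is caught despite round-off
    floor = 1e-18 * w.size * max(1.0, kd_before * kd_before)
    if r2_centered <= floor or not np.isfinite(r2_centered):
        raise ValueError("degenerate (constant) weight matrix: R^2 = 0 after centering")
    target = 75.0 * pwm.l1
    alpha = float(np.sqrt(target / r2_centered))
    out = centered * alpha
    record = {
        "kd_before": kd_before,
        "r2_before": r2_before,
        "kd_after": pwm_kd(out, p1, p2),
        "r2_after": pwm_r2(out),
        "alpha": alpha,
        "kappa": kd_before,
        "target_r2": target,
    }
    return PWM(
        weights=out,
        background=pwm.background,
        l1=pwm.l1,
        normalization=record,
        class_id=pwm.class_id,
        empty_columns=pwm.empty_columns,
    )


def conservation_profile(pwm: PWM) -> np.ndarray:
    """Per-column conservation statistic X(j).

    X(j) = sqrt(2 * sum_i W(i,j)^2) - sqrt(2n - 1) with n = 9 degrees of
    freedom; approximately standard normal for background columns, so
    |X| > 3-4 marks columns whose dinucleotide usage departs from chance.
    """
    chi2 = np.sum(pwm.weights**2, axis=0)
    return np.sqrt(2.0 * chi2) - np.sqrt(2.0 * PROFILE_DF - 1.0)


def save_pwm(pwm: PWM, tsv_path: str | Path, header: str | None = None) -> None:
    """Serialize weights as TSV (rows = dinucleotides, columns 2..L1) + JSON sidecar."""
    tsv_path = Path(tsv_path)
    cols = [str(j) for j in range(2, 2 + pwm.n_columns)]
    df = pd.DataFrame(pwm.weights, index=DINUCLEOTIDES, columns=cols)
    with open(tsv_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label="dinucleotide")
    sidecar = {
        "l1": pwm.l1,
        "class_id": pwm.class_id,
        "background": pwm.background.tolist(),
        "normalization": pwm.normalization,
    }
    tsv_path.with_suffix(tsv_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def load_pwm(tsv_path: str | Path) -> PWM:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", comment="#", index_col=0)
    meta = json.loads(tsv_path.with_suffix(tsv_path.suffix + ".json").read_text())
    return PWM(
        weights=df.loc[DINUCLEOTIDES].to_numpy(dtype=np.float64),
        background=np.asarray(meta["background"], dtype=np.float64),
        l1=int(meta["l1"]),
        normalization=meta.get("normalization", {}),
        class_id=meta.get("class_id"),
    )
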