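"""Shuffle-based null distributions and Z scores.

Every similarity score in the pipeline is judged against a Monte-Carlo null
built by shuffling the scored sequence (class membership) or the chromosome
(genome scan): Z = (observed - null mean) / null standard deviation. The
default null is a mononucleotide shuffle; local pair- and triplet-token
shuffles, which preserve short-range composition inside sliding windows,
serve as harder controls only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .alignment import DEFAULT_GAP, global_score, local_best
from .pwm_core import PWM, base_codes, dinucleotide_codes

SHUFFLE_MODES = ("mono", "pair", "triplet")

_BASES = np.frombuffer(b"ATCGN", dtype=np.uint8)


@dataclass
class NullModel:
    """Moments of a shuffle null for one (matrix, sequence source) pairing."""

    mean: float
    variance: float
    n_samples: int
    mode: str
    seed: int | None = None
    context: str | None = None  # e.g. "class3/chr1"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 null samples")
        if self.variance <= 0:
            raise ValueError("null variance must be positive (degenerate sequence?)")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def z(self, score: float) -> float:
        return (score - self.mean) / self.sd


def save_null_models(models: dict[str, NullModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: asdict(m) for k, m in models.items()}, indent=1)
    )


def load_null_models(path: str | Path) -> dict[str, NullModel]:
    raw = json.loads(Path(path).read_text())
    return {k: NullModel(**v) for k, v in raw.items()}


def _codes_of(seq: str | np.ndarray) -> np.ndarray:
    return base_codes(seq) if isinstance(seq, str) else np.asarray(seq, np.int8)


def shuffle_codes(
    codes: np.ndarray,
    mode: str = "mono",
    window: int = 600,
    stride: int = 300,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Shuffle a base-code array; see shuffle_sequence."""
    rng = rng or np.random.default_rng()
    if mode == "mono":
        return rng.permutation(codes)
    if mode not in SHUFFLE_MODES:
        raise ValueError(f"unknown shuffle mode: {mode!r}")
    k = 2 if mode == "pair" else 3
    out = codes.copy()
    n = out.shape[0]
    start = 0
    while start < n:
        end = min(start + window, n)
        n_tok = (end - start) // k
        if n_tok > 1:
            block = out[start : start + n_tok * k].reshape(n_tok, k)
            out[start : start + n_tok * k] = block[rng.permutation(n_tok)].reshape(-1)
        if end == n:
            break
        start += stride
    return out


def shuffle_sequence(
    seq: str,
    mode: str = "mono",
    window: int = 600,
    stride: int = 300,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Composition-preserving randomization of a sequence.

    ``mono`` permutes single bases globally. ``pair``/``triplet`` tokenize a
    sliding window (length ``window``) into non-overlapping 2- or 3-base
    tokens, permute the tokens within the window, then advance the window by
    ``stride`` and repeat, so local token composition is preserved while
    longer-range order is destroyed. Deterministic under a fixed seed.
    """
    rng = rng or np.random.default_rng(seed)
    codes = _codes_of(seq)
    shuffled = shuffle_codes(codes, mode, window, stride, rng)
    return _BASES[np.where(shuffled < 0, 4, shuffled)].tobytes().decode("ascii")


def z_score_membership(
    seq: str | np.ndarray,
    pwm: PWM,
    n: int = 1000,
    gap: float = DEFAULT_GAP,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, NullModel]:
    """Studentized global-alignment score of a promoter window against a PWM.

    F_max is compared with n mononucleotide shuffles of the same sequence:
    Z = (F_max - mean F_r) / sd(F_r). Members of a class are sequences with
    Z above the membership threshold (5.0 in the reference pipeline).
    """
    rng = rng or np.random.default_rng(seed)
    codes = _codes_of(seq)
    f_max = float(global_score(dinucleotide_codes(codes), pwm.weights, gap))
    null = np.empty(n)
    for i in range(n):
        shuf = rng.permutation(codes)
        null[i] = global_score(dinucleotide_codes(shuf), pwm.weights, gap)
    var = float(null.var(ddof=1))
    if var <= 0:
        raise ValueError("degenerate null: zero variance of shuffled scores")
    model = NullModel(
        mean=float(null.mean()), variance=var, n_samples=n, mode="mono", seed=seed
    )
    return model.z(f_max), model


def chromosome_null(
    chrom: str | np.ndarray,
    pwm: PWM,
    n_windows: int = 10_000,
    window_len: int | None = None,
    gap: float = DEFAULT_GAP,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    context: str | None = None,
) -> NullModel:
    """Null moments of the local-alignment score E_max on a shuffled chromosome.

    The chromosome is mononucleotide-shuffled once; E_max is computed on up
    to ``n_windows`` non-overlapping windows (stride = window length, for
    independence of the samples) of length L1 + 50 by default.
    """
    rng = rng or np.random.default_rng(seed)
    codes = _codes_of(chrom)
    if (codes < 0).all():
        raise ValueError("chromosome is all N")
    window_len = window_len or pwm.l1 + 50
    if codes.shape[0] <= window_len:
        raise ValueError("chromosome shorter than one scan window")
    shuffled = rng.permutation(codes)
    starts = np.arange(0, codes.shape[0] - window_len + 1, window_len)
    if starts.shape[0] > n_windows:
        starts = starts[
            np.sort(rng.choice(starts.shape[0], size=n_windows, replace=False))
        ]
    scores = np.empty(starts.shape[0])
    for i, s in enumerate(starts):
        din = dinucleotide_codes(shuffled[s : s + window_len])
        scores[i], *_ = local_best(din, pwm.weights, gap)
    var = float(scores.var(ddof=1))
    if var <= 0:
        raise ValueError("degenerate chromosome null: zero variance")
    return NullModel(
        mean=float(scores.mean()),
        variance=var,
        n_samples=int(starts.shape[0]),
        mode="mono",
        seed=seed,
        context=context,
    )
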