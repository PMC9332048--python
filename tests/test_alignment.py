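"""Sequence-vs-PWM dynamic programming against an exhaustive path oracle."""

import numpy as np
import pytest

from ppscan.alignment import (
    AlignmentResult,
    GapParams,
    global_align,
    local_align,
    local_align_best,
)
from ppscan.pwm_core import PWM, dinucleotide_codes


def make_pwm(weights):
    weights = np.asarray(weights, dtype=np.float64)
    return PWM(
        weights=weights, background=np.full(16, 1 / 16), l1=weights.shape[1] + 1
    )


def brute_global(codes, weights, gap):
    """Exhaustive enumeration of all monotone global alignment paths."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == 0 and j == 0:
            return 0.0
        best = -np.inf
        if i > 0 and j > 0:
            w = weights[codes[i - 1], j - 1] if codes[i - 1] >= 0 else 0.0
            best = max(best, f(i - 1, j - 1) + w)
        if i > 0:
            best = max(best, f(i - 1, j) - gap)
        if j > 0:
            best = max(best, f(i, j - 1) - gap)
        return best

    return f(len(codes), weights.shape[1])


def brute_local(codes, weights, gap):
    """Best local segment score by enumeration with a zero floor."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def h(i, j):
        if i == 0 or j == 0:
            return 0.0
        w = weights[codes[i - 1], j - 1] if codes[i - 1] >= 0 else 0.0
        return max(0.0, h(i - 1, j - 1) + w, h(i - 1, j) - gap, h(i, j - 1) - gap)

    return max(
        h(i, j)
        for i in range(len(codes) + 1)
        for j in range(weights.shape[1] + 1)
    )


class TestGlobalAlign:
    def test_zero_matrix_pure_gap_cost(self):
        pwm = make_pwm(np.zeros((16, 3)))
        res = global_align("ACGTACGT", pwm, gaps=GapParams(d_seq=5.0))
        # 7 dinucleotide positions vs 3 columns -> 4 unmatched positions
        assert res.score == -5.0 * 4

    def test_equal_length_peaked_matrix_sums_column_maxima(self):
        seq = "AACGT"
        codes = dinucleotide_codes(seq)
        weights = np.full((16, 4), -1.0)
        for j, c in enumerate(codes):
            weights[c, j] = 3.0
        res = global_align(seq, make_pwm(weights))
        assert res.score == 12.0
        assert res.cigar == "4M"

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            global_align("A", make_pwm(np.zeros((16, 3))))

    def test_matches_brute_force(self, rng):
        """DP equals exhaustive path enumeration on small random instances."""
        for _ in range(150):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(1, 7))
            codes = rng.integers(0, 16, size=n - 1).astype(np.int8)
            weights = rng.choice([-1.0, 0.0, 1.0], size=(16, m))
            gap = float(rng.choice([0.5, 1.0, 2.0]))
            res = global_align(codes, make_pwm(weights), gap)
            assert res.score == pytest.approx(brute_global(tuple(codes), weights, gap))

    def test_gapless_limit_is_dot_product(self, rng):
        """With a huge gap penalty and equal lengths the optimum is gapless."""
        n = 30
        codes = rng.integers(0, 16, size=n).astype(np.int8)
        weights = rng.normal(size=(16, n))
        res = global_align(codes, make_pwm(weights), gaps=1e9)
        expected = sum(weights[c, j] for j, c in enumerate(codes))
        assert res.score == pytest.approx(expected)
        assert res.cigar == f"{n}M"


class TestLocalAlign:
    def test_all_negative_matrix_floors_at_zero(self):
        pwm = make_pwm(np.full((16, 5), -2.0))
        res = local_align("ACGTACGTAC", pwm)
        assert res.score == 0.0
        assert res.seq_interval is None and res.pwm_interval is None

    def test_matches_brute_force(self, rng):
        for _ in range(150):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(1, 7))
            codes = rng.integers(0, 16, size=n - 1).astype(np.int8)
            weights = rng.choice([-1.0, 0.0, 1.0], size=(16, m))
            gap = float(rng.choice([0.5, 1.0, 2.0]))
            res = local_align(codes, make_pwm(weights), gap)
            assert res.score == pytest.approx(brute_local(tuple(codes), weights, gap))
            e, *_ = local_align_best(codes, make_pwm(weights), gap)
            assert e == pytest.approx(res.score)

    def test_planted_segment_recovered(self, rng):
        """An exact consensus segment inside random flanks is localized."""
        m = 40
        weights = np.full((16, m), -1.0)
        consensus = rng.integers(0, 16, size=m).astype(np.int8)
        weights[consensus, np.arange(m)] = 4.0
        flank_left = rng.integers(0, 16, size=30).astype(np.int8)
        flank_right = rng.integers(0, 16, size=25).astype(np.int8)
        codes = np.concatenate([flank_left, consensus, flank_right])
        res = local_align(codes, make_pwm(weights))
        # positions are 1-based over dinucleotide slots: plant occupies 31..70
        i0, imax = res.seq_interval
        assert (i0 - 1, imax - 1) == (31, 70)
        assert res.pwm_interval == (2, m + 1)
        assert res.score >= 4.0 * m - 9  # a few chance matches may extend it

    def test_score_exceeds_best_single_column(self, rng):
        weights = rng.normal(size=(16, 8))
        codes = rng.integers(0, 16, size=20).astype(np.int8)
        e, *_ = local_align_best(codes, make_pwm(weights))
        reachable = max(weights[c, :].max() for c in codes)
        assert e >= max(0.0, reachable)

    def test_flank_content_does_not_change_local_score(self, rng):
        """Randomizing sequence outside the reported interval leaves E_max."""
        m = 30
        weights = np.full((16, m), -1.5)
        consensus = rng.integers(0, 16, size=m).astype(np.int8)
        weights[consensus, np.arange(m)] = 5.0
        for _ in range(5):
            left = rng.integers(0, 16, size=15).astype(np.int8)
            right = rng.integers(0, 16, size=15).astype(np.int8)
            codes = np.concatenate([left, consensus, right])
            e, *_ = local_align_best(codes, make_pwm(weights))
            assert e >= 5.0 * m - 7.5  # full plant always reachable


class TestTraceConsistency:
    def test_cigar_lengths_match_intervals(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            m = int(rng.integers(3, 20))
            codes = rng.integers(0, 16, size=n).astype(np.int8)
            weights = rng.normal(size=(16, m))
            res = global_align(codes, make_pwm(weights), gaps=2.0)
            n_m = sum(
                int(tok[:-1])
                for tok in _cigar_tokens(res.cigar)
                if tok[-1] in "MI"
            )
            n_c = sum(
                int(tok[:-1])
                for tok in _cigar_tokens(res.cigar)
                if tok[-1] in "MD"
            )
            assert n_m == n and n_c == m


def _cigar_tokens(cigar):
    import re

    return re.findall(r"\d+[MID]", cigar)
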