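"""Dinucleotide encoding, frequency matrices, PWM normalization, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppscan.pwm_core import (
    DINUCLEOTIDES,
    PWM,
    build_frequency_matrix,
    compute_pwm,
    conservation_profile,
    decode_dinucleotide,
    default_p1_p2,
    encode_dinucleotides,
    load_pwm,
    normalize_pwm,
    pwm_kd,
    pwm_r2,
    save_pwm,
)


class TestEncoding:
    @pytest.mark.parametrize("pair,s", [("AA", 1), ("GG", 16), ("TC", 10), ("TA", 2)])
    def test_formula(self, pair, s):
        assert encode_dinucleotides(pair)[0] == s

    def test_bijection(self):
        codes = {encode_dinucleotides(d)[0] for d in DINUCLEOTIDES}
        assert codes == set(range(1, 17))
        for s in range(1, 17):
            assert encode_dinucleotides(decode_dinucleotide(s))[0] == s

    def test_n_is_missing(self):
        assert list(encode_dinucleotides("ANA")) == [0, 0]


class TestFrequencyMatrix:
    def test_direct_count(self):
        fm = build_frequency_matrix(["ACG", "ACG"])
        s_ac = encode_dinucleotides("AC")[0] - 1
        s_cg = encode_dinucleotides("CG")[0] - 1
        assert fm.counts[s_ac, 0] == 2 and fm.counts[s_cg, 1] == 2
        assert fm.counts.sum() == 4

    def test_gap_breaks_both_pairs(self):
        fm = build_frequency_matrix(["ACG", "A-G"])
        assert fm.counts[:, 0].sum() == 1 and fm.counts[:, 1].sum() == 1

    def test_total_equals_ungapped_pair_count(self, rng):
        # oracle: enumerate ungapped adjacent pairs per row
        rows = []
        for _ in range(20):
            rows.append("".join(rng.choice(list("ACGT-N"), size=30)))
        fm = build_frequency_matrix(rows)
        expected = sum(
            sum(
                1
                for a, b in zip(row, row[1:])
                if a in "ACGT" and b in "ACGT"
            )
            for row in rows
        )
        assert fm.counts.sum() == expected

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_frequency_matrix(["ACG", "AC"])


def _eq1_oracle(m):
    """Independent single-pass coding of the raw weight definition."""
    m = np.asarray(m, float)
    njs = m.sum(axis=0)
    y = m.sum(axis=1)
    k = y.sum()
    p = y / k
    out = np.empty_like(m)
    for i in range(16):
        for j in range(m.shape[1]):
            out[i, j] = (m[i, j] - njs[j] * p[i]) / np.sqrt(
                njs[j] * p[i] * (1 - p[i])
            )
    return out


class TestComputePwm:
    def test_zero_deviation(self):
        m = np.outer(np.arange(1, 17, dtype=float), np.ones(5)) * 4
        # scale columns so M(i,j) = N(j) p(i) exactly
        pwm = compute_pwm(build_like(m))
        assert np.allclose(pwm.weights, 0.0)

    def test_uniform_counts_give_zero(self):
        m = np.full((16, 7), 3.0)
        pwm = compute_pwm(build_like(m))
        assert np.allclose(pwm.weights, 0.0)

    def test_matches_independent_oracle(self):
        m = np.arange(1, 49, dtype=float).reshape(16, 3)
        pwm = compute_pwm(build_like(m))
        assert np.allclose(pwm.weights, _eq1_oracle(m))

    def test_empty_column_flagged_zero(self):
        m = np.ones((16, 4))
        m[:, 2] = 0.0
        pwm = compute_pwm(build_like(m))
        assert np.allclose(pwm.weights[:, 2], 0.0)
        assert list(pwm.empty_columns) == [2]

    def test_standardization_on_iid_alignment(self, rng):
        """Cells of the raw PWM have mean ~0, variance ~1 on iid alignments."""
        n_seq, l1 = 1000, 40
        aln = rng.integers(0, 4, size=(n_seq, l1)).astype(np.int8)
        pwm = compute_pwm(build_frequency_matrix(aln))
        cells = pwm.weights.ravel()
        assert abs(cells.mean()) < 0.1
        assert 0.7 < cells.var() < 1.3


def build_like(m):
    from ppscan.pwm_core import FrequencyMatrix

    return FrequencyMatrix(counts=m, l1=m.shape[1] + 1, n_seq=int(m.sum(axis=0).max()))


class TestNormalizePwm:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_contract_on_random_matrices(self, seed):
        """After the transform, the centering statistic is 0 and the total
        sum of squares is 75 L1, to 1e-9 relative tolerance."""
        rng = np.random.default_rng(seed)
        l1 = int(rng.integers(5, 80))
        pwm = PWM(
            weights=rng.normal(rng.normal(), rng.uniform(0.5, 3), size=(16, l1 - 1)),
            background=np.full(16, 1 / 16),
            l1=l1,
        )
        out = normalize_pwm(pwm)
        p1, p2 = default_p1_p2(out)
        r = np.sqrt(75.0 * l1)
        assert abs(pwm_kd(out.weights, p1, p2)) < 1e-9 * r
        assert abs(pwm_r2(out.weights) / (75.0 * l1) - 1.0) < 1e-9

    def test_fixed_point(self, rng):
        pwm = PWM(
            weights=rng.normal(size=(16, 19)), background=np.full(16, 1 / 16), l1=20
        )
        once = normalize_pwm(pwm)
        twice = normalize_pwm(once)
        assert np.allclose(once.weights, twice.weights)
        assert np.isclose(twice.normalization["alpha"], 1.0)
        assert abs(twice.normalization["kappa"]) < 1e-12

    def test_scale_invariance(self, rng):
        w = rng.normal(size=(16, 29))
        a = normalize_pwm(PWM(weights=w, background=np.full(16, 1 / 16), l1=30))
        b = normalize_pwm(PWM(weights=10 * w, background=np.full(16, 1 / 16), l1=30))
        assert np.allclose(a.weights, b.weights)

    def test_constant_matrix_rejected(self):
        pwm = PWM(
            weights=np.full((16, 9), 2.5), background=np.full(16, 1 / 16), l1=10
        )
        with pytest.raises(ValueError, match="degenerate"):
            normalize_pwm(pwm)


class TestConservationProfile:
    def test_closed_forms(self):
        w = np.zeros((16, 3))
        w[:, 1] = np.sqrt(8.5 / 16)  # column sum of squares = 8.5
        pwm = PWM(weights=w, background=np.full(16, 1 / 16), l1=4)
        x = conservation_profile(pwm)
        assert np.isclose(x[0], -np.sqrt(17.0))
        assert abs(x[1]) < 1e-12

    def test_background_columns_rarely_exceed_four(self, rng):
        """Raw PWMs of iid alignments give |X| < 4 almost everywhere."""
        exceed = total = 0
        for _ in range(100):
            aln = rng.integers(0, 4, size=(300, 31)).astype(np.int8)
            pwm = compute_pwm(build_frequency_matrix(aln))
            x = conservation_profile(pwm)
            exceed += int((np.abs(x) >= 4).sum())
            total += x.size
        assert exceed / total < 0.01

    def test_planted_core_stands_out(self, small_synth):
        seqs, labels = small_synth.member_sequences()
        cls = [s for s, l in zip(seqs, labels) if l == 1]
        pwm = compute_pwm(build_frequency_matrix(cls))
        x = conservation_profile(pwm)
        core = slice(489, 515)  # columns 491..515 in column-2-based indexing
        assert x[core].max() > 10.0
        assert x[core].max() == x.max()


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        pwm = normalize_pwm(
            PWM(weights=rng.normal(size=(16, 49)), background=np.full(16, 1 / 16), l1=50)
        )
        pwm.class_id = 7
        save_pwm(pwm, tmp_path / "c.pwm.tsv", header="test")
        back = load_pwm(tmp_path / "c.pwm.tsv")
        assert np.allclose(back.weights, pwm.weights)
        assert back.l1 == 50 and back.class_id == 7
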