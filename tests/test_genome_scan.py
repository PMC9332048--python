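"""Genome scanning, overlap resolution, strand variants, feature intersection."""

import numpy as np
import pytest

from ppscan.class_builder import class_model_from_sequences
from ppscan.genome_scan import (
    ScanConfig,
    intersect_features,
    make_null_models,
    overlap_length,
    resolve_overlaps,
    scan_chromosome,
    scan_variants,
)
from ppscan.io_formats import FeatureInterval, PPSRecord
from ppscan.synthetic_data import (
    SynthSpec,
    _codes_to_str,
    _draw_consensus,
    _markov_background,
    sample_member,
)


@pytest.fixture(scope="module")
def planted_genome():
    """50 kb chromosome with a single planted class instance."""
    rng = np.random.default_rng(21)
    spec = SynthSpec(seed=21, sharpness=0.5)
    cons = _draw_consensus(spec, rng)
    members = [sample_member(cons, spec, rng) for _ in range(120)]
    model = class_model_from_sequences(members, class_id=1)
    chrom = _markov_background(50_000, spec, rng)
    plant = sample_member(cons, spec, rng)
    codes = np.array([{"A": 0, "T": 1, "C": 2, "G": 3}[b] for b in plant], np.int8)
    start = 20_000  # 0-based
    chrom[start : start + 600] = codes
    genome = {"chr1": _codes_to_str(chrom)}
    return genome, model, (start + 1, start + 600)


@pytest.fixture(scope="module")
def scan_cfg():
    return ScanConfig(stride=50, null_windows=60, variants=("forward",))


class TestScanChromosome:
    def test_single_plant_found_once(self, planted_genome, scan_cfg):
        genome, model, (t_start, t_end) = planted_genome
        nulls = make_null_models(genome, [model], scan_cfg, seed=4)["chr1"]
        recs = scan_chromosome(
            "chr1", genome["chr1"], [model], nulls, scan_cfg
        )
        recs = resolve_overlaps(recs)
        assert len(recs) == 1
        (rec,) = recs
        ov = overlap_length(rec.start, rec.end, t_start, t_end)
        assert ov >= 0.9 * 600
        assert rec.z >= 6.0 and rec.class_id == 1

    def test_infinite_threshold_empty(self, planted_genome):
        genome, model, _ = planted_genome
        cfg = ScanConfig(
            z0=float("inf"), stride=50, null_windows=60, variants=("forward",)
        )
        nulls = make_null_models(genome, [model], cfg, seed=4)["chr1"]
        assert scan_chromosome("chr1", genome["chr1"], [model], nulls, cfg) == []

    def test_missing_null_model_errors(self, planted_genome, scan_cfg):
        genome, model, _ = planted_genome
        with pytest.raises(KeyError, match="null model"):
            scan_chromosome("chr1", genome["chr1"], [model], {}, scan_cfg)

    def test_shuffled_chromosome_hit_rate(self, planted_genome, scan_cfg):
        """On a fully shuffled chromosome, Z >= 6 hits are almost absent."""
        genome, model, _ = planted_genome
        rng = np.random.default_rng(6)
        from ppscan.nullstats import shuffle_sequence

        shuf = {"chr1": shuffle_sequence(genome["chr1"], "mono", rng=rng)}
        nulls = make_null_models(shuf, [model], scan_cfg, seed=5)["chr1"]
        recs = scan_chromosome("chr1", shuf["chr1"], [model], nulls, scan_cfg)
        n_windows = (50_000 - model.l1 - 50) // scan_cfg.stride + 1
        assert len(recs) / n_windows <= 0.005

    def test_all_n_chromosome_yields_nothing(self, planted_genome, scan_cfg):
        genome, model, _ = planted_genome
        nulls = make_null_models(genome, [model], scan_cfg, seed=4)["chr1"]
        recs = scan_chromosome("chr1", "N" * 30_000, [model], nulls, scan_cfg)
        assert recs == []

    def test_monotone_in_z0(self, planted_genome):
        genome, model, _ = planted_genome
        hits = {}
        nulls = None
        for z0 in (6.0, 6.5, 7.0):
            cfg = ScanConfig(z0=z0, stride=50, null_windows=60, variants=("forward",))
            nulls = nulls or make_null_models(genome, [model], cfg, seed=4)["chr1"]
            recs = scan_chromosome("chr1", genome["chr1"], [model], nulls, cfg)
            hits[z0] = {(r.start, r.end) for r in recs}
        assert hits[7.0] <= hits[6.5] <= hits[6.0]


def _rec(rid, start, end, z, cid=1, chrom="c1", variant="forward"):
    return PPSRecord(rid, chrom, start, end, variant, z, 100.0, cid)


def _resolve_oracle(records, frac=0.10):
    """O(n^2) iterative reference: repeatedly drop the smaller-Z member of
    the worst surviving conflict, preferring conflicts involving the
    current best record."""
    pool = list(records)
    out = []
    while pool:
        pool.sort(key=lambda r: (-r.z, r.class_id, r.chrom, r.start))
        best = pool.pop(0)
        out.append(best)
        survivors = []
        for r in pool:
            if r.chrom == best.chrom:
                ov = overlap_length(r.start, r.end, best.start, best.end)
                if ov > frac * min(r.length, best.length):
                    continue
            survivors.append(r)
        pool = survivors
    out.sort(key=lambda r: (r.chrom, r.start, r.class_id))
    return out


class TestResolveOverlaps:
    def test_half_overlap_larger_z_wins(self):
        a = _rec("a", 100, 299, z=7.0, cid=1)
        b = _rec("b", 200, 399, z=8.0, cid=2)
        out = resolve_overlaps([a, b])
        assert [r.record_id for r in out] == ["b"]

    def test_small_overlap_both_survive(self):
        a = _rec("a", 100, 299, z=7.0)
        b = _rec("b", 291, 490, z=8.0, cid=2)  # 9/200 = 4.5% overlap
        assert len(resolve_overlaps([a, b])) == 2

    def test_equal_z_lower_class_id_wins(self):
        a = _rec("a", 100, 299, z=7.0, cid=2)
        b = _rec("b", 150, 349, z=7.0, cid=1)
        out = resolve_overlaps([a, b])
        assert out[0].class_id == 1

    def test_matches_oracle_on_random_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 31))
            records = []
            for i in range(n):
                start = int(rng.integers(1, 3000))
                length = int(rng.integers(50, 700))
                records.append(
                    _rec(
                        f"r{i}",
                        start,
                        start + length - 1,
                        z=float(np.round(rng.uniform(6, 20), 3)),
                        cid=int(rng.integers(1, 4)),
                        chrom=f"c{int(rng.integers(1, 3))}",
                    )
                )
            got = resolve_overlaps(records)
            want = _resolve_oracle(records)
            assert [r.record_id for r in got] == [r.record_id for r in want]

    def test_final_records_pairwise_compatible(self, rng):
        records = []
        for i in range(40):
            s = int(rng.integers(1, 1500))
            records.append(_rec(f"r{i}", s, s + 400, z=float(rng.uniform(6, 12))))
        out = resolve_overlaps(records, 0.10)
        for i, a in enumerate(out):
            for b in out[i + 1 :]:
                ov = overlap_length(a.start, a.end, b.start, b.end)
                assert ov <= 0.10 * min(a.length, b.length)


class TestScanVariants:
    def test_reverse_complement_plant_found_on_reverse_variant(self):
        rng = np.random.default_rng(31)
        spec = SynthSpec(seed=31, sharpness=0.5)
        cons = _draw_consensus(spec, rng)
        members = [sample_member(cons, spec, rng) for _ in range(100)]
        model = class_model_from_sequences(members, class_id=1)
        chrom = _markov_background(30_000, spec, rng)
        plant = sample_member(cons, spec, rng)
        from ppscan.io_formats import sequence_transform

        rc = sequence_transform(plant, "reverse_complement")
        codes = np.array([{"A": 0, "T": 1, "C": 2, "G": 3}[b] for b in rc], np.int8)
        chrom[12_000 : 12_600] = codes
        genome = {"chr1": _codes_to_str(chrom)}
        cfg = ScanConfig(stride=50, null_windows=40, variants=("forward", "reverse"))
        out = scan_variants(genome, [model], cfg, seed=2)
        assert out["forward"] == []
        assert len(out["reverse"]) == 1
        rec = out["reverse"][0]
        # coordinates are mapped back to the forward frame
        assert overlap_length(rec.start, rec.end, 12_001, 12_600) >= 540
        assert rec.strand_variant == "reverse"

    def test_unknown_variant_rejected(self, planted_genome):
        genome, model, _ = planted_genome
        cfg = ScanConfig(variants=("mirror",), stride=200, null_windows=20)
        with pytest.raises(ValueError, match="unknown strand variant"):
            scan_variants(genome, [model], cfg, seed=1)

    def test_variant_tag_preserved_in_export(self, tmp_path):
        from ppscan.io_formats import export_pps, parse_pps_tsv

        recs = [
            _rec("a", 10, 500, 7.0, variant="reverse_only"),
            _rec("b", 600, 900, 6.5, variant="complement_only"),
        ]
        export_pps(recs, tmp_path / "x.tsv", "tsv")
        back = parse_pps_tsv(tmp_path / "x.tsv")
        assert [r.strand_variant for r in back] == ["reverse_only", "complement_only"]


def _sweep_oracle(records, features, min_fraction, mode):
    rows = 0
    for r in records:
        for f in features:
            if f.chrom != r.chrom:
                continue
            ov = overlap_length(r.start, r.end, f.start, f.end)
            if ov == 0:
                continue
            denom = {
                "of_feature": f.end - f.start + 1,
                "of_record": r.length,
                "of_min": min(f.end - f.start + 1, r.length),
            }[mode]
            if ov / denom >= min_fraction:
                rows += 1
    return rows


class TestIntersectFeatures:
    def test_worked_example(self):
        rec = _rec("p", 100, 699, 7.0, variant="forward")
        feat = FeatureInterval("prom1", "c1", 150, 749, "+", "annotated-promoter")
        df = intersect_features([rec], [feat], 0.5, "of_min")
        assert len(df) == 1
        row = df.iloc[0]
        assert row["overlap_len"] == 550
        assert row["fraction"] == pytest.approx(550 / 600, abs=1e-4)
        assert row["strand_label"] == "++"

    def test_strand_labels(self):
        rec = _rec("p", 100, 699, 7.0, variant="reverse")
        feat = FeatureInterval("prom1", "c1", 150, 749, "+")
        df = intersect_features([rec], [feat], 0.5)
        assert df.iloc[0]["strand_label"] == "+-"

    @pytest.mark.parametrize("mode", ["of_feature", "of_record", "of_min"])
    def test_counts_match_brute_force(self, rng, mode):
        records, features = [], []
        for i in range(60):
            s = int(rng.integers(1, 5000))
            records.append(
                _rec(
                    f"r{i}", s, s + int(rng.integers(50, 800)),
                    z=7.0, chrom=f"c{int(rng.integers(1, 3))}",
                    variant="forward" if rng.random() < 0.5 else "reverse",
                )
            )
        for i in range(60):
            s = int(rng.integers(1, 5000))
            features.append(
                FeatureInterval(
                    f"f{i}", f"c{int(rng.integers(1, 3))}", s,
                    s + int(rng.integers(30, 900)),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        df = intersect_features(records, features, 0.5, mode)
        assert len(df) == _sweep_oracle(records, features, 0.5, mode)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            intersect_features([], [], 0.5, "of_union")
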