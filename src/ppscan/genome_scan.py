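"""Genome-wide search for potential promoter sequences (PPSs).

For every class PWM a window of length L1 + 50 slides along each chromosome;
the best local alignment of each window yields an E_max(k) series whose
non-intersecting local maxima, studentized against a shuffled-chromosome
null, become PPS candidates at Z >= Z0 (default 6.0). Candidates from
different classes competing for the same locus are resolved by the 10%
mutual-overlap rule: of any pair overlapping by more than a tenth of the
shorter record, only the larger-Z record survives, and its class is the one
remembered.

Strand handling is explicit: the forward scan and the reverse-complement
scan cover the two biological strands, while complement-only (base
substitution without the 180-degree flip) and reverse-only (flip without
complementing) are mirror controls. All coordinates are mapped back to the
forward reference frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import DEFAULT_GAP, local_align, local_best
from .class_builder import ClassModel
from .io_formats import FeatureInterval  # noqa: F401  (re-exported)
from .io_formats import PPSRecord, sequence_transform
from .nullstats import NullModel, chromosome_null
from .pwm_core import base_codes, dinucleotide_codes

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Genome-scan settings; defaults are the reference pipeline's."""

    z0: float = 6.0
    window_slack: int = 50  # window length = L1 + slack
    stride: int = 1
    overlap_fraction: float = 0.10
    gap: float = DEFAULT_GAP
    max_n_fraction: float = 0.10  # windows with more N are skipped
    variants: tuple[str, ...] = ("forward", "reverse")
    null_windows: int = 10_000

    def __post_init__(self) -> None:
        if self.z0 <= 0:
            raise ValueError("Z0 must be positive")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap fraction must be in (0, 1]")


_VARIANT_TRANSFORM = {
    "forward": "identity",
    "reverse": "reverse_complement",
    "complement_only": "complement_only",
    "reverse_only": "reverse_only",
}


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap of two 1-based inclusive intervals (0 when disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def scan_chromosome(
    chrom_name: str,
    chrom_seq: str,
    class_models: list[ClassModel],
    null_models: dict[int, NullModel],
    config: ScanConfig | None = None,
    variant: str = "forward",
) -> list[PPSRecord]:
    """PPS candidates of one chromosome (one strand variant), all classes.

    Per class, the E_max(k) series is reduced to non-intersecting local
    maxima by greedy selection in descending score, each maximum is
    studentized with the class's chromosome null, and survivors with
    Z >= Z0 are returned (not yet resolved across classes). Windows with
    more than ``max_n_fraction`` N bases are skipped.
    """
    config = config or ScanConfig()
    codes = base_codes(chrom_seq)
    din = dinucleotide_codes(codes)
    n = codes.shape[0]
    records: list[PPSRecord] = []
    for model in class_models:
        if model.class_id not in null_models:
            raise KeyError(
                f"no null model for class {model.class_id} on {chrom_name}"
            )
        null = null_models[model.class_id]
        wlen = model.l1 + config.window_slack
        if n < wlen:
            continue
        weights = model.pwm.weights
        candidates = []  # (E, i0_abs, imax_abs, l0, lmax, win_start)
        is_n = codes < 0
        n_cum = np.concatenate(([0], np.cumsum(is_n)))
        for start in range(0, n - wlen + 1, config.stride):
            if (n_cum[start + wlen] - n_cum[start]) > config.max_n_fraction * wlen:
                continue
            e, i0, imax, l0, lmax = local_best(
                din[start : start + wlen - 1], weights, config.gap
            )
            if e <= 0.0:
                continue
            # dinucleotide position t covers bases (t-1, t) of the window;
            # absolute 1-based interval therefore starts at win_start + t - 1
            candidates.append(
                (e, start + i0 - 1, start + imax, l0, lmax, start)
            )
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], c[1]))
        chosen: list[tuple] = []
        occupied: list[tuple[int, int]] = []
        for cand in candidates:
            _, a, b = cand[0], cand[1], cand[2]
            if any(overlap_length(a, b, oa, ob) > 0 for oa, ob in occupied):
                continue
            occupied.append((a, b))
            chosen.append(cand)
        for e, a, b, l0, lmax, start in chosen:
            z = null.z(e)
            if z < config.z0:
                continue
            res = local_align(
                chrom_seq[start : start + wlen], model.pwm, config.gap
            )
            records.append(
                PPSRecord(
                    record_id=f"{chrom_name}:{a}-{b}:c{model.class_id}",
                    chrom=chrom_name,
                    start=a,
                    end=b,
                    strand_variant=variant,
                    z=float(z),
                    score=float(e),
                    class_id=model.class_id,
                    cigar=res.cigar,
                )
            )
    return records


def resolve_overlaps(
    candidates: list[PPSRecord], overlap_fraction: float = 0.10
) -> list[PPSRecord]:
    """Cross-class overlap resolution: larger Z wins.

    Any pair overlapping by more than ``overlap_fraction`` of the shorter
    record keeps only the larger-Z record. Realized as greedy acceptance in
    descending Z (ties: lower class id, then leftmost interval), which is
    deterministic and order-independent.
    """
    order = sorted(candidates, key=lambda r: (-r.z, r.class_id, r.chrom, r.start))
    accepted: list[PPSRecord] = []
    for rec in order:
        conflict = False
        for kept in accepted:
            if kept.chrom != rec.chrom:
                continue
            ov = overlap_length(rec.start, rec.end, kept.start, kept.end)
            if ov > overlap_fraction * min(rec.length, kept.length):
                conflict = True
                break
        if not conflict:
            accepted.append(rec)
    accepted.sort(key=lambda r: (r.chrom, r.start, r.class_id))
    return accepted


def make_null_models(
    genome: dict[str, str],
    class_models: list[ClassModel],
    config: ScanConfig | None = None,
    seed: int | None = None,
) -> dict[str, dict[int, NullModel]]:
    """Chromosome-shuffle null per (chromosome, class)."""
    config = config or ScanConfig()
    out: dict[str, dict[int, NullModel]] = {}
    for ci, (name, seq) in enumerate(genome.items()):
        out[name] = {}
        for model in class_models:
            child_seed = None if seed is None else seed + 1000 * ci + model.class_id
            out[name][model.class_id] = chromosome_null(
                seq,
                model.pwm,
                n_windows=config.null_windows,
                window_len=model.l1 + config.window_slack,
                gap=config.gap,
                seed=child_seed,
                context=f"class{model.class_id}/{name}",
            )
    return out


def _map_back(rec: PPSRecord, variant: str, chrom_len: int) -> PPSRecord:
    """Map an interval found on a transformed chromosome to forward coordinates."""
    if variant in ("reverse", "reverse_only"):
        start = chrom_len - rec.end + 1
        end = chrom_len - rec.start + 1
        rec.record_id = f"{rec.chrom}:{start}-{end}:c{rec.class_id}:{variant}"
        rec.start, rec.end = start, end
    elif variant == "complement_only":
        rec.record_id = f"{rec.record_id}:{variant}"
    return rec


def scan_variants(
    genome: dict[str, str],
    class_models: list[ClassModel],
    config: ScanConfig | None = None,
    seed: int | None = None,
    null_models: dict[str, dict[str, dict[int, NullModel]]] | None = None,
) -> dict[str, list[PPSRecord]]:
    """Scan the requested strand/mirror variants of every chromosome.

    Returns {variant: resolved records} with all coordinates in the forward
    reference frame. Null models are estimated per (variant, chromosome,
    class) unless provided (keyed null_models[variant][chrom][class_id]).
    """
    config = config or ScanConfig()
    out: dict[str, list[PPSRecord]] = {}
    for vi, variant in enumerate(config.variants):
        if variant not in _VARIANT_TRANSFORM:
            raise ValueError(f"unknown strand variant: {variant!r}")
        transform = _VARIANT_TRANSFORM[variant]
        collected: list[PPSRecord] = []
        for name, seq in genome.items():
            tseq = sequence_transform(seq, transform)
            if null_models is not None:
                nulls = null_models[variant][name]
            else:
                vseed = None if seed is None else seed + 7919 * vi
                nulls = make_null_models(
                    {name: tseq}, class_models, config, seed=vseed
                )[name]
            recs = scan_chromosome(
                name, tseq, class_models, nulls, config, variant=variant
            )
            collected.extend(_map_back(r, variant, len(seq)) for r in recs)
        out[variant] = resolve_overlaps(collected, config.overlap_fraction)
    return out


def intersect_features(
    records: list[PPSRecord],
    features: list,
    min_fraction: float = 0.5,
    mode: str = "of_min",
) -> pd.DataFrame:
    """Match PPS records against annotated features by overlap fraction.

    ``mode`` selects the denominator of the overlap fraction: "of_feature"
    (the feature's length — the SINE-style rule), "of_record", or "of_min"
    (the shorter of the two — the annotated-promoter-style rule). The strand
    label pairs the feature strand with the record strand: '++', '--', '+-',
    '-+' (records from mirror variants are labeled '.').
    """
    if mode not in ("of_feature", "of_record", "of_min"):
        raise ValueError(f"unknown intersect mode: {mode!r}")
    rec_strand = {"forward": "+", "reverse": "-"}
    rows = []
    by_chrom: dict[str, list] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for feats in by_chrom.values():
        feats.sort(key=lambda f: f.start)
    for rec in records:
        feats = by_chrom.get(rec.chrom, ())
        for f in feats:
            if f.start > rec.end:
                break
            ov = overlap_length(rec.start, rec.end, f.start, f.end)
            if ov == 0:
                continue
            flen = f.end - f.start + 1
            denom = {
                "of_feature": flen,
                "of_record": rec.length,
                "of_min": min(flen, rec.length),
            }[mode]
            fraction = ov / denom
            if fraction < min_fraction:
                continue
            label = f.strand + rec_strand.get(rec.strand_variant, ".")
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pps_id": rec.record_id,
                    "feature_id": f.feature_id,
                    "overlap_len": ov,
                    "fraction": round(fraction, 4),
                    "strand_label": label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pps_id", "feature_id", "overlap_len", "fraction", "strand_label"],
    )
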