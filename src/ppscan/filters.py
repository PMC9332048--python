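"""Promoter-set filters and run-length threshold derivation.

Four per-sequence rules clean the raw promoter windows before class
construction: (1) no single nucleotide may exceed a fraction of the window
(low-complexity guard), (2) at most a fixed number of N characters (assembly
quality), (3) no homopolymer run longer than a per-base threshold m0, and
(4) G+C fraction inside a plant-promoter-like band. The m0 thresholds can be
re-derived from any reference promoter set by bounding the fraction of
sequences that contain longer runs.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

RULES = ("max_base_frac", "max_n", "run_length", "gc_range")


@dataclass
class FilterParams:
    """Thresholds of the four selection rules.

    Defaults: each base <= 60% of the window, <= 1 N, homopolymer caps
    m0 = {A: 13, T: 12, C: 5, G: 5}, and GC fraction in [0.29, 0.37].
    """

    max_base_frac: float = 0.60
    max_n: int = 1
    m0: dict[str, int] = field(
        default_factory=lambda: {"A": 13, "T": 12, "C": 5, "G": 5}
    )
    gc_min: float = 0.29
    gc_max: float = 0.37

    def __post_init__(self) -> None:
        for frac in (self.max_base_frac, self.gc_min, self.gc_max):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(m < 1 for m in self.m0.values()):
            raise ValueError("m0 thresholds must be positive integers")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterParams":
        """Build from flat config keys (max_base_frac, max_n, m0_A, ..., gc_max)."""
        kwargs = {}
        m0 = {"A": 13, "T": 12, "C": 5, "G": 5}
        for key, val in d.items():
            if key.startswith("m0_"):
                m0[key[3:]] = int(val)
            elif key in ("max_base_frac", "gc_min", "gc_max"):
                kwargs[key] = float(val)
            elif key == "max_n":
                kwargs[key] = int(val)
        return cls(m0=m0, **kwargs)


def max_run_lengths(seq: str) -> dict[str, int]:
    """Longest homopolymer run per base (N runs never count toward any base)."""
    out = {b: 0 for b in "ATCG"}
    for match in re.finditer(r"A+|T+|C+|G+", seq):
        base = match.group(0)[0]
        out[base] = max(out[base], match.end() - match.start())
    return out


def failing_rules(seq: str, params: FilterParams) -> list[str]:
    """Names of every rule the sequence violates, in rule order.

    Base fractions and the GC fraction use the full window length as
    denominator (N positions count in the denominator only).
    """
    length = len(seq)
    counts = Counter(seq)
    failures = []
    if any(counts.get(b, 0) / length > params.max_base_frac for b in "ATCG"):
        failures.append("max_base_frac")
    if counts.get("N", 0) > params.max_n:
        failures.append("max_n")
    runs = max_run_lengths(seq)
    if any(runs[b] > params.m0[b] for b in "ATCG"):
        failures.append("run_length")
    gc = (counts.get("G", 0) + counts.get("C", 0)) / length
    if not params.gc_min <= gc <= params.gc_max:
        failures.append("gc_range")
    return failures


def filter_promoters(regions, params: FilterParams | None = None):
    """Split regions into the kept set (Set1) and a per-rule rejection report.

    A region is kept iff it passes all four rules. The report counts
    rejections both by the first failing rule and by every failing rule;
    decisions are per-sequence, so filtering is idempotent and
    order-independent.

    ``regions`` may hold PromoterRegion objects or plain strings.
    """
    params = params or FilterParams()
    kept = []
    first = Counter()
    any_rule = Counter()
    for region in regions:
        seq = region if isinstance(region, str) else region.sequence
        failures = failing_rules(seq, params)
        if failures:
            first[failures[0]] += 1
            any_rule.update(failures)
        else:
            kept.append(region)
    report = pd.DataFrame(
        {
            "rule": RULES,
            "rejected_first": [first.get(r, 0) for r in RULES],
            "rejected_any": [any_rule.get(r, 0) for r in RULES],
        }
    )
    return kept, report


def write_filter_report(report: pd.DataFrame, path: str | Path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        report.to_csv(fh, sep="\t", index=False)


def derive_run_thresholds(
    reference_regions, cutoffs: dict[str, float]
) -> dict[str, int]:
    """Smallest m0 per base such that P(a reference sequence has a run > m0)
    falls below the base's probability cutoff.

    This reproduces, on any reference promoter set, the calibration that
    produced the default caps {A: 13, T: 12, C: 5, G: 5}.
    """
    seqs = [r if isinstance(r, str) else r.sequence for r in reference_regions]
    if not seqs:
        raise ValueError("reference set is empty")
    for base, cutoff in cutoffs.items():
        if not 0.0 < cutoff < 1.0:
            raise ValueError(f"cutoff for {base} must be in (0, 1), got {cutoff}")
    max_runs = pd.DataFrame([max_run_lengths(s) for s in seqs])
    out = {}
    n = len(seqs)
    for base, cutoff in cutoffs.items():
        runs = max_runs[base]
        m = 1
        while (runs > m).sum() / n >= cutoff:
            m += 1
        out[base] = m
    return out
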