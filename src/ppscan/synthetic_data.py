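"""Seeded synthetic genomes with planted promoter classes.

The generator emulates the statistical structure the discovery pipeline
assumes: an order-1 Markov background genome, a set of annotated gene starts
on both strands, and a small number of promoter classes, each a noisy
per-column profile around a class consensus, planted upstream of genes and at
intergenic decoy positions. Truth labels for every planted instance make all
downstream stages (filtering, class building, scanning) testable offline.

A class profile is a per-column categorical distribution over bases: column j
emits the class consensus base with probability ``sharpness_j`` and a
background draw otherwise, followed by an independent per-member substitution
noise of rate ``mutation_rate``. Columns in a conserved core just upstream of
the TSS-proxy position (column 501) use a higher sharpness, giving each class
the characteristic conservation peak near the annotated start. Members are
composition-controlled: each is resampled until it passes the four promoter
filters, so clean planted promoters are never rejected downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import FilterParams, failing_rules
from .io_formats import GeneAnnotation, extract_promoters, sequence_transform

_BASES = "ATCG"


@dataclass
class SynthSpec:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the desk-scale recovery benchmark: three classes of
    600/300/150 members planted in a ~1.2 Mb chromosome together with 200
    background genes and 20 intergenic decoys per class, 15% per-member
    substitution noise, and an A/T-rich background (GC ~= 0.33) matching the
    promoter GC filter band.
    """

    chrom_length: int = 1_200_000
    n_chromosomes: int = 1
    composition: tuple[float, float, float, float] = (0.335, 0.335, 0.165, 0.165)
    markov_rho: float = 0.0  # probability of copying the previous base
    class_sizes: tuple[int, ...] = (600, 300, 150)
    n_background_genes: int = 200
    n_decoys_per_class: int = 20
    mutation_rate: float = 0.15
    # Per-class consensus-emission probability outside the core. The graded
    # hierarchy (largest class most conserved) mirrors real promoter classes,
    # whose first, TATA-like class is the best conserved, and keeps each class
    # dominant in its own discovery round.
    sharpness: float | tuple[float, ...] = (0.55, 0.30, 0.19)
    core_sharpness: float = 0.90
    core: tuple[int, int] = (491, 515)  # promoter columns (1..600) of the core
    upstream: int = 500
    downstream: int = 100
    seed: int = 0
    filter_params: FilterParams = field(default_factory=FilterParams)

    @property
    def window(self) -> int:
        return self.upstream + self.downstream

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.chrom_length < self.window:
            raise ValueError("chromosome shorter than the promoter window")
        if not np.isclose(sum(self.composition), 1.0):
            raise ValueError("composition must sum to 1")

    def class_sharpness(self, class_index: int) -> float:
        """Base sharpness of class ``class_index`` (0-based)."""
        if np.isscalar(self.sharpness):
            return float(self.sharpness)
        values = tuple(self.sharpness)
        return float(values[min(class_index, len(values) - 1)])

    def sharpness_profile(self, class_index: int = 0) -> np.ndarray:
        prof = np.full(self.window, self.class_sharpness(class_index))
        lo, hi = self.core
        prof[lo - 1 : hi] = self.core_sharpness
        return prof


@dataclass
class SynthResult:
    genome: dict[str, str]
    genes: list[GeneAnnotation]
    truth: pd.DataFrame  # instance_id, class_id, chrom, start, end, strand, kind, gene_id
    consensus: list[str]  # one per class
    spec: SynthSpec

    def promoter_labels(self) -> dict[str, int]:
        """gene_id -> planted class id (0 for background genes)."""
        rows = self.truth[self.truth["gene_id"] != ""]
        return dict(zip(rows["gene_id"], rows["class_id"]))

    def member_sequences(self) -> tuple[list[str], list[int]]:
        """Promoter windows of all annotated genes plus their truth labels."""
        labels = self.promoter_labels()
        regions = extract_promoters(
            self.genome, self.genes, self.spec.upstream, self.spec.downstream
        )
        return [r.sequence for r in regions], [labels[r.gene_id] for r in regions]


def _markov_background(n: int, spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Order-1 chain: with prob rho copy the previous base, else draw iid."""
    iid = rng.choice(4, size=n, p=spec.composition).astype(np.int8)
    copy = rng.random(n) < spec.markov_rho
    copy[0] = False
    src = np.where(~copy, np.arange(n), 0)
    np.maximum.accumulate(src, out=src)
    return iid[src]


def _draw_consensus(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Consensus with runs capped at 4 and GC held near the band center."""
    comp = np.asarray(spec.composition)
    for _ in range(200):
        cons = np.empty(spec.window, dtype=np.int8)
        run = 0
        for j in range(spec.window):
            b = int(rng.choice(4, p=comp))
            if j > 0 and b == cons[j - 1] and run >= 3:
                others = [x for x in range(4) if x != b]
                w = comp[others] / comp[others].sum()
                b = int(rng.choice(others, p=w))
            run = run + 1 if j > 0 and b == cons[j - 1] else 1
            cons[j] = b
        gc = np.isin(cons, (2, 3)).mean()
        if 0.31 <= gc <= 0.35:
            return cons
    raise RuntimeError("could not draw a composition-controlled consensus")


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def sample_member(
    consensus: np.ndarray,
    spec: SynthSpec,
    rng: np.random.Generator,
    class_index: int = 0,
) -> str:
    """One class member: profile draw + substitution noise, filter-controlled."""
    comp = np.asarray(spec.composition)
    sharp = spec.sharpness_profile(class_index)
    for _ in range(200):
        keep = rng.random(spec.window) < sharp
        bg = rng.choice(4, size=spec.window, p=comp).astype(np.int8)
        member = np.where(keep, consensus, bg)
        mut = rng.random(spec.window) < spec.mutation_rate
        member = np.where(mut, rng.choice(4, size=spec.window, p=comp), member)
        seq = _codes_to_str(member.astype(np.int8))
        if not failing_rules(seq, spec.filter_params):
            return seq
    raise RuntimeError("could not sample a filter-passing member in 200 tries")


def generate(spec: SynthSpec) -> SynthResult:
    """Build the genome, annotation, and truth table for one specification.

    Planted instances (class members as gene promoters, plus intergenic
    decoys) and background genes are interleaved on an even grid of slots
    along each chromosome; an error is raised if the requested instances do
    not fit. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    window = spec.window
    consensus = [_draw_consensus(spec, rng) for _ in spec.class_sizes]

    # one item = (class_id, kind); class 0 = background gene
    items: list[tuple[int, str]] = []
    for cid, size in enumerate(spec.class_sizes, start=1):
        items += [(cid, "promoter")] * size
        items += [(cid, "decoy")] * spec.n_decoys_per_class
    items += [(0, "background")] * spec.n_background_genes
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    per_chrom = int(np.ceil(len(items) / spec.n_chromosomes))
    slot = (spec.chrom_length - 2 * window) // max(per_chrom, 1)
    if slot < window + 60:
        raise ValueError(
            f"infeasible spec: {len(items)} instances do not fit in "
            f"{spec.n_chromosomes} x {spec.chrom_length} nt"
        )

    genome: dict[str, str] = {}
    genes: list[GeneAnnotation] = []
    truth_rows = []
    idx = 0
    for c in range(spec.n_chromosomes):
        name = f"chr{c + 1}"
        seq = _markov_background(spec.chrom_length, spec, rng)
        chunk = items[c * per_chrom : (c + 1) * per_chrom]
        for k, (cid, kind) in enumerate(chunk):
            jitter = int(rng.integers(0, max(slot - window - 20, 1)))
            left = window + k * slot + jitter  # 0-based leftmost of the window
            strand = "+" if rng.random() < 0.5 else "-"
            tss = left + spec.upstream + 1 if strand == "+" else left + spec.downstream
            if cid > 0:
                member = sample_member(consensus[cid - 1], spec, rng, cid - 1)
                planted = (
                    member
                    if strand == "+"
                    else sequence_transform(member, "reverse_complement")
                )
                codes = np.array(
                    [{"A": 0, "T": 1, "C": 2, "G": 3}[b] for b in planted], np.int8
                )
                seq[left : left + window] = codes
            gene_id = ""
            if kind in ("promoter", "background"):
                gene_id = f"g{idx:05d}"
                genes.append(
                    GeneAnnotation(gene_id=gene_id, chrom=name, start=tss, strand=strand)
                )
            truth_rows.append(
                {
                    "instance_id": f"i{idx:05d}",
                    "class_id": cid,
                    "chrom": name,
                    "start": left + 1,
                    "end": left + window,
                    "strand": strand,
                    "kind": kind,
                    "gene_id": gene_id,
                }
            )
            idx += 1
        genome[name] = _codes_to_str(seq)
    truth = pd.DataFrame(truth_rows)
    return SynthResult(
        genome=genome, genes=genes, truth=truth, consensus=[
            _codes_to_str(c) for c in consensus
        ], spec=spec
    )


def write_truth_tsv(truth: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        truth.to_csv(fh, sep="\t", index=False)
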