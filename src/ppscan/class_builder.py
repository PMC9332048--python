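"""Iterative promoter-class construction.

A class is discovered by (1) multiply aligning a random sample of the working
promoter set against a shared pattern — a dinucleotide PWM optimized by a
small genetic algorithm whose individuals are alignment layouts and whose
fitness is the total global-alignment score of the sample against the PWM
rebuilt from the layout — and (2) scoring *every* remaining sequence against
the resulting class PWM with a shuffle-null Z. Sequences with Z above the
membership threshold become the class and leave the pool; the loop repeats
until a candidate class is smaller than the minimum volume.

The GA is deliberately modest: the initial layout is the gapless stack of the
600-nt windows (already column-consistent because all windows are anchored on
the annotated start), and the operators are an EM-like re-alignment of each
sequence to the current PWM, random all-gap column insertion/deletion, and
elitist selection. Alignment length may grow to 600 + 50 columns, matching
the genome-scan window slack.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import DEFAULT_GAP, global_matches, global_score
from .nullstats import z_score_membership
from .pwm_core import (
    GAP,
    PWM,
    FrequencyMatrix,
    base_codes,
    compute_pwm,
    dinucleotide_codes,
    load_pwm,
    normalize_pwm,
    save_pwm,
)

logger = logging.getLogger(__name__)

MAX_L1 = 650  # 600-nt windows + 50 columns of indel slack


@dataclass
class GAParams:
    """Genetic-algorithm settings for the multiple alignment."""

    population: int = 20
    generations: int = 200
    mut_insert: float = 0.30  # per-offspring probability of an all-gap column insert
    mut_delete: float = 0.30
    tol: float = 1e-3
    patience: int = 10
    sample_size: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.population, self.sample_size) < 1 or self.generations < 0:
            raise ValueError("population, sample_size must be positive")


@dataclass
class BuildParams:
    """Iterative classification settings (membership Z > 5, volume >= 100)."""

    membership_z: float = 5.0
    min_class_size: int = 100
    n_shuffles: int = 1000
    gap: float = DEFAULT_GAP
    max_rounds: int = 50
    ga: GAParams = field(default_factory=GAParams)


@dataclass
class ClassModel:
    """A discovered promoter class: its matrices and membership."""

    class_id: int
    l1: int
    freq: FrequencyMatrix
    pwm: PWM
    member_ids: list[str]
    member_z: list[float]
    converged: bool = True

    @property
    def volume(self) -> int:
        return len(self.member_ids)


def _freq_from_matches(
    codes_list: list[np.ndarray],
    matches: list[tuple[np.ndarray, np.ndarray]],
    l1: int,
) -> FrequencyMatrix:
    """Frequency matrix straight from per-sequence match traces.

    A matched pair (t, l) contributes the sequence's actual dinucleotide at
    position t (its real previous base, even across gaps — the same
    convention the DP scores with) to matrix column l.
    """
    counts = np.zeros((16, l1 - 1), dtype=np.float64)
    n_seq = len(codes_list)
    for din, (t_idx, l_idx) in zip(codes_list, matches):
        # base position t (2..window) -> dinucleotide index t-2;
        # matrix column l (2..L1) -> counts column l-2
        s = din[t_idx - 2]
        ok = s >= 0
        np.add.at(counts, (s[ok], l_idx[ok] - 2), 1.0)
    return FrequencyMatrix(counts=counts, l1=l1, n_seq=n_seq)


class _Individual:
    """One alignment layout: per-sequence match traces plus its PWM."""

    __slots__ = ("l1", "matches", "pwm", "fitness")

    def __init__(self, l1, matches, pwm=None, fitness=-np.inf):
        self.l1 = l1
        self.matches = matches
        self.pwm = pwm
        self.fitness = fitness


def _gapless_layout(n_seq: int, window: int) -> list[tuple[np.ndarray, np.ndarray]]:
    t = np.arange(2, window + 1, dtype=np.int64)
    return [(t, t.copy()) for _ in range(n_seq)]


def _evaluate(ind: _Individual, dins: list[np.ndarray]) -> None:
    freq = _freq_from_matches(dins, ind.matches, ind.l1)
    ind.pwm = normalize_pwm(compute_pwm(freq))
    ind.fitness = float(
        sum(global_score(din, ind.pwm.weights, DEFAULT_GAP) for din in dins)
    )


def _realign(ind: _Individual, dins: list[np.ndarray]) -> _Individual:
    """EM step: re-align every sequence to the individual's current PWM."""
    t_buf = np.empty(MAX_L1, dtype=np.int64)
    l_buf = np.empty(MAX_L1, dtype=np.int64)
    matches = []
    for din in dins:
        _, k = global_matches(din, ind.pwm.weights, DEFAULT_GAP, t_buf, l_buf)
        # stored l indices are DP columns (1-based over informative columns);
        # +1 converts to matrix column numbering used by the layout
        matches.append((t_buf[:k] + 1, l_buf[:k] + 1))
    return _Individual(ind.l1, matches)


def _mutate(
    ind: _Individual, params: GAParams, rng: np.random.Generator
) -> _Individual:
    """Insert or delete one alignment column (all-gap insert; hard delete)."""
    l1 = ind.l1
    matches = ind.matches
    if rng.random() < params.mut_insert and l1 < MAX_L1:
        col = int(rng.integers(2, l1 + 1))
        matches = [(t, np.where(l >= col, l + 1, l)) for t, l in matches]
        l1 += 1
    if rng.random() < params.mut_delete and l1 > 600:
        col = int(rng.integers(2, l1 + 1))
        new = []
        for t, l in matches:
            keep = l != col
            new.append((t[keep], np.where(l[keep] > col, l[keep] - 1, l[keep])))
        matches = new
        l1 -= 1
    return _Individual(l1, matches)


def layout_to_alignment(
    codes_list: list[np.ndarray], ind_or_model, l1: int | None = None
) -> np.ndarray:
    """Materialize a layout as a base-code alignment V (GAP = -2).

    For each matched pair (t, l) the base at sequence position t is placed in
    column l; the dinucleotide partner base t-1 is placed at column l-1 when
    that cell is still free, so adjacent matched pairs re-create contiguous
    rows and the first matched base of a segment keeps its real left
    neighbor.
    """
    matches = ind_or_model.matches if isinstance(ind_or_model, _Individual) else ind_or_model
    l1 = l1 or max(int(l.max()) if len(l) else 600 for _, l in matches)
    v = np.full((len(codes_list), l1), GAP, dtype=np.int8)
    for row, (bases, (t_idx, l_idx)) in enumerate(zip(codes_list, matches)):
        v[row, l_idx - 1] = bases[t_idx - 1]
        prev_free = v[row, l_idx - 2] == GAP
        v[row, l_idx[prev_free] - 2] = bases[t_idx[prev_free] - 2]
    return v


def mahds_align(
    seqs: list[str],
    ga_params: GAParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ClassModel]:
    """Multiple alignment of a promoter sample and the candidate class model.

    Returns the alignment as a base-code matrix V (n_seq x L1, GAP marks) and
    a candidate ClassModel (members not yet assigned). Deterministic under a
    seeded generator; if the GA hits its generation cap without the fitness
    stagnating, the best-so-far individual is returned with
    ``converged=False`` and a warning.
    """
    params = ga_params or GAParams()
    rng = rng or np.random.default_rng(params.seed)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all sequences must have equal length")
    window = lengths.pop()
    codes_list = [base_codes(s) for s in seqs]
    dins = [dinucleotide_codes(c) for c in codes_list]

    elite = _Individual(window, _gapless_layout(len(seqs), window))
    _evaluate(elite, dins)
    population = [elite]
    best, stall = elite.fitness, 0
    converged = params.generations == 0
    for _ in range(params.generations):
        offspring = []
        for parent in population:
            child = _mutate(parent, params, rng)
            _evaluate(child, dins)  # PWM of the mutated layout
            child = _realign(child, dins)  # EM step against that PWM
            _evaluate(child, dins)
            offspring.append(child)
        population = sorted(
            population + offspring, key=lambda x: -x.fitness
        )[: params.population]
        if population[0].fitness > best + params.tol:
            best, stall = population[0].fitness, 0
        else:
            stall += 1
            if stall >= params.patience:
                converged = True
                break
    if not converged:
        logger.warning("GA hit the generation cap before fitness stagnated")
    winner = population[0]
    freq = _freq_from_matches(dins, winner.matches, winner.l1)
    model = ClassModel(
        class_id=0,
        l1=winner.l1,
        freq=freq,
        pwm=winner.pwm,
        member_ids=[],
        member_z=[],
        converged=converged,
    )
    return layout_to_alignment(codes_list, winner, winner.l1), model


def build_classes(
    set1: list[str] | dict[str, str],
    params: BuildParams | None = None,
    seed: int | None = None,
) -> list[ClassModel]:
    """Peel promoter classes off Set1 until a candidate is too small.

    Each round samples min(sample_size, |remaining|) sequences, aligns them,
    scores every remaining sequence's Z against the candidate PWM, accepts
    the class if at least ``min_class_size`` sequences exceed the membership
    threshold, removes the members, and repeats. Classes are numbered in
    creation order. All remaining sequences, sampled or not, are eligible
    for membership.
    """
    params = params or BuildParams()
    rng = np.random.default_rng(seed)
    if isinstance(set1, dict):
        ids, seqs = list(set1.keys()), list(set1.values())
    else:
        ids, seqs = [f"seq{i:05d}" for i in range(len(set1))], list(set1)
    remaining = list(range(len(seqs)))
    classes: list[ClassModel] = []
    for _ in range(params.max_rounds):
        if len(remaining) < 2:
            break
        if len(remaining) <= params.ga.sample_size:
            sample = list(remaining)
        else:
            sample = sorted(
                rng.choice(remaining, size=params.ga.sample_size, replace=False)
            )
        _, candidate = mahds_align([seqs[i] for i in sample], params.ga, rng)
        zs = np.empty(len(remaining))
        for k, i in enumerate(remaining):
            zs[k], _ = z_score_membership(
                seqs[i], candidate.pwm, n=params.n_shuffles, gap=params.gap, rng=rng
            )
        member_mask = zs > params.membership_z
        volume = int(member_mask.sum())
        logger.info(
            "round %d: candidate volume %d (remaining %d)",
            len(classes) + 1, volume, len(remaining),
        )
        if volume < params.min_class_size:
            break
        candidate.class_id = len(classes) + 1
        candidate.member_ids = [ids[i] for i, m in zip(remaining, member_mask) if m]
        candidate.member_z = [float(z) for z, m in zip(zs, member_mask) if m]
        classes.append(candidate)
        remaining = [i for i, m in zip(remaining, member_mask) if not m]
    return classes


def random_control_classes(
    set1: list[str],
    params: BuildParams | None = None,
    seed: int | None = None,
) -> dict:
    """Classify shuffled copies of Set1 for one round; report candidate volume.

    Shuffling every sequence destroys any shared pattern, so the candidate
    volume measures the pure noise floor of the procedure (which motivates
    the minimum accepted class volume).
    """
    params = params or BuildParams()
    rng = np.random.default_rng(seed)
    shuffled = []
    for s in set1:
        codes = base_codes(s)
        shuffled.append(rng.permutation(codes))
    seqs = ["".join("ATCGN"[c if c >= 0 else 4] for c in arr) for arr in shuffled]
    rng2 = np.random.default_rng(seed)
    sample_n = min(params.ga.sample_size, len(seqs))
    sample_idx = (
        list(range(len(seqs)))
        if sample_n == len(seqs)
        else sorted(rng2.choice(len(seqs), size=sample_n, replace=False))
    )
    _, candidate = mahds_align([seqs[i] for i in sample_idx], params.ga, rng2)
    zs = np.array(
        [
            z_score_membership(s, candidate.pwm, n=params.n_shuffles, rng=rng2)[0]
            for s in seqs
        ]
    )
    volume = int((zs > params.membership_z).sum())
    return {
        "volume": volume,
        "z_mean": float(zs.mean()),
        "z_sd": float(zs.std(ddof=1)),
        "n": len(seqs),
        "seed": seed,
    }


def save_classes(classes: list[ClassModel], outdir: str | Path, header=None) -> None:
    """Persist each class (PWM TSV + JSON sidecar + members) and a registry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = {}
    for model in classes:
        stem = f"class_{model.class_id}"
        model.pwm.class_id = model.class_id
        save_pwm(model.pwm, outdir / f"{stem}.pwm.tsv", header=header)
        np.savetxt(
            outdir / f"{stem}.freq.tsv", model.freq.counts, fmt="%.0f", delimiter="\t"
        )
        (outdir / f"{stem}.members.json").write_text(
            json.dumps(
                {"member_ids": model.member_ids, "member_z": model.member_z}, indent=1
            )
        )
        registry[model.class_id] = {
            "pwm": f"{stem}.pwm.tsv",
            "freq": f"{stem}.freq.tsv",
            "members": f"{stem}.members.json",
            "volume": model.volume,
            "l1": model.l1,
            "converged": model.converged,
        }
    (outdir / "registry.json").write_text(json.dumps(registry, indent=1))


def load_classes(outdir: str | Path) -> list[ClassModel]:
    outdir = Path(outdir)
    registry_path = outdir / "registry.json"
    if not registry_path.exists():
        raise FileNotFoundError(
            f"no class registry at {registry_path}; run classification first"
        )
    registry = json.loads(registry_path.read_text())
    classes = []
    for cid_str, entry in sorted(registry.items(), key=lambda kv: int(kv[0])):
        pwm = load_pwm(outdir / entry["pwm"])
        counts = np.loadtxt(outdir / entry["freq"], delimiter="\t", ndmin=2)
        members = json.loads((outdir / entry["members"]).read_text())
        classes.append(
            ClassModel(
                class_id=int(cid_str),
                l1=entry["l1"],
                freq=FrequencyMatrix(
                    counts=counts, l1=entry["l1"], n_seq=entry["volume"]
                ),
                pwm=pwm,
                member_ids=members["member_ids"],
                member_z=members["member_z"],
                converged=entry.get("converged", True),
            )
        )
    return classes


def class_model_from_sequences(
    seqs: list[str], class_id: int = 1, ga: GAParams | None = None, seed=None
) -> ClassModel:
    """Convenience: align a fixed member list and package the class model."""
    rng = np.random.default_rng(seed)
    _, model = mahds_align(seqs, ga or GAParams(generations=0), rng)
    model.class_id = class_id
    model.member_ids = [f"seq{i:05d}" for i in range(len(seqs))]
    return model
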