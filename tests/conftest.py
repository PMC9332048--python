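"""Shared fixtures.

Small fixtures are built per module; the full-size recovery benchmark
(three planted classes of 600/300/150 members plus 200 background genes in
a ~1.2 Mb genome) is session-scoped because class building and genome
scanning are the expensive stages. All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppscan.class_builder import BuildParams, GAParams, build_classes
from ppscan.synthetic_data import SynthSpec, generate

BENCH_SEED = 1

#: Reduced GA settings used for the desk-scale benchmark runs.
BENCH_BUILD = BuildParams(
    n_shuffles=40,
    ga=GAParams(population=3, generations=4, patience=2, sample_size=1000),
)


@pytest.fixture(scope="session")
def bench_result():
    """The full-size synthetic benchmark genome (default study conditions)."""
    return generate(SynthSpec(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def bench_set1(bench_result):
    """Promoter windows of all annotated genes, with truth labels."""
    seqs, labels = bench_result.member_sequences()
    return seqs, labels


@pytest.fixture(scope="session")
def bench_classes(bench_set1):
    """Classes recovered by the iterative procedure on the benchmark set."""
    seqs, _ = bench_set1
    return build_classes(seqs, BENCH_BUILD, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def small_synth():
    """A small planted genome for fast module-level checks."""
    return generate(
        SynthSpec(
            chrom_length=150_000,
            class_sizes=(80, 40),
            n_background_genes=20,
            n_decoys_per_class=5,
            seed=5,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
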