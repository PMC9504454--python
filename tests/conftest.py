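import numpy as np
import pytest
from hypothesis import settings

import ctxpred as cp
from ctxpred.neural import ArchitectureSpec, ContextLSTM, TrainingConfig

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_genome():
    """The 8-base toy sequence whose k=1 central contexts are deterministic."""
    return cp.GenomeSequence.from_string("toy", "ACGTACGT")


@pytest.fixture(scope="session")
def order2_chain():
    return cp.default_order2_chain()


@pytest.fixture(scope="session")
def genome_2mb_order2(order2_chain):
    """2 Mb genome from the reference order-2 chain, no GC modulation."""
    spec = cp.SyntheticGenomeSpec(length=2_000_000, order=2,
                                  transition_table=order2_chain.table,
                                  seed=11, name="train2mb")
    genome, chain = cp.generate_genome(spec)
    return genome, chain


@pytest.fixture(scope="session")
def fresh_1mb_order2(order2_chain):
    """An independent 1 Mb genome from the same chain, for held-out scoring."""
    spec = cp.SyntheticGenomeSpec(length=1_000_000, order=2,
                                  transition_table=order2_chain.table,
                                  seed=12, name="fresh1mb")
    genome, _ = cp.generate_genome(spec)
    return genome


@pytest.fixture(scope="session")
def trained_neural(genome_2mb_order2):
    """Tiny conv-biLSTM trained on the 2 Mb order-2 genome (desk scale)."""
    genome, _ = genome_2mb_order2
    arch = ArchitectureSpec.tiny(flank_size=5)
    config = TrainingConfig(sample_fraction=1.0 / 3.0, rounds=8,
                            batches_per_round=300, batch_size=256,
                            validation_size=4096, learning_rate=3e-3, seed=0)
    return ContextLSTM(genome, arch, config).fit()


@pytest.fixture(scope="session")
def planted_1mb():
    """1 Mb genome with a planted 200 bp GC period (frequency 5,000/Mb)."""
    spec = cp.small_genome_spec(seed=3, length=1_000_000)
    genome, chain = cp.generate_genome(spec)
    return genome, chain, spec


def brute_force_central_counts(bases: str, k: int):
    """Independent oracle: per-context focus counts by direct string scanning."""
    counts = {}
    L = len(bases)
    for i in range(k, L - k):
        window = bases[i - k : i + k + 1]
        if "N" in window:
            continue
        ctx = window[:k] + window[k + 1 :]
        counts.setdefault(ctx, {b: 0 for b in "ACGT"})[window[k]] += 1
    return counts


def brute_force_markov_counts(bases: str, k: int):
    counts = {}
    for i in range(k, len(bases)):
        window = bases[i - k : i + 1]
        if "N" in window:
            continue
        counts.setdefault(window[:k], {b: 0 for b in "ACGT"})[window[k]] += 1
    return counts
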