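from __future__ import annotations

import numpy as np
import pytest

from memalign import MEM, MutationProfile, ScoringScheme, generate_pair

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutated_pair(rng: np.random.Generator, length: int, snp: float, indel: float):
    """A (target, query) pair with the given per-base mutation rates."""
    rec = generate_pair(MutationProfile(length, snp, indel, 0.2), rng)
    return rec.target, rec.query


@pytest.fixture
def scoring() -> ScoringScheme:
    """The worked-example scoring scheme: Rm=2, Px=3, Po=4, Pg=1."""
    return ScoringScheme(2, 3, 4, 1)


@pytest.fixture
def table1_mems() -> list[MEM]:
    """The six printed MEM triplets of the worked alignment example,
    EQ-sorted (their natural left-to-right order)."""
    return [
        MEM(4, 1, 1),
        MEM(3, 5, 7),
        MEM(5, 11, 12),
        MEM(5, 18, 19),
        MEM(4, 25, 24),
        MEM(5, 31, 31),
    ]


def random_mem_instance(
    rng: np.random.Generator, n_max: int = 10, span: int = 30
) -> tuple[list[MEM], int, int]:
    """A random EQ-sorted MEM list plus nominal sequence lengths."""
    n = int(rng.integers(1, n_max + 1))
    mems = []
    for _ in range(n):
        length = int(rng.integers(1, 9))
        st = int(rng.integers(1, span - length + 2))
        sq = int(rng.integers(1, span - length + 2))
        mems.append(MEM(length, st, sq))
    mems.sort(key=lambda m: (m.query_end, m.diagonal, m.target_start))
    return mems, span, span
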