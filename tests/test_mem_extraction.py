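"""MEM enumeration: banded extraction, filtering, sorting, brute force."""

from __future__ import annotations

import numpy as np
import pytest

from memalign import (
    MEM,
    brute_force_mems,
    counting_sort_by_query_end,
    extract_mems,
)

from conftest import random_dna


def test_identical_sequences_main_diagonal():
    assert extract_mems("AAAA", "AAAA", gl=0) == [MEM(4, 1, 1)]


def test_example_pair_band_zero(scoring):
    # one SNP at position 4 splits the main diagonal into two MEMs
    assert extract_mems("ACGTACGT", "ACGAACGT", gl=0) == [
        MEM(3, 1, 1),
        MEM(4, 5, 5),
    ]


def test_full_band_matches_brute_force_bulk():
    rng = np.random.default_rng(21)
    for _ in range(300):
        t = random_dna(rng, int(rng.integers(1, 51)))
        q = random_dna(rng, int(rng.integers(1, 51)))
        assert set(extract_mems(t, q)) == brute_force_mems(t, q)


def test_mem_invariants_from_extraction():
    rng = np.random.default_rng(22)
    for _ in range(100):
        t = random_dna(rng, 40)
        q = random_dna(rng, 35)
        for m in extract_mems(t, q):
            assert 1 <= m.target_start <= m.target_end <= len(t)
            assert 1 <= m.query_start <= m.query_end <= len(q)
            assert (
                t[m.target_start - 1 : m.target_end]
                == q[m.query_start - 1 : m.query_end]
            )
            # maximality on both sides
            i, j = m.target_start - 2, m.query_start - 2
            assert i < 0 or j < 0 or t[i] != q[j]
            i, j = m.target_end, m.query_end
            assert i >= len(t) or j >= len(q) or t[i] != q[j]


def test_filter_consistency():
    rng = np.random.default_rng(23)
    for _ in range(100):
        t, q = random_dna(rng, 40), random_dna(rng, 40)
        full = extract_mems(t, q, gl=4, sl=1)
        for k in (2, 3, 5):
            assert extract_mems(t, q, gl=4, sl=k) == [m for m in full if m.length >= k]


def test_band_consistency():
    rng = np.random.default_rng(24)
    for _ in range(100):
        t = random_dna(rng, 40)
        q = random_dna(rng, int(rng.integers(20, 41)))
        full = extract_mems(t, q)
        shift = len(t) - len(q)
        for gl in (0, 2, 5):
            lo = min(0, shift) - gl
            hi = max(0, shift) + gl
            expect = [m for m in full if lo <= m.diagonal <= hi]
            assert extract_mems(t, q, gl=gl) == expect


def test_output_sorted_by_query_end():
    rng = np.random.default_rng(25)
    for _ in range(50):
        t, q = random_dna(rng, 40), random_dna(rng, 40)
        mems = extract_mems(t, q)
        assert all(a.query_end <= b.query_end for a, b in zip(mems, mems[1:]))


def test_empty_sequence_error():
    with pytest.raises(ValueError, match="query"):
        extract_mems("ACGT", "")
    with pytest.raises(ValueError, match="target"):
        extract_mems("", "ACGT")


def test_counting_sort_examples():
    assert counting_sort_by_query_end([], 10) == []
    mems = [MEM(3, 1, 7), MEM(2, 5, 3), MEM(4, 2, 13)]  # EQ 9, 4, 16
    assert [m.query_end for m in counting_sort_by_query_end(mems, 16)] == [4, 9, 16]


def test_counting_sort_against_comparison_sort():
    rng = np.random.default_rng(26)
    for _ in range(200):
        n = int(rng.integers(0, 40))
        mems = [
            MEM(int(rng.integers(1, 6)), int(rng.integers(1, 30)), int(rng.integers(1, 30)))
            for _ in range(n)
        ]
        out = counting_sort_by_query_end(mems, 40)
        assert sorted(out, key=lambda m: m.query_end) == sorted(
            mems, key=lambda m: m.query_end
        )
        # permutation: multiset preserved, and stable on equal EQ
        assert len(out) == len(mems)
        from collections import Counter

        assert Counter(out) == Counter(mems)
        by_eq = {}
        for m in mems:
            by_eq.setdefault(m.query_end, []).append(m)
        for eq, group in by_eq.items():
            assert [m for m in out if m.query_end == eq] == group


def test_counting_sort_range_error():
    with pytest.raises(ValueError):
        counting_sort_by_query_end([MEM(3, 1, 8)], 5)


def test_brute_force_identical_repeats():
    mems = brute_force_mems("AAAA", "AAAA")
    lengths = sorted(m.length for m in mems)
    assert lengths == [1, 1, 2, 2, 3, 3, 4]  # one MEM per diagonal


def test_brute_force_reversed_alphabet():
    mems = brute_force_mems("ACGT", "TGCA")
    assert mems == {MEM(1, 1, 4), MEM(1, 2, 3), MEM(1, 3, 2), MEM(1, 4, 1)}
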