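"""Chaining DP: junction arithmetic, overlap exclusion, scoring, CIGARs."""

from __future__ import annotations

import numpy as np
import pytest

from memalign import (
    MEM,
    AlignmentStats,
    ScoringScheme,
    dp_align,
    emit_cigar,
    eq1_score,
    extract_mems,
    inter_mem_penalty,
    overlap_length,
    sw_global,
    sw_local,
)

from conftest import mutated_pair, random_mem_instance
from oracles import best_chain_by_enumeration


def test_eq1_two_gaps_example(scoring):
    # two continuous gaps of lengths 3 and 4: two openings, seven gapped symbols
    stats = AlignmentStats(matches=0, mismatches=0, gap_opens=2, gap_length=7)
    assert eq1_score(stats, scoring) == -(2 * 4 + 7 * 1)


def test_eq1_zero_stats(scoring):
    assert eq1_score(AlignmentStats(), scoring) == 0


def test_eq1_worked_alignment_counts(scoring):
    # counts of the full six-MEM worked alignment: 26 matches, 6 mismatches,
    # 4 gap openings, 6 gapped symbols
    assert eq1_score(AlignmentStats(26, 6, 4, 6), scoring) == 12


@pytest.mark.parametrize(
    "mi, mj, expected",
    [
        (MEM(4, 1, 1), MEM(5, 11, 12), -6),  # far apart: no overlap
        (MEM(5, 1, 1), MEM(5, 4, 4), 2),
        (MEM(5, 3, 3), MEM(5, 3, 3), 5),  # identical: full overlap
    ],
)
def test_overlap_length(mi, mj, expected):
    assert overlap_length(mi, mj) == expected


@pytest.mark.parametrize(
    "i, j, lt, lq, nx, ng, kind",
    [
        (0, 1, 0, 2, 0, 2, "insertion"),  # M1 -> M2
        (1, 2, 3, 2, 2, 1, "deletion"),  # M2 -> M3
        (2, 3, 2, 2, 2, 0, "none"),  # M3 -> M4
        (3, 4, 2, 0, 0, 2, "deletion"),  # M4 -> M5
        (4, 5, 2, 3, 2, 1, "insertion"),  # M5 -> M6
    ],
)
def test_junction_table_rows(table1_mems, scoring, i, j, lt, lq, nx, ng, kind):
    gap = inter_mem_penalty(table1_mems[i], table1_mems[j], scoring)
    assert (gap.lt, gap.lq) == (lt, lq)
    assert (gap.mismatches, gap.gap_length, gap.gap_kind) == (nx, ng, kind)


def test_junction_penalty_insertion(table1_mems, scoring):
    gap = inter_mem_penalty(table1_mems[0], table1_mems[1], scoring)
    assert gap.penalty == scoring.gap_open_penalty + 2 * scoring.gap_extend_penalty


def test_junction_abutting_mems(scoring):
    gap = inter_mem_penalty(MEM(3, 1, 1), MEM(3, 4, 4), scoring)
    assert gap.penalty == 0 and gap.gap_kind == "none" and gap.mismatches == 0


def test_junction_precondition_error(scoring):
    with pytest.raises(ValueError):
        inter_mem_penalty(MEM(5, 1, 1), MEM(5, 4, 4), scoring)


def test_single_mem_chain(scoring):
    res = dp_align([MEM(7, 3, 3)], scoring, "A" * 12, "A" * 12)
    assert res.score == 7 * scoring.match_reward
    assert res.chain == (MEM(7, 3, 3),)
    assert list(res.table.backtrack) == [-1]


def test_worked_example_chain(table1_mems, scoring):
    """The six printed MEMs chain to score 16 through the third, fourth and
    fifth MEM — confirmed here against subset enumeration."""
    best, idx = best_chain_by_enumeration(table1_mems, scoring, 35, 35, "local")
    assert (best, idx) == (16, (2, 3, 4))
    res = dp_align(table1_mems, scoring, "N" * 35, "N" * 35)
    assert res.score == 16
    assert res.chain_indices == (2, 3, 4)
    assert res.chain == (MEM(5, 11, 12), MEM(5, 18, 19), MEM(4, 25, 24))


def test_dp_matches_subset_enumeration(scoring):
    rng = np.random.default_rng(31)
    for mode in ("local", "global"):
        for _ in range(250):
            mems, tlen, qlen = random_mem_instance(rng)
            expect, _ = best_chain_by_enumeration(mems, scoring, tlen, qlen, mode)
            res = dp_align(mems, scoring, "N" * tlen, "N" * qlen, mode=mode)
            assert res.score == expect, (mode, mems)


def test_empty_mem_list(scoring):
    res = dp_align([], scoring, "ACGT", "ACGT")
    assert res.score == 0 and res.chain == () and res.no_mem


def test_unsorted_input_error(scoring):
    mems = [MEM(3, 10, 10), MEM(3, 1, 1)]
    with pytest.raises(ValueError, match="sorted"):
        dp_align(mems, scoring, "A" * 15, "A" * 15)


def test_deterministic_output(scoring):
    rng = np.random.default_rng(32)
    mems, tlen, qlen = random_mem_instance(rng, n_max=8)
    a = dp_align(mems, scoring, "N" * tlen, "N" * qlen)
    b = dp_align(mems, scoring, "N" * tlen, "N" * qlen)
    assert a.score == b.score and a.chain == b.chain and a.cigar == b.cigar


def test_filtered_path_is_noop(scoring):
    """A predecessor filter that skips nothing reproduces the default path
    exactly (the pruning-strategy equivalence contract)."""
    rng = np.random.default_rng(33)
    for _ in range(50):
        t, q = mutated_pair(rng, 30, 0.08, 0.02)
        for sl in (1, 4):
            mems = extract_mems(t, q, gl=5, sl=sl)
            if not mems:
                continue
            a = dp_align(mems, scoring, t, q, sl=sl, td=20)
            b = dp_align(
                mems, scoring, t, q, sl=sl, td=20,
                predecessor_filter=lambda j, i, S: False,
            )
            assert (a.score, a.chain, a.cigar) == (b.score, b.chain, b.cigar)


def test_td_unlimited_equivalence(scoring):
    rng = np.random.default_rng(34)
    for _ in range(100):
        t, q = mutated_pair(rng, 30, 0.1, 0.02)
        mems = extract_mems(t, q)
        a = dp_align(mems, scoring, t, q, td=None)
        b = dp_align(mems, scoring, t, q, td=60)  # >= max sequence length
        assert a.score == b.score and a.chain == b.chain


def test_score_upper_bounded_by_gotoh(scoring):
    rng = np.random.default_rng(35)
    for _ in range(200):
        t, q = mutated_pair(rng, 25, 0.1, 0.03)
        for sl, gl in ((1, None), (4, 6)):
            mems = extract_mems(t, q, gl=gl, sl=sl)
            if mems:
                res = dp_align(mems, scoring, t, q, sl=sl)
                assert res.score <= sw_local(t, q, scoring)
            gmems = extract_mems(t, q, gl=gl, sl=sl)
            if gmems:
                res = dp_align(gmems, scoring, t, q, mode="global", sl=sl)
                assert res.score <= sw_global(t, q, scoring)


def test_local_mode_matches_gotoh_with_complete_mems(scoring):
    rng = np.random.default_rng(36)
    for _ in range(300):
        t, q = mutated_pair(rng, 28, 0.08, 0.02)
        mems = extract_mems(t, q)  # full band, sl=1
        res = dp_align(mems, scoring, t, q)
        assert res.score == sw_local(t, q, scoring), (t, q)


def test_chain_monotone_after_exclusion(scoring):
    rng = np.random.default_rng(37)
    for _ in range(100):
        t, q = mutated_pair(rng, 30, 0.1, 0.03)
        mems = extract_mems(t, q)
        if not mems:
            continue
        res = dp_align(mems, scoring, t, q)
        for a, b in zip(res.chain, res.chain[1:]):
            assert a.target_start < b.target_start
            assert a.query_start < b.query_start
            assert a.target_end < b.target_end
            assert a.query_end < b.query_end


def test_cigar_single_full_mem(scoring):
    res = dp_align([MEM(6, 1, 1)], scoring, "ACGTAC", "ACGTAC")
    assert res.cigar == "6M"


def test_cigar_insertion_junction(scoring):
    # two MEMs with LT=0, LQ=2: mismatch-free junction with a 2-insertion
    chain = [MEM(4, 1, 1), MEM(4, 5, 7)]
    gap = inter_mem_penalty(chain[0], chain[1], scoring)
    cigar = emit_cigar(chain, [gap], 8, 10, "local")
    assert cigar == "4M2I4M"


def test_cigar_conservation(scoring):
    rng = np.random.default_rng(38)
    import re

    for _ in range(100):
        t, q = mutated_pair(rng, 30, 0.1, 0.03)
        for mode in ("local", "global"):
            for sl in (1, 3):
                mems = extract_mems(t, q, sl=sl)
                if not mems:
                    continue
                res = dp_align(mems, scoring, t, q, mode=mode, sl=sl)
                ops = re.findall(r"(\d+)([MIDS])", res.cigar)
                q_used = sum(int(n) for n, op in ops if op in "MIS")
                assert q_used == len(q)
                if mode == "global":
                    t_used = sum(int(n) for n, op in ops if op in "MD")
                    assert t_used == len(t)
                    assert "S" not in res.cigar
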