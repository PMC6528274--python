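"""Affine-gap Smith-Waterman / Needleman-Wunsch (Gotoh) aligner.

Three-state quadratic dynamic programme over the full (|T|+1) x (|Q|+1)
lattice: a match/mismatch state H and two gap states, one per sequence.
Opening a gap costs Po + Pg, extending it Pg, so a gap of length g costs
Po + g*Pg, matching the affine-gap score model of the chaining stage.
Mismatches carry a flat penalty (no substitution matrix).

This module is the hybrid fallback and the gold-standard oracle that the
MEM-chaining path is measured against.  The score-only path is JIT-compiled
and is the hot path; traceback (for CIGARs) walks the filled matrices on
request.
"""

from __future__ import annotations

import numpy as np

from .chain_dp import AlignmentStats, ScoringScheme, _seq_codes

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

_NEG = np.int64(-(1 << 60))


def _gotoh_fill(tc, qc, rm, px, po, pg, local):
    n = tc.shape[0]
    m = qc.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap consuming query
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap consuming target
    if not local:
        for j in range(1, m + 1):
            E[0, j] = -(po + j * pg)
            H[0, j] = E[0, j]
        for i in range(1, n + 1):
            F[i, 0] = -(po + i * pg)
            H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - po - pg
            e2 = E[i, j - 1] - pg
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - po - pg
            f2 = F[i - 1, j] - pg
            if f2 > f:
                f = f2
            F[i, j] = f
            if tc[i - 1] == qc[j - 1]:
                h = H[i - 1, j - 1] + rm
            else:
                h = H[i - 1, j - 1] - px
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


if _njit is not None:
    _gotoh_fill = _njit(cache=True)(_gotoh_fill)


def _fill(target: str, query: str, scoring: ScoringScheme, local: bool):
    return _gotoh_fill(
        _seq_codes(target, -1),
        _seq_codes(query, -2),
        np.int64(scoring.match_reward),
        np.int64(scoring.mismatch_penalty),
        np.int64(scoring.gap_open_penalty),
        np.int64(scoring.gap_extend_penalty),
        local,
    )


def sw_local(target: str, query: str, scoring: ScoringScheme) -> int:
    """Optimal local affine-gap alignment score (always >= 0)."""
    if not target or not query:
        return 0
    H, _, _ = _fill(target, query, scoring, True)
    return int(H.max())


def sw_global(target: str, query: str, scoring: ScoringScheme) -> int:
    """Optimal global (end-to-end) affine-gap alignment score."""
    if not target and not query:
        return 0
    if not target or not query:
        gap = len(target) or len(query)
        return -(scoring.gap_open_penalty + gap * scoring.gap_extend_penalty)
    H, _, _ = _fill(target, query, scoring, False)
    return int(H[-1, -1])


def sw_align(
    target: str, query: str, scoring: ScoringScheme, mode: str = "local"
) -> tuple[int, str, AlignmentStats, int, int]:
    """Score plus CIGAR and stats via traceback.

    Returns (score, cigar, stats, target_start, query_start) with 1-based
    starts of the aligned window.  Traceback ties prefer the diagonal, then
    the query-consuming gap state, deterministically.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    local = mode == "local"
    n, m = len(target), len(query)
    if not target or not query:
        if local:
            cigar = f"{m}S" if m else ""
            return 0, cigar, AlignmentStats(), 0, 0
        stats = AlignmentStats(gap_opens=1 if n + m else 0, gap_length=n + m)
        cigar = (f"{n}D" if n else "") + (f"{m}I" if m else "")
        return sw_global(target, query, scoring), cigar, stats, 1 if n else 0, 1 if m else 0
    H, E, F = _fill(target, query, scoring, local)
    rm, px = scoring.match_reward, scoring.mismatch_penalty
    po, pg = scoring.gap_open_penalty, scoring.gap_extend_penalty
    tc = _seq_codes(target, -1)
    qc = _seq_codes(query, -2)
    if local:
        flat = int(np.argmax(H))
        i, j = divmod(flat, m + 1)
        score = int(H[i, j])
    else:
        i, j = n, m
        score = int(H[i, j])
    end_i, end_j = i, j
    rev_ops: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if local and H[i, j] == 0:
                break
            if not local and i == 0 and j == 0:
                break
            if (
                i > 0
                and j > 0
                and H[i, j]
                == H[i - 1, j - 1] + (rm if tc[i - 1] == qc[j - 1] else -px)
            ):
                rev_ops.append("M")
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - matrices are self-consistent
                raise AssertionError("traceback dead end")
        elif state == "E":
            rev_ops.append("I")
            opened = H[i, j - 1] - po - pg == E[i, j]
            j -= 1
            if opened:
                state = "H"
        else:  # state == "F"
            rev_ops.append("D")
            opened = H[i - 1, j] - po - pg == F[i, j]
            i -= 1
            if opened:
                state = "H"
    t_start, q_start = i + 1, j + 1
    ops: list[tuple[str, int]] = []
    if local and j > 0:
        ops.append(("S", j))
    ti, qi = i, j
    stats = AlignmentStats()
    for op in reversed(rev_ops):
        if op == "M":
            if tc[ti] == qc[qi]:
                stats.matches += 1
            else:
                stats.mismatches += 1
            ti += 1
            qi += 1
        elif op == "I":
            stats.gap_length += 1
            qi += 1
        else:
            stats.gap_length += 1
            ti += 1
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    # gap openings = number of I/D runs
    stats.gap_opens = sum(1 for op, _ in ops if op in "ID")
    if local and end_j < m:
        ops.append(("S", m - end_j))
    cigar = "".join(f"{count}{op}" for op, count in ops)
    return score, cigar, stats, t_start, q_start
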