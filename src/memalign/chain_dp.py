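"""MEM-chaining dynamic programming under affine-gap scoring (DP-MEM).

Given the MEMs of a sequence pair sorted by query end, the DP selects the
chain of MEMs maximising the affine-gap alignment score

    AS = Nm*Rm - (Nx*Px + No*Po + Ng*Pg)

where junction costs between adjacent chain members are derived purely from
MEM coordinates: with LT and LQ symbols between the two MEMs in target and
query, the junction charges min(LT, LQ) mismatches and one continuous gap
of length |LT - LQ| (a single gap opening).  This assumes no matching
symbol survives between adjacent chain MEMs, which is exact when the
complete MEM set is supplied: any surviving match is itself a MEM and the
optimal chain would pass through it.

When short MEMs have been filtered out (sl > 1) that assumption can fail,
so a compensation scan re-examines each junction region under the two
extreme gap placements (all gap left / all gap right), counts matches
sequentially, and converts the best count from mismatches back to matches.

Overlapping adjacent MEMs are handled by trimming the start of the later
MEM by the overlap length before the junction is measured.  Local mode
leaves both ends of both sequences uncharged; global mode charges leading
and trailing regions with the same junction formula extended to the
sequence boundaries.

All MEM coordinates are 1-based inclusive; scores are exact integers for
integer scoring parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mem_extraction import MEM

try:  # JIT the hot Phi-2 loop when numba is importable
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    _njit = None

_ACGT = frozenset("ACGT")

_CODE_LUT = np.full(256, -9, dtype=np.int8)
for _i, _b in enumerate("ACTG"):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def _seq_codes(seq: str, sentinel: int) -> np.ndarray:
    """Sequence as int8 codes; non-ACGT become ``sentinel`` (< 0)."""
    arr = _CODE_LUT[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)].copy()
    arr[arr == -9] = sentinel
    return arr


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters (all non-negative magnitudes).

    ``match_reward`` is added per match; the penalties are subtracted: one
    ``gap_open_penalty`` per continuous gap plus ``gap_extend_penalty`` per
    gapped symbol, and ``mismatch_penalty`` per mismatch (flat, no
    substitution matrix).
    """

    match_reward: int = 2
    mismatch_penalty: int = 3
    gap_open_penalty: int = 4
    gap_extend_penalty: int = 1

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match reward must be > 0")
        if min(self.mismatch_penalty, self.gap_open_penalty, self.gap_extend_penalty) < 0:
            raise ValueError("penalties must be >= 0")


@dataclass
class AlignmentStats:
    """Counts feeding the affine-gap score: matches, mismatches, gap
    openings and total gapped symbols."""

    matches: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    gap_length: int = 0

    def __post_init__(self) -> None:
        if min(self.matches, self.mismatches, self.gap_opens, self.gap_length) < 0:
            raise ValueError("alignment counts must be >= 0")
        if self.gap_opens > self.gap_length:
            raise ValueError("more gap openings than gapped symbols")


def eq1_score(stats: AlignmentStats, scoring: ScoringScheme) -> int:
    """Affine-gap alignment score of a set of alignment counts."""
    return stats.matches * scoring.match_reward - (
        stats.mismatches * scoring.mismatch_penalty
        + stats.gap_opens * scoring.gap_open_penalty
        + stats.gap_length * scoring.gap_extend_penalty
    )


def overlap_length(mi: MEM, mj: MEM) -> int:
    """Overlap between an earlier MEM ``mi`` and a later MEM ``mj``.

    The overlap is the larger of the target-side and query-side overlaps;
    a value <= 0 means the MEMs are disjoint in both sequences.
    """
    return max(
        mi.target_end - mj.target_start + 1,
        mi.query_end - mj.query_start + 1,
    )


@dataclass(frozen=True)
class InterMemGap:
    """Junction between two adjacent chain MEMs.

    ``lt``/``lq`` are the symbol counts separating the MEMs in target and
    query; the junction charges ``mismatches = min(lt, lq)`` mismatches and
    a single continuous gap of ``gap_length = |lt - lq|`` symbols.
    ``recovered_matches`` counts mismatch positions converted back to
    matches by the compensation scan; ``penalty`` is the net score
    contribution subtracted at this junction (it may be negative when
    compensation recovers matches).
    """

    lt: int
    lq: int
    mismatches: int
    gap_length: int
    gap_kind: str  # "insertion" | "deletion" | "none"
    overlap: int
    recovered_matches: int
    penalty: int


def _end_region_penalty(lt: int, lq: int, scoring: ScoringScheme) -> int:
    """Junction formula applied to a free sequence-end region (global mode)."""
    w = min(lt, lq)
    ng = abs(lt - lq)
    pen = w * scoring.mismatch_penalty
    if ng > 0:
        pen += scoring.gap_open_penalty + ng * scoring.gap_extend_penalty
    return pen


def _compensation_matches(
    target: str, query: str, mi: MEM, mj: MEM, lt: int, lq: int
) -> int:
    """Best sequential match count over the two extreme gap placements.

    The inter-MEM region is aligned twice — single gap flushed right
    (regions aligned from their left ends) and flushed left (aligned from
    their right ends) — and the larger match count is returned.
    """
    t0 = mi.target_end  # 0-based index of first region symbol in target
    q0 = mi.query_end
    tr = target[t0 : t0 + lt].upper()
    qr = query[q0 : q0 + lq].upper()
    w = min(lt, lq)
    left = sum(
        1 for k in range(w) if tr[k] == qr[k] and tr[k] in _ACGT
    )
    right = sum(
        1
        for k in range(w)
        if tr[lt - w + k] == qr[lq - w + k] and tr[lt - w + k] in _ACGT
    )
    return max(left, right)


def inter_mem_penalty(
    mi: MEM,
    mj: MEM,
    scoring: ScoringScheme,
    target: str | None = None,
    query: str | None = None,
    sl: int = 1,
) -> InterMemGap:
    """Mismatch/gap accounting for the region between adjacent chain MEMs.

    ``mj`` must start strictly after ``mi`` in both sequences (overlap
    already excluded).  With ``sl > 1`` and both sequences supplied, the
    compensation scan may convert junction mismatches back into matches.
    """
    lt = mj.target_start - mi.target_end - 1
    lq = mj.query_start - mi.query_end - 1
    if lt < 0 or lq < 0:
        raise ValueError(
            f"MEMs overlap or are out of order: {mi} -> {mj} (LT={lt}, LQ={lq});"
            " exclude overlap first"
        )
    nx = min(lt, lq)
    ng = abs(lt - lq)
    if ng == 0:
        kind = "none"
    elif lt < lq:
        kind = "insertion"
    else:
        kind = "deletion"
    penalty = nx * scoring.mismatch_penalty
    if ng > 0:
        penalty += scoring.gap_open_penalty + ng * scoring.gap_extend_penalty
    recovered = 0
    if sl > 1 and nx > 0 and target is not None and query is not None:
        recovered = _compensation_matches(target, query, mi, mj, lt, lq)
        penalty -= recovered * (scoring.mismatch_penalty + scoring.match_reward)
    return InterMemGap(lt, lq, nx, ng, kind, overlap_length(mi, mj), recovered, penalty)


@dataclass
class ChainTable:
    """DP state: best score per MEM, backtrack indices, best end index."""

    scores: np.ndarray
    backtrack: np.ndarray
    best_end: int
    extension_count: int = 0
    skipped_count: int = 0


@dataclass(frozen=True)
class ChainResult:
    """Outcome of aligning one pair: score, chosen chain and bookkeeping.

    ``chain`` holds the selected MEMs left-to-right with overlaps already
    trimmed; ``junctions`` the inter-MEM accounting between them.  ``stats``
    is recomputed from the chain and reproduces ``score`` exactly (over the
    spanned window in local mode).  ``method`` distinguishes chain-based
    alignment from a Smith-Waterman fallback.
    """

    score: int
    chain: tuple[MEM, ...]
    chain_indices: tuple[int, ...]
    junctions: tuple[InterMemGap, ...]
    stats: AlignmentStats
    cigar: str
    mode: str
    target_start: int
    query_start: int
    method: str = "memalign"
    fallback_reason: str | None = None
    table: ChainTable | None = field(default=None, repr=False, compare=False)

    @property
    def no_mem(self) -> bool:
        return not self.chain and self.method == "memalign"


# ---------------------------------------------------------------------------
# Phi-2 core loop.  Written once in plain Python; JIT-compiled at import for
# the default (unfiltered) path.  int64 throughout; td < 0 means unlimited.
# ---------------------------------------------------------------------------


def _chain_core(L, ST, SQ, rm, px, po, pg, td, glob, comp, tc, qc, tlen, qlen):
    n = L.shape[0]
    ET = ST + L - 1
    EQ = SQ + L - 1
    S = np.empty(n, dtype=np.int64)
    W = np.full(n, -1, dtype=np.int64)
    extensions = 0
    skipped = 0
    for j in range(n):
        s0 = L[j] * rm
        if glob:
            lt0 = ST[j] - 1
            lq0 = SQ[j] - 1
            w0 = min(lt0, lq0)
            ng0 = abs(lt0 - lq0)
            pen = w0 * px
            if ng0 > 0:
                pen += po + ng0 * pg
            if comp and w0 > 0:
                # recover matches in the leading region under the two
                # extreme gap placements (gap at outer / inner end)
                left = 0
                right = 0
                for k in range(w0):
                    if tc[k] == qc[k]:
                        left += 1
                    if tc[lt0 - w0 + k] == qc[lq0 - w0 + k]:
                        right += 1
                m = max(left, right)
                pen -= m * (px + rm)
            s0 -= pen
        elif comp:
            # free leading end: recover matches from filtered short MEMs
            s0 += _end_bonus(
                tc, qc, ST[j] - 1, SQ[j] - 1, -1, ST[j] - 1, SQ[j] - 1,
                rm, px, po, pg,
            )
        S[j] = s0
    for j in range(n):
        for i in range(j):
            if (
                ET[i] > ET[j]
                or EQ[i] == EQ[j]
                or ET[i] == ET[j]
                or SQ[i] >= SQ[j]
                or ST[i] >= ST[j]
            ):
                continue
            mo = max(ET[i] - ST[j] + 1, EQ[i] - SQ[j] + 1)
            if mo < 0:
                mo = 0
            lj = L[j] - mo
            if lj < 1:
                continue
            stj = ST[j] + mo
            sqj = SQ[j] + mo
            lt = stj - ET[i] - 1
            lq = sqj - EQ[i] - 1
            if td >= 0 and max(lt, lq) > td:
                skipped += 1
                continue
            w = min(lt, lq)
            ng = lt - lq
            if ng < 0:
                ng = -ng
            pen = w * px
            if ng > 0:
                pen += po + ng * pg
            if comp and w > 0:
                t0 = ET[i]
                q0 = EQ[i]
                left = 0
                right = 0
                for k in range(w):
                    if tc[t0 + k] == qc[q0 + k]:
                        left += 1
                    if tc[t0 + lt - w + k] == qc[q0 + lq - w + k]:
                        right += 1
                m = max(left, right)
                pen -= m * (px + rm)
            s = S[i] + lj * rm - pen
            extensions += 1
            if s > S[j]:
                S[j] = s
                W[j] = i
    best = np.int64(-(1 << 62))
    e = -1
    for j in range(n):
        s = S[j]
        if glob:
            lt = tlen - ET[j]
            lq = qlen - EQ[j]
            w = min(lt, lq)
            ng = abs(lt - lq)
            pen = w * px
            if ng > 0:
                pen += po + ng * pg
            if comp and w > 0:
                t0 = ET[j]
                q0 = EQ[j]
                left = 0
                right = 0
                for k in range(w):
                    if tc[t0 + k] == qc[q0 + k]:
                        left += 1
                    if tc[t0 + lt - w + k] == qc[q0 + lq - w + k]:
                        right += 1
                m = max(left, right)
                pen -= m * (px + rm)
            s -= pen
        elif comp:
            # free trailing end: recover matches from filtered short MEMs
            s += _end_bonus(
                tc, qc, ET[j] - 1, EQ[j] - 1, 1, tlen - ET[j], qlen - EQ[j],
                rm, px, po, pg,
            )
        if s > best:
            best = s
            e = j
    return S, W, e, best, extensions, skipped


def _end_bonus(tc, qc, t0, q0, step, lt, lq, rm, px, po, pg):
    """Best score recoverable beyond a free chain end in local mode.

    Models the terminal region like a junction: at most one continuous
    gap, here placed adjacent to the chain end (a gap at the outer end is
    equivalent to clipping).  Scans outward from the 0-based boundary
    symbol (t0, q0) in direction ``step`` over regions of ``lt`` target
    and ``lq`` query symbols, maximising the cumulative score of an
    ungapped run after an optional gap of g symbols on either side.
    Always >= 0 (clipping everything is free).
    """
    bonus = 0
    lim = lt if lt < lq else lq
    cum = 0
    for k in range(1, lim + 1):
        if tc[t0 + step * k] == qc[q0 + step * k]:
            cum += rm
        else:
            cum -= px
        if cum > bonus:
            bonus = cum
    for g in range(1, lt):  # gap consuming target symbols (deletion)
        lim = lt - g if lt - g < lq else lq
        if lim < 1 or rm * lim <= po + g * pg + bonus:
            break  # larger g only shrinks lim and raises the gap cost
        cum = 0
        run = 0
        for k in range(1, lim + 1):
            if tc[t0 + step * (g + k)] == qc[q0 + step * k]:
                cum += rm
            else:
                cum -= px
            if cum > run:
                run = cum
        if run - po - g * pg > bonus:
            bonus = run - po - g * pg
    for g in range(1, lq):  # gap consuming query symbols (insertion)
        lim = lq - g if lq - g < lt else lt
        if lim < 1 or rm * lim <= po + g * pg + bonus:
            break
        cum = 0
        run = 0
        for k in range(1, lim + 1):
            if tc[t0 + step * k] == qc[q0 + step * (g + k)]:
                cum += rm
            else:
                cum -= px
            if cum > run:
                run = cum
        if run - po - g * pg > bonus:
            bonus = run - po - g * pg
    return bonus


_end_bonus_py = _end_bonus

if _njit is not None:
    _end_bonus = _njit(cache=True)(_end_bonus)
    _chain_core_jit = _njit(cache=True)(_chain_core)
else:  # pragma: no cover
    _chain_core_jit = _chain_core


@dataclass(frozen=True)
class EndExtension:
    """Detailed form of a free-end recovery: an optional gap adjacent to
    the chain end (``gap_op`` D/I, length ``gap_len``) followed by an
    ungapped run of ``length`` columns with the given match/mismatch
    split.  ``bonus`` is its net score contribution (>= 0)."""

    bonus: int = 0
    gap_op: str | None = None
    gap_len: int = 0
    length: int = 0
    matches: int = 0
    mismatches: int = 0

    @property
    def t_consumed(self) -> int:
        return self.length + (self.gap_len if self.gap_op == "D" else 0)

    @property
    def q_consumed(self) -> int:
        return self.length + (self.gap_len if self.gap_op == "I" else 0)


def _local_end_search(
    tc: np.ndarray,
    qc: np.ndarray,
    t0: int,
    q0: int,
    step: int,
    lt: int,
    lq: int,
    scoring: ScoringScheme,
) -> EndExtension:
    """Structured twin of :func:`_end_bonus`: same maximum, plus the gap
    placement and run composition realising it (shortest run, ungapped
    preferred, then smallest deletion, then smallest insertion)."""
    rm, px = scoring.match_reward, scoring.mismatch_penalty
    po, pg = scoring.gap_open_penalty, scoring.gap_extend_penalty
    best = EndExtension()

    def scan(g_t: int, g_q: int, gap_op: str | None, gap_len: int) -> None:
        nonlocal best
        lim = min(lt - g_t, lq - g_q)
        gap_cost = po + gap_len * pg if gap_len else 0
        cum = m = x = 0
        run = EndExtension(-gap_cost if gap_len else 0)
        for k in range(1, lim + 1):
            if tc[t0 + step * (g_t + k)] == qc[q0 + step * (g_q + k)]:
                cum += rm
                m += 1
            else:
                cum -= px
                x += 1
            if cum - gap_cost > run.bonus:
                run = EndExtension(cum - gap_cost, gap_op, gap_len, k, m, x)
        if run.bonus > best.bonus:
            best = run

    scan(0, 0, None, 0)
    for g in range(1, lt):
        if min(lt - g, lq) < 1 or rm * min(lt - g, lq) <= po + g * pg + best.bonus:
            break
        scan(g, 0, "D", g)
    for g in range(1, lq):
        if min(lt, lq - g) < 1 or rm * min(lt, lq - g) <= po + g * pg + best.bonus:
            break
        scan(0, g, "I", g)
    return best


def _global_end_recovered(
    tc: np.ndarray, qc: np.ndarray, t0: int, lt: int, q0: int, lq: int
) -> int:
    """Matches recovered in a charged end region (global mode), taking the
    better of the two extreme gap placements."""
    w = min(lt, lq)
    left = sum(1 for k in range(w) if tc[t0 + k] == qc[q0 + k])
    right = sum(
        1 for k in range(w) if tc[t0 + lt - w + k] == qc[q0 + lq - w + k]
    )
    return max(left, right)


def _chain_core_filtered(
    mems, scoring, td, glob, comp, target, query, tlen, qlen, sl, predecessor_filter
):
    """Python twin of :func:`_chain_core` with a pluggable predecessor filter.

    The filter receives (j, i, scores) and returns True to skip predecessor
    ``i``; its binding contract is that skipped predecessors never change
    the maximum (the pruning-equivalence property).
    """
    n = len(mems)
    rm, px, po, pg = (
        scoring.match_reward,
        scoring.mismatch_penalty,
        scoring.gap_open_penalty,
        scoring.gap_extend_penalty,
    )
    S = np.empty(n, dtype=np.int64)
    W = np.full(n, -1, dtype=np.int64)
    extensions = 0
    skipped = 0
    tc = _seq_codes(target, -1)
    qc = _seq_codes(query, -2)
    for j, m in enumerate(mems):
        s0 = m.length * rm
        lt0, lq0 = m.target_start - 1, m.query_start - 1
        if glob:
            pen = _end_region_penalty(lt0, lq0, scoring)
            if comp and min(lt0, lq0) > 0:
                pen -= _global_end_recovered(tc, qc, 0, lt0, 0, lq0) * (
                    scoring.mismatch_penalty + rm
                )
            s0 -= pen
        elif comp:
            s0 += _end_bonus_py(
                tc, qc, lt0, lq0, -1, lt0, lq0,
                rm, scoring.mismatch_penalty, scoring.gap_open_penalty,
                scoring.gap_extend_penalty,
            )
        S[j] = s0
    for j in range(n):
        mj = mems[j]
        for i in range(j):
            mi = mems[i]
            if (
                mi.target_end > mj.target_end
                or mi.query_end == mj.query_end
                or mi.target_end == mj.target_end
                or mi.query_start >= mj.query_start
                or mi.target_start >= mj.target_start
            ):
                continue
            if predecessor_filter is not None and predecessor_filter(j, i, S):
                skipped += 1
                continue
            mo = max(overlap_length(mi, mj), 0)
            if mj.length - mo < 1:
                continue
            mj_trim = (
                MEM(mj.length - mo, mj.target_start + mo, mj.query_start + mo)
                if mo
                else mj
            )
            lt = mj_trim.target_start - mi.target_end - 1
            lq = mj_trim.query_start - mi.query_end - 1
            if td is not None and max(lt, lq) > td:
                skipped += 1
                continue
            gap = inter_mem_penalty(mi, mj_trim, scoring, target if comp else None,
                                    query if comp else None, sl)
            s = S[i] + mj_trim.length * rm - gap.penalty
            extensions += 1
            if s > S[j]:
                S[j] = s
                W[j] = i
    best = None
    e = -1
    for j, m in enumerate(mems):
        s = int(S[j])
        lt, lq = tlen - m.target_end, qlen - m.query_end
        if glob:
            pen = _end_region_penalty(lt, lq, scoring)
            if comp and min(lt, lq) > 0:
                pen -= _global_end_recovered(
                    tc, qc, m.target_end, lt, m.query_end, lq
                ) * (scoring.mismatch_penalty + scoring.match_reward)
            s -= pen
        elif comp:
            s += _end_bonus_py(
                tc, qc, m.target_end - 1, m.query_end - 1, 1, lt, lq,
                scoring.match_reward, scoring.mismatch_penalty,
                scoring.gap_open_penalty, scoring.gap_extend_penalty,
            )
        if best is None or s > best:
            best = s
            e = j
    return S, W, e, best, extensions, skipped


def _empty_result(mode: str) -> ChainResult:
    # no MEM to chain: score 0, empty chain; `no_mem` property flags it
    return ChainResult(
        score=0,
        chain=(),
        chain_indices=(),
        junctions=(),
        stats=AlignmentStats(),
        cigar="",
        mode=mode,
        target_start=0,
        query_start=0,
    )


def dp_align(
    mems: list[MEM],
    scoring: ScoringScheme,
    target: str,
    query: str,
    *,
    mode: str = "local",
    td: int | None = None,
    sl: int = 1,
    predecessor_filter=None,
) -> ChainResult:
    """Best-scoring MEM chain for one sequence pair.

    ``mems`` must be sorted by query end ascending.  ``td`` skips
    predecessor pairs whose junction distance max(LT, LQ) exceeds it
    (``None`` = unlimited).  ``sl`` is the short-MEM threshold the input was
    filtered with; values > 1 enable the junction compensation scan.  All
    argmax ties break toward the smaller index (and toward starting a new
    chain over an equal-scoring extension), making output deterministic.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    if td is not None and td < 1:
        raise ValueError("td must be >= 1 or None")
    for a, b in zip(mems, mems[1:]):
        if a.query_end > b.query_end:
            raise ValueError("MEMs must be sorted by query end ascending")
    if not mems:
        return _empty_result(mode)
    tlen, qlen = len(target), len(query)
    glob = mode == "global"
    comp = sl > 1
    if predecessor_filter is None:
        L = np.fromiter((m.length for m in mems), dtype=np.int64, count=len(mems))
        ST = np.fromiter((m.target_start for m in mems), dtype=np.int64, count=len(mems))
        SQ = np.fromiter((m.query_start for m in mems), dtype=np.int64, count=len(mems))
        S, W, e, best, ext, skipped = _chain_core_jit(
            L,
            ST,
            SQ,
            np.int64(scoring.match_reward),
            np.int64(scoring.mismatch_penalty),
            np.int64(scoring.gap_open_penalty),
            np.int64(scoring.gap_extend_penalty),
            np.int64(-1 if td is None else td),
            glob,
            comp,
            _seq_codes(target, -1),
            _seq_codes(query, -2),
            np.int64(tlen),
            np.int64(qlen),
        )
    else:
        S, W, e, best, ext, skipped = _chain_core_filtered(
            mems, scoring, td, glob, comp, target, query, tlen, qlen, sl,
            predecessor_filter,
        )
    table = ChainTable(S, W, int(e), int(ext), int(skipped))
    # backtrack
    order: list[int] = []
    f = int(e)
    while f != -1:
        order.append(f)
        f = int(W[f])
        if len(order) > len(mems):  # pragma: no cover - cycle guard
            raise RuntimeError("backtracking cycle in chain table")
    order.reverse()
    return _build_result(
        mems, order, int(best), scoring, target, query, mode, sl, comp, table
    )


def _build_result(
    mems, order, score, scoring, target, query, mode, sl, comp, table
) -> ChainResult:
    """Re-walk the chosen chain, apply overlap trimming, recompute stats and
    CIGAR, and verify the DP score from first principles."""
    chain: list[MEM] = []
    junctions: list[InterMemGap] = []
    stats = AlignmentStats()
    for idx in order:
        m = mems[idx]
        if chain:
            prev = chain[-1]
            mo = max(overlap_length(prev, m), 0)
            if mo:
                m = MEM(m.length - mo, m.target_start + mo, m.query_start + mo)
            gap = inter_mem_penalty(
                prev, m, scoring, target if comp else None,
                query if comp else None, sl,
            )
            junctions.append(gap)
            stats.matches += gap.recovered_matches
            stats.mismatches += gap.mismatches - gap.recovered_matches
            if gap.gap_length:
                stats.gap_opens += 1
                stats.gap_length += gap.gap_length
        chain.append(m)
        stats.matches += m.length
    first, last = chain[0], chain[-1]
    tc = _seq_codes(target, -1)
    qc = _seq_codes(query, -2)
    lead_ext = tail_ext = EndExtension()
    if mode == "global":
        for t0, q0, lt, lq in (
            (0, 0, first.target_start - 1, first.query_start - 1),
            (last.target_end, last.query_end, len(target) - last.target_end,
             len(query) - last.query_end),
        ):
            w = min(lt, lq)
            rec = (
                _global_end_recovered(tc, qc, t0, lt, q0, lq)
                if comp and w > 0
                else 0
            )
            stats.matches += rec
            stats.mismatches += w - rec
            ng = abs(lt - lq)
            if ng:
                stats.gap_opens += 1
                stats.gap_length += ng
    elif comp:
        # free ends: recover filtered short-MEM matches (optionally past a
        # single gap adjacent to the chain end)
        lead_ext = _local_end_search(
            tc, qc, first.target_start - 1, first.query_start - 1, -1,
            first.target_start - 1, first.query_start - 1, scoring,
        )
        tail_ext = _local_end_search(
            tc, qc, last.target_end - 1, last.query_end - 1, 1,
            len(target) - last.target_end, len(query) - last.query_end, scoring,
        )
        for ext in (lead_ext, tail_ext):
            stats.matches += ext.matches
            stats.mismatches += ext.mismatches
            if ext.gap_len:
                stats.gap_opens += 1
                stats.gap_length += ext.gap_len
    check = eq1_score(stats, scoring)
    if check != score:  # internal consistency: chain replay must equal DP score
        raise AssertionError(
            f"chain replay score {check} != DP score {score} (chain {chain})"
        )
    cigar = emit_cigar(
        chain, junctions, len(target), len(query), mode,
        lead_ext=lead_ext, tail_ext=tail_ext,
    )
    return ChainResult(
        score=score,
        chain=tuple(chain),
        chain_indices=tuple(order),
        junctions=tuple(junctions),
        stats=stats,
        cigar=cigar,
        mode=mode,
        target_start=1 if mode == "global" else first.target_start - lead_ext.t_consumed,
        query_start=1 if mode == "global" else first.query_start - lead_ext.q_consumed,
        table=table,
    )


def emit_cigar(
    chain: list[MEM] | tuple[MEM, ...],
    junctions: list[InterMemGap] | tuple[InterMemGap, ...],
    tlen: int,
    qlen: int,
    mode: str,
    lead_ext: "EndExtension | None" = None,
    tail_ext: "EndExtension | None" = None,
) -> str:
    """CIGAR text for a trimmed chain and its junctions.

    M covers MEMs and junction mismatch columns, I extra query symbols, D
    extra target symbols; in local mode the query's free ends are soft
    clips (S).  ``lead_ext``/``tail_ext`` are free-end recoveries (local
    mode with short-MEM compensation): an M run, with the optional gap
    emitted between the run and the chain.  Within each junction
    mismatches precede the single continuous gap (score-neutral
    placement).
    """
    lead_ext = lead_ext or EndExtension()
    tail_ext = tail_ext or EndExtension()
    if not chain:
        return ""
    if len(junctions) != len(chain) - 1:
        raise ValueError("junction count must be one less than chain length")
    ops: list[tuple[str, int]] = []

    def emit(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    def emit_region(lt: int, lq: int) -> None:
        emit("M", min(lt, lq))
        if lt < lq:
            emit("I", lq - lt)
        elif lt > lq:
            emit("D", lt - lq)

    first, last = chain[0], chain[-1]
    if mode == "local":
        emit("S", first.query_start - 1 - lead_ext.q_consumed)
        emit("M", lead_ext.length)
        if lead_ext.gap_len:
            emit(lead_ext.gap_op, lead_ext.gap_len)
    else:
        emit_region(first.target_start - 1, first.query_start - 1)
    for k, m in enumerate(chain):
        if k:
            g = junctions[k - 1]
            emit_region(g.lt, g.lq)
        emit("M", m.length)
    if mode == "local":
        if tail_ext.gap_len:
            emit(tail_ext.gap_op, tail_ext.gap_len)
        emit("M", tail_ext.length)
        emit("S", qlen - last.query_end - tail_ext.q_consumed)
    else:
        emit_region(tlen - last.target_end, qlen - last.query_end)
    q_consumed = sum(n for op, n in ops if op in "MIS")
    if q_consumed != qlen:
        raise ValueError(f"CIGAR consumes {q_consumed} query symbols, expected {qlen}")
    t_span = sum(n for op, n in ops if op in "MD")
    t_expect = (
        tlen
        if mode == "global"
        else last.target_end
        + tail_ext.t_consumed
        - (first.target_start - lead_ext.t_consumed)
        + 1
    )
    if t_span != t_expect:
        raise ValueError(f"CIGAR spans {t_span} target symbols, expected {t_expect}")
    return "".join(f"{n}{op}" for op, n in ops)
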