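"""Independent reference implementations used only by the test suite.

Everything here is deliberately naive and written against the definitions,
not against the package code paths it checks: per-character comparison for
match masks, O(n^3)-style enumeration for MEMs (the package ships its own
copy of that oracle, so this module focuses on the rest), exhaustive
alignment-path enumeration for affine-gap scores on tiny strings, and
subset enumeration for the chaining DP.
"""

from __future__ import annotations

from itertools import combinations

from memalign import MEM, ScoringScheme

ACGT = "ACGT"


def naive_match_bits(target: str, query: str, d: int) -> list[bool]:
    """Per-symbol comparison of the overlap window at diagonal d."""
    a0, b0 = max(d, 0), max(-d, 0)
    width = min(len(target) - a0, len(query) - b0)
    out = []
    for k in range(width):
        tc, qc = target[a0 + k].upper(), query[b0 + k].upper()
        out.append(tc == qc and tc in ACGT)
    return out


def naive_runs(bits: list[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True values as (start, length)."""
    runs = []
    k = 0
    while k < len(bits):
        if bits[k]:
            start = k
            while k < len(bits) and bits[k]:
                k += 1
            runs.append((start, k - start))
        else:
            k += 1
    return runs


def exhaustive_global(target: str, query: str, s: ScoringScheme) -> int:
    """Best end-to-end affine-gap score by enumerating every alignment path."""
    rm, px = s.match_reward, s.mismatch_penalty
    po, pg = s.gap_open_penalty, s.gap_extend_penalty
    n, m = len(target), len(query)
    best = [None]

    def rec(i: int, j: int, last: str, score: int) -> None:
        if i == n and j == m:
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            delta = rm if target[i] == query[j] else -px
            rec(i + 1, j + 1, "M", score + delta)
        if i < n:
            rec(i + 1, j, "D", score - (pg if last == "D" else po + pg))
        if j < m:
            rec(i, j + 1, "I", score - (pg if last == "I" else po + pg))

    rec(0, 0, "", 0)
    return best[0]


def exhaustive_local(target: str, query: str, s: ScoringScheme) -> int:
    """Best local affine-gap score: max over substring pairs (tiny inputs)."""
    best = 0
    for i0 in range(len(target)):
        for i1 in range(i0 + 1, len(target) + 1):
            for j0 in range(len(query)):
                for j1 in range(j0 + 1, len(query) + 1):
                    g = exhaustive_global(target[i0:i1], query[j0:j1], s)
                    if g > best:
                        best = g
    return best


def chain_score(
    mems: list[MEM],
    idxs: tuple[int, ...],
    s: ScoringScheme,
    tlen: int,
    qlen: int,
    mode: str,
) -> int | None:
    """Score of one ordered MEM subset, or None if it is not a valid chain.

    Junction model (complete-MEM-set assumption, no compensation): trim the
    later MEM's start by any overlap, then charge min(LT, LQ) mismatches
    and one continuous gap of |LT - LQ| symbols.
    """
    rm, px = s.match_reward, s.mismatch_penalty
    po, pg = s.gap_open_penalty, s.gap_extend_penalty
    total = 0
    prev = None
    first = None
    for k in idxs:
        m = mems[k]
        length, st, sq = m.length, m.target_start, m.query_start
        et, eq = st + length - 1, sq + length - 1
        if prev is not None:
            # screen against the predecessor's *original* coordinates:
            # overlap trimming is transient and never moves MEM ends
            pst, psq, pet, peq = prev
            if pet >= et or peq >= eq or pst >= st or psq >= sq:
                return None
            mo = max(pet - st + 1, peq - sq + 1)
            if mo > 0:
                st += mo
                sq += mo
                length -= mo
                if length < 1:
                    return None
            lt = st - pet - 1
            lq = sq - peq - 1
            total -= min(lt, lq) * px
            gap = abs(lt - lq)
            if gap:
                total -= po + gap * pg
        else:
            first = (st, sq)
        total += length * rm
        prev = (m.target_start, m.query_start, et, eq)
    if mode == "global":
        for lt, lq in ((first[0] - 1, first[1] - 1), (tlen - prev[2], qlen - prev[3])):
            total -= min(lt, lq) * px
            gap = abs(lt - lq)
            if gap:
                total -= po + gap * pg
    return total


def best_chain_by_enumeration(
    mems: list[MEM],
    s: ScoringScheme,
    tlen: int,
    qlen: int,
    mode: str = "local",
) -> tuple[int, tuple[int, ...]]:
    """Max chain score over every admissible MEM subset (mems EQ-sorted).

    Returns (score, indices); ties prefer the lexicographically smallest
    index tuple of the shortest chain achieving the score.
    """
    best: int | None = None
    best_idx: tuple[int, ...] = ()
    n = len(mems)
    for r in range(1, n + 1):
        for combo in combinations(range(n), r):
            sc = chain_score(mems, combo, s, tlen, qlen, mode)
            if sc is not None and (best is None or sc > best):
                best = sc
                best_idx = combo
    if best is None:
        raise ValueError("no admissible chain")
    return best, best_idx
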