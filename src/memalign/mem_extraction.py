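"""Maximal exact match (MEM) enumeration by banded shift-and-compare.

A MEM is a shared substring of the target and the query that cannot be
extended on either side without hitting a mismatch or a sequence end.  Every
MEM lies on exactly one diagonal d = ST - SQ, so enumerating MEMs reduces to
scanning diagonals: at each diagonal the packed sequences are shifted,
XOR-compared and the runs of matching symbols decoded (:mod:`.seqbits`).
A band limit ``gl`` restricts the scan to diagonals near the main one,
bounding the net gap an alignment may contain; a length filter ``sl`` drops
short MEMs, which are overwhelmingly chance matches.

Coordinates are 1-based inclusive throughout, matching the conventions of
the chaining stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import seqbits
from .seqbits import PackedSequence


@dataclass(frozen=True)
class MEM:
    """One maximal exact match: length plus 1-based start coordinates."""

    length: int
    target_start: int
    query_start: int

    @property
    def target_end(self) -> int:
        """1-based inclusive end in the target."""
        return self.target_start + self.length - 1

    @property
    def query_end(self) -> int:
        """1-based inclusive end in the query."""
        return self.query_start + self.length - 1

    @property
    def diagonal(self) -> int:
        return self.target_start - self.query_start

    def __repr__(self) -> str:  # compact: MEM(L=4, ST=1, SQ=1)
        return (
            f"MEM(L={self.length}, ST={self.target_start}, SQ={self.query_start})"
        )


def _as_packed(seq: str | PackedSequence, name: str) -> PackedSequence:
    packed = seqbits.encode(seq) if isinstance(seq, str) else seq
    if packed.length == 0:
        raise ValueError(f"{name} sequence is empty")
    return packed


def band_diagonals(tlen: int, qlen: int, gl: int | None) -> range:
    """Diagonal offsets to scan for a band of half-width ``gl``.

    The band always contains the corridor between the two corner diagonals
    (0 and |T|-|Q|), widened by ``gl`` on each side, so that any alignment
    whose net insertions and net deletions each stay within ``gl`` is
    representable.  ``gl=None`` scans every diagonal.
    """
    lo_valid, hi_valid = -(qlen - 1), tlen - 1
    if gl is None:
        return range(lo_valid, hi_valid + 1)
    if gl < 0:
        raise ValueError("gl must be >= 0")
    lo = min(0, tlen - qlen) - gl
    hi = max(0, tlen - qlen) + gl
    return range(max(lo, lo_valid), min(hi, hi_valid) + 1)


def extract_mems(
    target: str | PackedSequence,
    query: str | PackedSequence,
    gl: int | None = None,
    sl: int = 1,
) -> list[MEM]:
    """All MEMs on diagonals within the band with length >= ``sl``.

    Returns MEMs sorted by query end (EQ) ascending, ties in (diagonal,
    target start) order, as required by the chaining DP.  With ``gl=None``
    and ``sl=1`` this is the complete MEM set of the pair.
    """
    t = _as_packed(target, "target")
    q = _as_packed(query, "query")
    if sl < 1:
        raise ValueError("sl must be >= 1")
    mems: list[MEM] = []
    for d in band_diagonals(t.length, q.length, gl):
        mask = seqbits.diagonal_match_mask(t, q, d)
        a0 = max(d, 0)
        b0 = max(-d, 0)
        for start, length in seqbits.match_runs(mask):
            if length >= sl:
                mems.append(MEM(length, a0 + start + 1, b0 + start + 1))
    return counting_sort_by_query_end(mems, q.length)


def counting_sort_by_query_end(mems: list[MEM], max_eq: int) -> list[MEM]:
    """Stable linear-time bucket sort of MEMs on their query end (EQ).

    Runs in O(n + max_eq); MEMs sharing an EQ keep their input order, which
    for :func:`extract_mems` means (diagonal, target start) order.
    """
    buckets: list[list[MEM]] = [[] for _ in range(max_eq + 1)]
    for m in mems:
        eq = m.query_end
        if not 1 <= eq <= max_eq:
            raise ValueError(f"query end {eq} outside [1, {max_eq}] for {m}")
        buckets[eq].append(m)
    return [m for bucket in buckets for m in bucket]


def brute_force_mems(target: str, query: str) -> set[MEM]:
    """Reference O(n^3) MEM enumeration by direct extension (test oracle).

    Tries every start pair (i, j), extends while symbols match, and keeps
    maximal runs only.  Intended for short sequences; the bit-parallel
    extractor is checked against this in the test suite.
    """
    t = target.upper()
    q = query.upper()

    def ok(a: str, b: str) -> bool:
        return a == b and a in "ACGT"

    out: set[MEM] = set()
    for i in range(len(t)):
        for j in range(len(q)):
            if not ok(t[i], q[j]):
                continue
            if i > 0 and j > 0 and ok(t[i - 1], q[j - 1]):
                continue  # not a run start
            k = 1
            while i + k < len(t) and j + k < len(q) and ok(t[i + k], q[j + k]):
                k += 1
            out.add(MEM(k, i + 1, j + 1))
    return out
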