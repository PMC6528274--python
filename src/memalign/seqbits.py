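"""2-bit packed DNA sequences and the shift/XOR primitives of MEM extraction.

A DNA string is packed two bits per symbol (A=00, C=01, T=10, G=11) into a
single arbitrary-width Python integer, with symbol ``i`` occupying bit
positions ``[2i, 2i+1]``.  Comparing two sequences at a fixed diagonal
offset then reduces to a symbol-granular shift, one XOR over the whole
overlap, and a collapse of each 2-bit code pair into a single per-symbol
match bit.  Runs of set match bits are decoded through an edge bit-vector
(the mask XORed with a one-symbol-shifted copy of itself), so the cost of
run decoding scales with the number of runs, not the sequence length.

Characters outside {A, C, G, T} cannot be represented in two bits; they are
kept in place but flagged in a per-symbol ambiguity mask and forced to
mismatch in every comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CODE = {"A": 0, "C": 1, "T": 2, "G": 3}
_BASE = "ACTG"  # index == 2-bit code

# ASCII -> 2-bit code (ambiguous characters get code 0 and a mask flag)
_ASCII_CODE = np.zeros(256, dtype=np.uint8)
_ASCII_VALID = np.zeros(256, dtype=bool)
for _b, _c in _CODE.items():
    for _ch in (_b, _b.lower()):
        _ASCII_CODE[ord(_ch)] = _c
        _ASCII_VALID[ord(_ch)] = True

# byte -> its four even-position bits packed into a nibble, used to collapse
# a 2-bit-per-symbol flag vector down to 1 bit per symbol
_EVEN_NIBBLE = np.array(
    [(b & 1) | ((b >> 1) & 2) | ((b >> 2) & 4) | ((b >> 3) & 8) for b in range(256)],
    dtype=np.uint8,
)


class DiagonalError(ValueError):
    """Requested diagonal offset lies outside the comparison rectangle."""


@dataclass(frozen=True)
class PackedSequence:
    """A DNA sequence packed 2 bits per symbol.

    ``bits`` holds the 2-bit codes, ``ambiguity_mask`` one bit per symbol
    (set where the input character was not A/C/G/T).
    """

    bits: int
    length: int
    ambiguity_mask: int = 0

    def __len__(self) -> int:
        return self.length

    def code(self, i: int) -> int:
        """2-bit code of symbol ``i`` (0-based)."""
        return (self.bits >> (2 * i)) & 3


@dataclass(frozen=True)
class MatchMask:
    """Per-symbol match flags for one diagonal of a sequence comparison.

    ``diagonal`` is the offset d = (target position - query position); bit k
    of ``match_bits`` is set when the k-th overlapping symbol pair matches.
    ``width`` is the overlap length at that diagonal.
    """

    diagonal: int
    match_bits: int
    width: int


def encode(sequence: str) -> PackedSequence:
    """Pack a DNA string into a :class:`PackedSequence`.

    Case-insensitive; any non-ACGT character is retained positionally but
    flagged ambiguous (it will never match anything, itself included).
    """
    n = len(sequence)
    if n == 0:
        return PackedSequence(0, 0, 0)
    ascii_codes = np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)
    codes = _ASCII_CODE[ascii_codes]
    valid = _ASCII_VALID[ascii_codes]
    # pack 4 symbols per byte, little-endian in both byte and bit order
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    packed = (
        quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    ).astype(np.uint8)
    bits = int.from_bytes(packed.tobytes(), "little")
    amb = 0
    if not valid.all():
        vpad = (-n) % 8
        v = np.concatenate([~valid, np.zeros(vpad, dtype=bool)])
        amb = int.from_bytes(np.packbits(v, bitorder="little").tobytes(), "little")
    return PackedSequence(bits, n, amb)


def decode(seq: PackedSequence) -> str:
    """Inverse of :func:`encode` for unambiguous positions.

    Ambiguous positions decode to ``N`` (their original character is not
    stored in the 2-bit codes).
    """
    out = []
    for i in range(seq.length):
        if (seq.ambiguity_mask >> i) & 1:
            out.append("N")
        else:
            out.append(_BASE[seq.code(i)])
    return "".join(out)


def _ones(width: int) -> int:
    return (1 << width) - 1


def _collapse_pairs(flags2: int, width: int) -> int:
    """Collapse a flag vector with one bit at each even position 2k into a
    vector with that flag at position k (per-symbol granularity)."""
    if width == 0:
        return 0
    nbytes = (2 * width + 7) // 8
    raw = np.frombuffer(flags2.to_bytes(nbytes, "little"), dtype=np.uint8)
    nib = _EVEN_NIBBLE[raw]
    if len(nib) % 2:
        nib = np.concatenate([nib, np.zeros(1, dtype=np.uint8)])
    out = (nib[0::2] | (nib[1::2] << 4)).astype(np.uint8)
    return int.from_bytes(out.tobytes(), "little")


def diagonal_match_mask(
    target: PackedSequence, query: PackedSequence, d: int
) -> MatchMask:
    """Compare target and query at diagonal offset ``d``.

    ``d = ST - SQ`` in 1-based MEM coordinates (equivalently the 0-based
    target/query index difference).  Bit k of the result is set when the
    overlapping symbol pair k matches and neither side is ambiguous.
    """
    if not (-(query.length - 1) <= d <= target.length - 1):
        raise DiagonalError(
            f"diagonal {d} impossible for |T|={target.length}, |Q|={query.length}"
        )
    a0 = max(d, 0)  # first overlapping target index
    b0 = max(-d, 0)  # first overlapping query index
    width = min(target.length - a0, query.length - b0)
    m2 = _ones(2 * width)
    tw = (target.bits >> (2 * a0)) & m2
    qw = (query.bits >> (2 * b0)) & m2
    x = tw ^ qw
    # a symbol matches iff both bits of its XORed code pair are clear
    mism2 = x | (x >> 1)  # even bit 2k set iff symbols k differ
    matched2 = ~mism2 & (m2 // 3)  # m2//3 == 0b0101..01, even positions
    matched = _collapse_pairs(matched2, width)
    m1 = _ones(width)
    amb = ((target.ambiguity_mask >> a0) | (query.ambiguity_mask >> b0)) & m1
    return MatchMask(d, matched & ~amb & m1, width)


def match_runs(mask: MatchMask) -> list[tuple[int, int]]:
    """Maximal runs of set bits in ``mask`` as (start_offset, run_length).

    Decoded through the edge bit-vector E = M xor (M << 1): E carries one
    set bit at the start of each run and one just past its end, so the scan
    touches only run boundaries.
    """
    m = mask.match_bits
    edges = m ^ (m << 1)
    runs: list[tuple[int, int]] = []
    start = -1
    while edges:
        low = edges & -edges
        pos = low.bit_length() - 1
        edges ^= low
        if start < 0:
            start = pos
        else:
            runs.append((start, pos - start))
            start = -1
    return runs
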