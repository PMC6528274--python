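"""Synthetic sequence-pair simulator with SNP and indel mutations.

Targets are drawn uniformly over ACGT; the query is the target passed
through a per-base mutation walk: each base may start an indel (insertion
or deletion, equiprobable) with probability ``indel_rate``, and each
retained base is substituted with probability ``snp_rate``.  Indel lengths
are geometric: after the first gapped base, each additional base is added
with probability ``indel_expansion``, so the mean length is
1 / (1 - indel_expansion).  An indel never starts inside another indel.

Four presets mirror the standard benchmark conditions: short/long targets
(125 / 500 bp) at low divergence (SNP 1%, indel 0.1%, expansion 5%) and at
high divergence (SNP 5%, indel 0.5%, expansion 10%).

Every pair carries its ground-truth edit list; replaying the edits over
the target reproduces the query exactly, which the test suite relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

_BASES = "ACGT"


@dataclass(frozen=True)
class MutationProfile:
    """Target length and per-base mutation rates of one dataset."""

    length: int = 125
    snp_rate: float = 0.01
    indel_rate: float = 0.001
    indel_expansion: float = 0.05
    name: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for attr in ("snp_rate", "indel_rate", "indel_expansion"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1]")


#: Benchmark presets: (length, SNP rate, indel rate, indel expansion).
PRESETS: dict[str, MutationProfile] = {
    "DSL": MutationProfile(125, 0.01, 0.001, 0.05, "DSL"),
    "DLL": MutationProfile(500, 0.01, 0.001, 0.05, "DLL"),
    "DSH": MutationProfile(125, 0.05, 0.005, 0.10, "DSH"),
    "DLH": MutationProfile(500, 0.05, 0.005, 0.10, "DLH"),
}


@dataclass(frozen=True)
class Edit:
    """One recorded mutation: 0-based target position, op, length, bases.

    ``snp``: replace target[position] with ``bases`` (length 1).
    ``ins``: insert ``bases`` immediately before target[position].
    ``del``: delete ``length`` bases starting at target[position].
    """

    position: int
    op: str
    length: int
    bases: str


@dataclass(frozen=True)
class PairRecord:
    """A simulated pair plus the ground-truth edits that produced it."""

    target: str
    query: str
    edits: tuple[Edit, ...]


def apply_edits(target: str, edits: tuple[Edit, ...] | list[Edit]) -> str:
    """Replay an edit list over the target (edits in left-to-right order)."""
    out: list[str] = []
    pos = 0
    for e in edits:
        out.append(target[pos : e.position])
        if e.op == "snp":
            out.append(e.bases)
            pos = e.position + 1
        elif e.op == "ins":
            out.append(e.bases)
            pos = e.position
        elif e.op == "del":
            pos = e.position + e.length
        else:
            raise ValueError(f"unknown edit op {e.op!r}")
    out.append(target[pos:])
    return "".join(out)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _indel_length(rng: np.random.Generator, expansion: float) -> int:
    length = 1
    while rng.random() < expansion:
        length += 1
    return length


def generate_pair(
    profile: MutationProfile, rng: np.random.Generator, target: str | None = None
) -> PairRecord:
    """Draw one target/query pair under ``profile``.

    ``target`` may be supplied (e.g. sliced from a reference FASTA);
    otherwise it is drawn uniformly over ACGT at the profile length.
    """
    if target is None:
        target = _random_dna(rng, profile.length)
    edits: list[Edit] = []
    query: list[str] = []
    i = 0
    n = len(target)
    while i < n:
        if profile.indel_rate and rng.random() < profile.indel_rate:
            length = _indel_length(rng, profile.indel_expansion)
            if rng.random() < 0.5:  # insertion: extra query symbols
                bases = _random_dna(rng, length)
                edits.append(Edit(i, "ins", length, bases))
                query.append(bases)
                # the base at i is still processed below
            else:  # deletion: skip target bases
                length = min(length, n - i)
                edits.append(Edit(i, "del", length, ""))
                i += length
                continue
        base = target[i]
        if profile.snp_rate and rng.random() < profile.snp_rate:
            sub = _BASES[(_BASES.index(base) + rng.integers(1, 4)) % 4]
            edits.append(Edit(i, "snp", 1, sub))
            query.append(sub)
        else:
            query.append(base)
        i += 1
    return PairRecord(target, "".join(query), tuple(edits))


def generate_pairs(
    profile: MutationProfile, n_pairs: int, seed: int | np.random.Generator
) -> list[PairRecord]:
    """``n_pairs`` independent pairs, fully determined by the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [generate_pair(profile, rng) for _ in range(n_pairs)]


def generate_dataset(
    profile: MutationProfile,
    n_pairs: int,
    out_dir: str | Path,
    seed: int = 0,
    prefix: str = "pairs",
) -> dict[str, Path]:
    """Write a dataset to ``out_dir`` and return the file paths.

    Emits paired FASTA files (record i of targets pairs with record i of
    queries), a two-column TSV, and a ground-truth TSV with one row per
    edit (pair_id, position, op, length, bases).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_pairs(profile, n_pairs, seed)
    paths = {
        "targets": out_dir / f"{prefix}_targets.fasta",
        "queries": out_dir / f"{prefix}_queries.fasta",
        "tsv": out_dir / f"{prefix}.tsv",
        "truth": out_dir / f"{prefix}_truth.tsv",
    }
    with open(paths["targets"], "w") as ft, open(paths["queries"], "w") as fq:
        for k, rec in enumerate(records):
            ft.write(f">pair{k}/target\n{rec.target}\n")
            fq.write(f">pair{k}/query\n{rec.query}\n")
    with open(paths["tsv"], "w") as f:
        f.write("target\tquery\n")
        for rec in records:
            f.write(f"{rec.target}\t{rec.query}\n")
    with open(paths["truth"], "w") as f:
        f.write("pair_id\tposition\top\tlength\tbases\n")
        for k, rec in enumerate(records):
            for e in rec.edits:
                f.write(f"pair{k}\t{e.position}\t{e.op}\t{e.length}\t{e.bases}\n")
    return paths
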