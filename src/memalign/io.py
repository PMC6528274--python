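"""File I/O, the score-agreement benchmark, and alignment pretty-printing.

Input pairs come either as two FASTA files paired positionally (record i
of the target file aligns with record i of the query file) or as a
two-column TSV (target, query per line; ``#`` comments and an optional
header are ignored).  Output coordinates are 1-based inclusive by default,
with an option to convert to 0-based half-open at the boundary.

The agreement benchmark mirrors the accuracy metrics used to evaluate
chain-based alignment: every pair is aligned both with the hybrid chainer
and with the exact Gotoh aligner, and the report counts suboptimal pairs
(reported score below the optimum) and their mean score deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from . import affine_sw
from .chain_dp import ChainResult
from .hybrid import BatchDiagnostics, HybridConfig, align_pair

Pair = tuple[str, str, str]  # (pair_id, target, query)


def read_fasta_pairs(target_path: str | Path, query_path: str | Path) -> list[Pair]:
    """Positionally paired records from two FASTA files."""

    def load(path: str | Path) -> list[tuple[str, str]]:
        records = []
        for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"{path}: record {idx} ({rec.id}) has empty sequence")
            records.append((rec.id, seq))
        if not records:
            raise ValueError(f"{path}: no FASTA records found")
        return records

    targets = load(target_path)
    queries = load(query_path)
    if len(targets) != len(queries):
        raise ValueError(
            f"record count mismatch: {target_path} has {len(targets)}, "
            f"{query_path} has {len(queries)}"
        )
    return [
        (f"pair{i}", t, q) for i, ((_, t), (_, q)) in enumerate(zip(targets, queries))
    ]


def read_tsv_pairs(path: str | Path) -> list[Pair]:
    """Pairs from a two-column TSV (target, query); '#' comments ignored."""
    pairs: list[Pair] = []
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[:2] == ["target", "query"]:  # header
                continue
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated sequences")
            pairs.append((f"pair{len(pairs)}", cols[0].upper(), cols[1].upper()))
    if not pairs:
        raise ValueError(f"{path}: no sequence pairs found")
    return pairs


def read_pairs(
    inputs: tuple[str | Path, ...] | list[str | Path],
) -> list[Pair]:
    """Dispatch on input shape: one TSV path, or (targets, queries) FASTA."""
    if len(inputs) == 1:
        return read_tsv_pairs(inputs[0])
    if len(inputs) == 2:
        return read_fasta_pairs(inputs[0], inputs[1])
    raise ValueError("supply either one TSV or two FASTA paths")


# ---------------------------------------------------------------------------
# Agreement benchmark
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Summary of chain-vs-optimal score agreement over a batch.

    ``n_suboptimal`` counts pairs whose reported score fell below the
    exact affine-gap optimum; ``mean_score_diff`` averages the deficit
    over those pairs only (0.0 when there are none).
    """

    n_pairs: int = 0
    n_suboptimal: int = 0
    score_diff_total: int = 0
    fallback_counts: dict[str, int] = field(default_factory=dict)
    theta: float = 0.0

    @property
    def mean_score_diff(self) -> float:
        return self.score_diff_total / self.n_suboptimal if self.n_suboptimal else 0.0

    @property
    def identical_fraction(self) -> float:
        return 1.0 - self.n_suboptimal / self.n_pairs if self.n_pairs else 1.0


def compare_pairs(
    pairs: Iterable[Pair], config: HybridConfig | None = None
) -> tuple[AgreementReport, list[dict]]:
    """Align every pair with the hybrid chainer and the Gotoh oracle.

    Returns the aggregate report and one row dict per pair.  The reported
    score can never exceed the optimum (every chain maps to a realisable
    alignment); this is asserted per pair.
    """
    config = config or HybridConfig()
    oracle = affine_sw.sw_local if config.mode == "local" else affine_sw.sw_global
    report = AgreementReport()
    batch = BatchDiagnostics()
    rows: list[dict] = []
    for pid, target, query in pairs:
        result, diag = align_pair(target, query, config)
        opt = oracle(target, query, config.scoring)
        if result.score > opt:
            raise AssertionError(
                f"{pid}: reported score {result.score} exceeds optimum {opt}"
            )
        batch.record(diag)
        report.n_pairs += 1
        diff = opt - result.score
        if diff > 0:
            report.n_suboptimal += 1
            report.score_diff_total += diff
        rows.append(
            {
                "pair_id": pid,
                "score": result.score,
                "optimal_score": opt,
                "score_diff": diff,
                "method": result.method,
                "fallback_reason": result.fallback_reason or "",
            }
        )
    report.fallback_counts = dict(batch.fallback_counts)
    report.theta = batch.theta
    return report, rows


# ---------------------------------------------------------------------------
# Pretty printer
# ---------------------------------------------------------------------------

_GREEN = "\x1b[32m"
_RED = "\x1b[31m"
_RESET = "\x1b[0m"


def _cigar_ops(cigar: str) -> Iterator[tuple[str, int]]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield ch, int(num)
            num = ""


def pretty_print(
    result: ChainResult, target: str, query: str, color: bool = False
) -> str:
    """Three-line human-readable rendering of an alignment.

    Top line: target (gapped); middle: ``|`` match, ``.`` mismatch; bottom:
    query with soft-clipped free ends in lowercase.  With ``color=True``
    the columns covered by chained MEMs are highlighted.  The de-gapped
    bottom line always reproduces the query.
    """
    if not result.cigar:
        return "(no alignment)"
    # columns covered by MEMs of the chain, as query positions (1-based)
    mem_q: set[int] = set()
    for m in result.chain:
        mem_q.update(range(m.query_start, m.query_end + 1))
    ti = result.target_start - 1 if result.target_start else 0
    qi = 0
    tline, mline, qline = [], [], []
    for op, n in _cigar_ops(result.cigar):
        for _ in range(n):
            if op == "S":
                tline.append(" ")
                mline.append(" ")
                qline.append(query[qi].lower())
                qi += 1
            elif op == "M":
                tc, qc = target[ti], query[qi]
                match = tc == qc and tc.upper() in "ACGT"
                if color and (qi + 1) in mem_q:
                    tc = f"{_GREEN}{tc}{_RESET}"
                    qc = f"{_GREEN}{qc}{_RESET}"
                tline.append(tc)
                mline.append("|" if match else ".")
                qline.append(qc)
                ti += 1
                qi += 1
            elif op == "I":
                tline.append("-")
                mline.append(" ")
                qline.append(query[qi])
                qi += 1
            elif op == "D":
                tline.append(target[ti])
                mline.append(" ")
                qline.append("-")
                ti += 1
            else:
                raise ValueError(f"unexpected CIGAR op {op!r}")
    header = (
        f"score={result.score} method={result.method} mode={result.mode} "
        f"cigar={result.cigar}"
    )
    return "\n".join([header, "".join(tline), "".join(mline), "".join(qline)])


# ---------------------------------------------------------------------------
# Flat key=value config files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "match": ("scoring", "match_reward", int),
    "mismatch": ("scoring", "mismatch_penalty", int),
    "gap_open": ("scoring", "gap_open_penalty", int),
    "gap_extend": ("scoring", "gap_extend_penalty", int),
    "gl": (None, "gl", int),
    "sl": (None, "sl", int),
    "tm": (None, "tm", int),
    "ts": (None, "ts", int),
    "td": (None, "td", int),
    "mode": (None, "mode", str),
    "hybrid": (None, "hybrid_enabled", bool),
}


def parse_config_file(path: str | Path) -> dict:
    """Flat ``key = value`` config; '#' comments; 'none' disables a limit."""
    values: dict = {}
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            _, _, cast = _CONFIG_KEYS[key]
            if raw.lower() in ("none", ""):
                values[key] = None
            elif cast is bool:
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            else:
                values[key] = cast(raw)
    return values


def build_config(file_values: dict | None = None, **overrides) -> HybridConfig:
    """Merge defaults, config-file values and explicit overrides.

    ``overrides`` use the same keys as the config file; ``None`` overrides
    are treated as "not given" except for the limit keys gl/tm/ts/td where
    the file may legitimately carry None (limit disabled).
    """
    from .chain_dp import ScoringScheme

    merged: dict = dict(file_values or {})
    for key, val in overrides.items():
        if key not in _CONFIG_KEYS:
            raise ValueError(f"unknown config key {key!r}")
        if val is not None:
            merged[key] = val
    scoring_kwargs = {}
    config_kwargs = {}
    for key, val in merged.items():
        group, attr, _ = _CONFIG_KEYS[key]
        if group == "scoring":
            scoring_kwargs[attr] = val
        else:
            config_kwargs[attr] = val
    if scoring_kwargs:
        config_kwargs["scoring"] = ScoringScheme(**scoring_kwargs)
    config = HybridConfig(**config_kwargs)
    config.validate()
    return config
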