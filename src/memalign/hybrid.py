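"""Per-pair orchestration: extract, chain, and fall back when unreliable.

The chain-based aligner is fast but heuristic: the band ``gl`` bounds the
net gap it can see, short-MEM removal (``sl``) discards evidence, and
repetitive sequences generate quadratically many MEM pairs.  Three rules
send a pair to the exact Gotoh aligner instead:

1. too_many_mems — more than ``tm`` MEMs were extracted (repetitive pair);
2. no_mem       — no MEM of length >= ``sl`` exists at all;
3. low_score    — the chain score fell below ``ts`` (typically a gap the
   band could not represent).

With well-chosen thresholds only a small fraction of pairs takes the slow
path, and every fallback returns the exact optimum, so the hybrid score is
never below the chain-only score.

The mean MEM count over pairs *not* rejected by rule 1, called theta, is
the tuning diagnostic for ``tm``: 4*theta < tm < 5*theta works well in
practice.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

from . import affine_sw, seqbits
from .chain_dp import ChainResult, ScoringScheme, dp_align
from .mem_extraction import extract_mems


@dataclass(frozen=True)
class HybridConfig:
    """All knobs of the hybrid aligner.

    Defaults are the standard configuration for ~125 bp sequences:
    band half-width ``gl=6``, minimum MEM length ``sl=4``, junction
    distance cutoff ``td=25``, fallback thresholds ``tm=50`` (MEM count)
    and ``ts=100`` (score), with match/mismatch/open/extend = 2/3/4/1.
    ``tm`` and ``ts`` are length-dependent and should be re-tuned for other
    lengths (see :func:`suggest_tm`).  ``gl=None`` or ``tm=None`` /
    ``ts=None`` / ``td=None`` disable the respective limit.
    """

    gl: int | None = 6
    sl: int = 4
    tm: int | None = 50
    ts: int | None = 100
    td: int | None = 25
    mode: str = "local"
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    hybrid_enabled: bool = True

    def validate(self) -> None:
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sl < 1:
            raise ValueError("sl must be >= 1")
        for name in ("gl", "tm", "ts", "td"):
            v = getattr(self, name)
            if v is not None and v < 0 and name != "ts":
                raise ValueError(f"{name} must be >= 0 or None")
        if self.td is not None and self.td < 1:
            raise ValueError("td must be >= 1 or None")


@dataclass
class PairDiagnostics:
    """Per-pair bookkeeping: MEM count, fallback reason, stage timings."""

    mem_count: int = 0
    fallback_reason: str | None = None
    timings: dict[str, float] = field(default_factory=dict)


def _sw_result(target: str, query: str, config: HybridConfig, reason: str) -> ChainResult:
    score, cigar, stats, t_start, q_start = affine_sw.sw_align(
        target, query, config.scoring, config.mode
    )
    return ChainResult(
        score=score,
        chain=(),
        chain_indices=(),
        junctions=(),
        stats=stats,
        cigar=cigar,
        mode=config.mode,
        target_start=t_start,
        query_start=q_start,
        method="sw",
        fallback_reason=reason,
    )


def align_pair(
    target: str, query: str, config: HybridConfig | None = None
) -> tuple[ChainResult, PairDiagnostics]:
    """Align one pair with the hybrid strategy.

    Returns the :class:`ChainResult` (``method`` is ``"memalign"`` or
    ``"sw"``) and per-pair diagnostics.  With ``hybrid_enabled=False`` the
    chain result is returned regardless of the thresholds (a pair with no
    MEM then scores 0 with an empty chain).
    """
    config = config or HybridConfig()
    config.validate()
    if not target:
        raise ValueError("target sequence is empty")
    if not query:
        raise ValueError("query sequence is empty")
    diag = PairDiagnostics()
    t0 = time.perf_counter()
    mems = extract_mems(target, query, gl=config.gl, sl=config.sl)
    diag.timings["extract"] = time.perf_counter() - t0
    diag.mem_count = len(mems)
    hybrid = config.hybrid_enabled
    if hybrid and config.tm is not None and len(mems) > config.tm:
        diag.fallback_reason = "too_many_mems"
        return _sw_result(target, query, config, "too_many_mems"), diag
    if not mems:
        if hybrid:
            diag.fallback_reason = "no_mem"
            return _sw_result(target, query, config, "no_mem"), diag
        return (
            dp_align([], config.scoring, target, query, mode=config.mode),
            diag,
        )
    t0 = time.perf_counter()
    result = dp_align(
        mems,
        config.scoring,
        target,
        query,
        mode=config.mode,
        td=config.td,
        sl=config.sl,
    )
    diag.timings["chain"] = time.perf_counter() - t0
    if hybrid and config.ts is not None and result.score < config.ts:
        diag.fallback_reason = "low_score"
        return _sw_result(target, query, config, "low_score"), diag
    return result, diag


@dataclass
class BatchDiagnostics:
    """Aggregated fallback accounting and the theta tuning statistic.

    ``theta`` is the mean MEM count over pairs *not* sent to fallback by
    the MEM-count rule (rule 1); pairs rejected for other reasons still
    contribute their MEM count.
    """

    n_pairs: int = 0
    fallback_counts: dict[str, int] = field(
        default_factory=lambda: {"too_many_mems": 0, "low_score": 0, "no_mem": 0}
    )
    _theta_sum: int = 0
    _theta_n: int = 0

    def record(self, diag: PairDiagnostics) -> None:
        self.n_pairs += 1
        if diag.fallback_reason:
            self.fallback_counts[diag.fallback_reason] += 1
        if diag.fallback_reason != "too_many_mems":
            self._theta_sum += diag.mem_count
            self._theta_n += 1

    @property
    def n_fallback(self) -> int:
        return sum(self.fallback_counts.values())

    @property
    def theta(self) -> float:
        return self._theta_sum / self._theta_n if self._theta_n else 0.0


def suggest_tm(theta: float) -> tuple[float, float]:
    """Recommended (lower, upper) bracket for ``tm`` given theta.

    Four to five times the mean extracted-MEM count is a practical band
    for the repetitive-sequence fallback threshold.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return 4 * theta, 5 * theta
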