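# Methods

## Problem and model

`memalign` computes pairwise alignments of short, similar DNA sequences
under the affine-gap scoring model: each match adds R<sub>m</sub>, each mismatch
subtracts P<sub>x</sub>, and each continuous run of g gap symbols subtracts
P<sub>o</sub> + g·P<sub>g</sub>. Mismatch cost is flat (no substitution matrix), which is the
usual choice for DNA. Two alignment modes are supported: *local* (free
ends — leading/trailing stretches of either sequence are clipped without
charge, reported as soft clips on the query) and *global* (end-to-end,
both ends charged).

Instead of filling a symbol-by-symbol DP table, the aligner operates on
the pair's **maximal exact matches**: shared substrings that cannot be
extended on either side. For similar sequences the informative MEMs are
few and long, so a DP over MEMs touches far fewer states than a DP over
symbols while targeting the same optimum.

## MEM extraction (seqbits, mem_extraction)

Sequences are packed 2 bits per symbol (A=00, C=01, T=10, G=11) into an
arbitrary-width integer, symbol i occupying bits [2i, 2i+1]. Every MEM
lies on a single diagonal d = ST − SQ, so extraction slides the query
across the target one diagonal at a time: the overlap windows are XORed,
each 2-bit code pair collapses to one per-symbol match bit (a byte-level
lookup table vectorised with numpy), and maximal runs of set bits are
decoded through an edge bit-vector E = M ⊕ (M ≪ 1), whose set bits mark
run boundaries — decoding cost scales with the number of runs, not the
sequence length. Each run on a diagonal is exactly one MEM.

Characters outside {A,C,G,T} cannot be represented in 2 bits; they are
retained positionally, flagged in a per-symbol ambiguity mask, and forced
to mismatch everywhere (including against themselves). This avoids
silently inflating MEMs across N runs.

Two extraction-time heuristics bound the work:

* **Band `gl`** — only diagonals within `gl` of the corridor between the
  two corner diagonals (0 and |T|−|Q|) are scanned. For equal lengths
  this is the classic band; for unequal lengths the corridor definition
  lets any alignment whose net insertions and net deletions each stay
  within `gl` remain representable. `gl=None` disables the band.
* **Short-MEM filter `sl`** — MEMs shorter than `sl` are dropped. Most
  short MEMs are chance matches (a random pair of length-n sequences has
  ≈ 3n²/16 of them), and removing them shrinks the quadratic chaining
  stage; the chaining DP compensates for the rare informative ones (see
  below).

MEMs are emitted sorted by query end (EQ) via a stable counting sort
(linear in n + |Q|); ties keep (diagonal, target-start) order so outputs
are reproducible. A brute-force enumerator (`brute_force_mems`, extend
from every start pair, keep maximal runs) ships as the reference oracle;
the bit-parallel path is set-equal to it on randomized suites.

## Chaining DP (chain_dp)

Given the EQ-sorted MEM list, the DP computes for each MEM M<sub>j</sub> the best
score S<sub>j</sub> of an alignment ending at M<sub>j</sub>:

* initialisation: S<sub>j</sub> = L<sub>j</sub>·R<sub>m</sub> (plus end handling, below);
* transition: for each admissible predecessor M<sub>i</sub>,
  S<sub>j</sub> = max(S<sub>j</sub>, S<sub>i</sub> + L'<sub>j</sub>·R<sub>m</sub> − P<sub>i</sub><sup>j</sup>), where L'<sub>j</sub> is M<sub>j</sub>'s length after
  trimming any overlap with M<sub>i</sub> off its start, and P<sub>i</sub><sup>j</sup> is the junction
  penalty;
* termination: the best S<sub>j</sub> (after trailing-end handling) is the score;
  backtracking over the argmax indices yields the chain.

**Junction model.** With LT and LQ symbols between the MEMs in target and
query, the junction charges min(LT, LQ) mismatches and one continuous gap
of |LT − LQ| symbols (one opening). This assumes no matching symbol
survives between adjacent chain MEMs — exact when the complete MEM set is
present, because any surviving match is itself a MEM and the optimal
chain would route through it. The overlap of adjacent MEMs (max of the
target-side and query-side overlaps) is excluded from the later MEM; the
trim is transient — a MEM re-enters later comparisons with its original
coordinates, which is sound because trimming never moves MEM ends.

**Admissibility screen.** A predecessor is skipped when it reaches past
M<sub>j</sub> in either sequence or fully overlaps it (equal ends, or starts not
strictly increasing). A distance cutoff `td` additionally skips junctions
with max(LT, LQ) > td; distant MEMs are almost never adjacent in a good
chain. The measure is symmetric in the two sequences by choice.

**Short-MEM compensation (sl > 1).** When filtering may have removed real
matches, the junction region is re-scanned under the two extreme
placements of its single gap (flushed against either MEM); matching
symbols are counted sequentially and the better count m* converts m*
charged mismatches back into matches (worth m*·(P<sub>x</sub>+R<sub>m</sub>) each). The scan
is skipped when `sl = 1` (provably nothing to recover) or when
min(LT, LQ) = 0 (no mismatch columns exist). Junctions whose true optimum
needs matches on *both* sides of a mid-region gap, or two separate gaps,
are not recovered — this is the documented residual error source, at the
~0.1% per-pair level on low-divergence data.

**Free-end recovery (local mode, sl > 1).** The same filtering loses
short MEMs near the sequence ends, where there is no flanking MEM to form
a junction. Each candidate chain start/end therefore gets an end bonus:
the best ungapped outward extension (max prefix of +R<sub>m</sub>/−P<sub>x</sub> steps),
optionally preceded by a single gap adjacent to the chain end — the
terminal analogue of the junction's one-gap assumption, since a gap at
the outer end is equivalent to free clipping. The search over gap lengths
breaks off as soon as R<sub>m</sub>·(remaining overlap) can no longer beat the
incumbent. With `sl = 1` the bonus is provably zero (any profitable
extension contains MEMs the DP already chains), so it is skipped.

**Global mode.** Leading and trailing regions are charged with the
junction formula extended to the boundaries (min mismatches + one gap),
with the same two-placement compensation when `sl > 1`.

**Determinism.** All argmax ties break toward the smaller index, and an
equal-scoring extension never displaces a chain start; outputs are
bit-reproducible. Scores are exact integers.

**Self-check.** After backtracking, the chain is replayed from first
principles — trims, junction counts, end handling — into match/mismatch/
gap-open/gap-length counts whose score must equal the DP score exactly
(an `AssertionError` otherwise), and the CIGAR must consume exactly |Q|
query symbols and span the aligned target window.

**Pruning hook.** `dp_align` accepts a `predecessor_filter` callable; its
contract is that filtered predecessors never change the maximum (verified
in the suite with a no-op filter against the default path). No default
pruning beyond the screen and `td` is enabled: a dominance rule that is
provably score-preserving under overlap trimming was not derivable, and
an unproven one risks silent suboptimality.

The transition loop is JIT-compiled (numba) for the default path; the
filtered path runs the same logic in Python and is held equal to the
kernel by tests.

## Exact aligner (affine_sw)

A three-state Gotoh DP (match state plus one gap state per sequence) over
the full (|T|+1)×(|Q|+1) lattice, gap open charged P<sub>o</sub>+P<sub>g</sub>, extension
P<sub>g</sub>; the local variant floors the match state at zero. It is validated
against exhaustive alignment-path enumeration on tiny strings and against
Biopython's `PairwiseAligner` on randomized suites, and serves both as
the hybrid fallback and as the oracle all agreement numbers are measured
against. Score-only evaluation is the JIT-compiled hot path; traceback
(for CIGARs and fallback stats) walks the filled matrices with
deterministic tie preference (diagonal, then query gap).

## Hybrid orchestration (hybrid)

Three rules route a pair to the exact aligner: (1) more than `tm` MEMs
extracted (repetitive sequences, where chaining is both slow and
error-prone — checked before chaining); (2) no MEM of length ≥ `sl` at
all; (3) chain score below `ts` (typically a gap the band cannot
represent — checked after chaining, against the mode-consistent score).
When rules 1 and 2 would both fire, rule 1 is recorded, as the MEM count
is known first. Every fallback returns the true optimum, so the hybrid
score is never below the chain-only score.

**Θ diagnostic.** Θ is the mean MEM count over pairs *not* rejected by
rule 1. The practical bracket for the MEM-count threshold is
4Θ < tm < 5Θ (`suggest_tm`); on the 125 bp low-divergence preset
Θ ≈ 6.5, for which the default tm=50 is comfortably safe.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| R<sub>m</sub>/P<sub>x</sub>/P<sub>o</sub>/P<sub>g</sub> | scoring magnitudes | 2/3/4/1 | integers; penalties subtracted |
| gl | band half-width (symbols) | 6 | `None` = full band |
| sl | minimum MEM length | 4 | 1 = complete MEM set |
| td | junction distance cutoff | 25 | `None` = unlimited |
| tm | MEM-count fallback threshold | 50 | length-dependent; see Θ |
| ts | score fallback threshold | 100 | length-dependent (~125 bp value) |

`tm` and `ts` scale with sequence length (a perfect 125 bp pair scores
250 under the defaults; `ts=100` flags anything below 40% of that).
For ~500 bp sequences, values around tm=200 and ts=300–450 are
appropriate.

## Synthetic data (simdata)

The simulator emulates resequencing-style divergence: targets drawn
uniformly over ACGT; per base, an indel starts with probability
`indel_rate` (insertion/deletion equiprobable, length 1 + geometric
extensions with probability `indel_expansion`, mean 1/(1−expansion));
surviving bases substitute with probability `snp_rate` to a uniformly
chosen different base. An indel never starts inside another indel. Four
presets cover short/long (125/500 bp) × low/high divergence
(SNP 1%/5%, indel 0.1%/0.5%, expansion 5%/10%). Every pair carries a
ground-truth edit list whose replay reproduces the query exactly.

What it does **not** model: real genomic base composition and repeat
structure, sequencing error profiles, or quality strings. Uniform random
targets make MEM statistics *more* benign than repeat-rich genomic
sequence; agreement numbers on this generator therefore bound behaviour
on repetitive regions optimistically, which is why the `tm` fallback
exists. An optional `target=` argument to `generate_pair` accepts
reference-derived sequences for users who want realistic targets.

## Numerical and edge-case choices

* All coordinates are 1-based inclusive internally and in default
  output; conversion to 0-based half-open happens only at the CLI
  boundary (`--zero-based`).
* Empty MEM list → score 0, empty chain, flagged `no_mem`; empty input
  sequences are rejected up front by the aligners that need them.
* Local Gotoh of any pair ≥ 0; `sw_global("A", "")` = −(P<sub>o</sub>+P<sub>g</sub>).
* Chain scores never exceed the Gotoh optimum of the same mode: every
  chain (with trims, junction placements, end recoveries) corresponds to
  a realisable alignment. This is asserted in the benchmark runner on
  every pair it processes.
* CIGAR convention: M for match/mismatch columns, I for extra query
  symbols, D for extra target symbols, S only in local mode for query
  free ends; within a junction, mismatch columns precede the single gap
  (score-neutral placement).

## Problem sizes used in the checks

The shipped suites run at desk scale: 2,000 simulated 125 bp pairs for
the headline agreement experiment (the generator is seeded, so the
number is reproducible), 1,000 random pairs ≤ 50 bp for
extraction-vs-brute-force set equality, 500 random MEM instances (≤ 10
MEMs) for DP-vs-subset-enumeration equality, and 10,000 random pairs
≤ 30 bp at 0–20% divergence for chain-vs-Gotoh agreement (≥ 99.9%
identical, every discrepancy printed). These sizes give tight empirical
bounds (a 99.9% claim is resolved to ±0.07% at n=2,000) while keeping a
full run in minutes on one core.

## Known limitations

* Only one optimal chain is reported; co-optimal paths are not
  enumerated.
* Junction regions needing two gaps or mid-region matches between two
  long MEMs are scored pessimistically (the ~0.1% residual).
* The band makes net gaps longer than `gl` invisible to the chainer;
  such pairs rely on the `ts` fallback.
* Global mode with aggressive filtering near the ends relies on the
  two-placement end compensation, which cannot represent a terminal
  region needing both a gap and flanking matches on both sides.
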