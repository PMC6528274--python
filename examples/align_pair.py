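"""Align one pair of sequences and show the chain, CIGAR and rendering.

The query below differs from the target by one substitution and a
two-base deletion, so the best chain has three MEMs joined by a mismatch
junction and a gap junction.
"""

from memalign import HybridConfig, ScoringScheme, align_pair, pretty_print

target = "ACGTACGTTTGCAGGCATTACCAGGCTTGA"
query = "ACGTACATTTGCAGGCATTCCAGGCTTGA"  # SNP at 7, 1 bp deleted near 20

config = HybridConfig(sl=1, gl=6, ts=None, scoring=ScoringScheme(2, 3, 4, 1))
result, diag = align_pair(target, query, config)

print(f"extracted MEMs : {diag.mem_count}")
print(f"method         : {result.method}")
print(f"score          : {result.score}")
print(f"cigar          : {result.cigar}")
print("chain          :", ", ".join(f"(L={m.length}, ST={m.target_start}, SQ={m.query_start})" for m in result.chain))
print()
print(pretty_print(result, target, query))
print()
print(
    "The score is matches*2 - mismatches*3 - gap_opens*4 - gap_symbols*1 "
    f"= {result.stats.matches}*2 - {result.stats.mismatches}*3 - "
    f"{result.stats.gap_opens}*4 - {result.stats.gap_length}*1"
)
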