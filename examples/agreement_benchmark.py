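"""Measure how often the chain-based aligner matches the exact optimum.

Simulates 500 low-divergence pairs, aligns each with the hybrid chainer
and with the exact Gotoh local aligner, and reports the agreement
statistics plus the theta diagnostic used to tune the MEM-count fallback
threshold tm.
"""

from memalign import HybridConfig, PRESETS, compare_pairs, generate_pairs, suggest_tm

recs = generate_pairs(PRESETS["DSL"], 500, seed=11)
pairs = [(f"p{i}", r.target, r.query) for i, r in enumerate(recs)]

report, rows = compare_pairs(pairs, HybridConfig())  # gl=6 sl=4 tm=50 ts=100 td=25

print(f"pairs                 : {report.n_pairs}")
print(f"identical scores      : {100 * report.identical_fraction:.2f}%")
print(f"suboptimal alignments : {report.n_suboptimal}")
print(f"mean score deficit    : {report.mean_score_diff:.2f} (over suboptimal pairs)")
print(f"fallbacks by reason   : {report.fallback_counts}")
print(f"theta (mean MEM count): {report.theta:.2f}")
lo, hi = suggest_tm(report.theta)
print(f"suggested tm bracket  : {lo:.1f} .. {hi:.1f}  (4*theta .. 5*theta)")
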