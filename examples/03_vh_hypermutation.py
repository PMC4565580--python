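"""Single-cell VH hypermutation: simulate, call, and summarize.

Draws mutant VH amplicons from the untagged-construct substitution spectrum,
calls mutations back against the parental reference by global alignment,
deduplicates sequences with identical mutation spectra, arranges the
distinct spectra into genealogies by subset order, and tabulates the
substitution spectrum and per-sequence mutation-load distribution.
"""

from aidcycle import pipeline, shm

res = pipeline.shm_experiment("AID-mCherry", n_cells=400, seed=3)

print(f"sequences: {len(res['reads'])}  failed amplicons: {res['n_failed']}")
print(f"distinct mutation spectra: {len(res['unique'])}")

sm = res["spectrum"]
print(f"point mutations: {sm.n_point}  deletions: {sm.n_deletions}  insertions: {sm.n_insertions}")
marg = sm.marginal_percent
print(
    f"marginals: A/T {marg['A'] + marg['T']:.1f}%  G/C {marg['G'] + marg['C']:.1f}%  "
    f"G->T {sm.percent[('G', 'T')]:.1f}%"
)

load = res["load"]
print("mutations per sequence:", {k: v for k, v in load.counts.items()})

# compare a heavier-mutating construct's load distribution against this one
cdt1 = pipeline.shm_experiment("AID-mCherry-CDT1", n_cells=400, seed=4)
chi2, df, p = shm.chi2_vs_reference(cdt1["load"], load)
print(f"CDT1 vs untagged load distribution: chi2 = {chi2:.1f}, df = {df}, p = {p:.3g}")

genealogy = res["genealogy"]
print(f"genealogy: {len(genealogy.nodes)} nodes, {len(genealogy.ambiguous)} ambiguous parent(s)")
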