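"""Simulate a small TRAC-seq experiment and call m7G sites.

Treated libraries accumulate read starts exactly at methylated positions;
the cleavage score contrasts that pile-up against the untreated control.
"""

from tracm7g import (
    SimConfig, build_cleavage_table, call_sites, consensus_motif, map_reads,
    simulate_cleavage_libraries, simulate_trna_set,
)
from tracm7g.trnaref import mature_set

cfg = SimConfig(seed=1, n_trnas=20, n_modified=8, reads_per_library=5000,
                n_genes=50, depth_per_library=50_000)
genes, truth = simulate_trna_set(cfg)
reads, _ = simulate_cleavage_libraries(genes, truth, cfg)
refs = {m.id: m.seq for m in mature_set(genes).values()}

treated = map_reads([s for _, s in reads["treated_ctrl_rep1"]], refs)
untreated = map_reads([s for _, s in reads["untreated_ctrl_rep1"]], refs)
table = build_cleavage_table(treated, untreated, refs)
calls = call_sites(table, refs)  # score > 3 and rate > 0.1 at reference G

print(f"planted sites: {len(truth.site_positions)}, called: {len(calls)}")
for c in calls[:5]:
    print(f"  {c.trna_id:24s} pos {c.position:3d} score {c.score:5.2f} "
          f"rate {c.rate:.2f} context {c.context}")
print("consensus motif:", consensus_motif(calls))
# Each line is one candidate m7G site; the consensus is the degenerate
# 5-mer covering all call contexts and should sit inside DURGY.
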