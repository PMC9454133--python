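"""Quantify tRNA expression and the knockdown fold change.

Modified tRNAs are simulated at half abundance under knockdown of the
methyltransferase; CPM-based quantification recovers the depletion.
"""

from tracm7g import (
    SimConfig, map_reads, quantify_expression, simulate_cleavage_libraries,
    simulate_trna_set,
)
from tracm7g.trnaref import mature_set

cfg = SimConfig(seed=0)  # 150 tRNAs, 21 m7G-modified, 50k reads/library
genes, truth = simulate_trna_set(cfg)
reads, _ = simulate_cleavage_libraries(genes, truth, cfg)
refs = {m.id: m.seq for m in mature_set(genes).values()}

prof_kd = map_reads([s for _, s in reads["untreated_kd_rep1"]], refs)
prof_ctrl = map_reads([s for _, s in reads["untreated_ctrl_rep1"]], refs)
expr = quantify_expression(prof_kd, prof_ctrl)

mod = expr.loc[sorted(truth.modified_trna_ids)]
other = expr.loc[~expr.index.isin(truth.modified_trna_ids)]
print(f"mean log2FC, m7G tRNAs:  {mod['log2fc'].mean():+.3f}  (true factor 0.5)")
print(f"mean log2FC, other tRNAs: {other['log2fc'].mean():+.3f}")
# The m7G group sits near -1 (halved abundance); the slight shortfall is the
# CPM compositional shift from renormalizing over all tRNAs.
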