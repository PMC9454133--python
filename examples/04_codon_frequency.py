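"""Compare m7G-codon frequencies across TE classes.

Genes enriched in codons decoded by m7G tRNAs are exactly those losing TE
under knockdown; the TE-down class should show a higher mean frequency than
TE-non, with a family-wise adjusted permutation p-value.
"""

from tracm7g import (
    SimConfig, build_te_table, compare_groups, decode_codons,
    simulate_rnc_counts, simulate_transcriptome, simulate_trna_set,
)
from tracm7g.codonfreq import codon_frequency_table

cfg = SimConfig(seed=3, n_trnas=20, n_modified=8, n_genes=400,
                depth_per_library=400_000)
genes, truth = simulate_trna_set(cfg)
cds, truth = simulate_transcriptome(cfg, truth)
lengths = {g: len(s) for g, s in cds.items()}
inp, rnc = simulate_rnc_counts(cfg, truth, lengths)
te = build_te_table(inp, rnc, lengths)

codon_set = decode_codons(truth.modified_anticodons)  # strict reverse complement
freqs = codon_frequency_table(cds, codon_set)
cls = te["te_class"]
groups = {c: freqs[cls[cls == c].index].to_numpy()
          for c in ("TE-down", "TE-up", "TE-non") if (cls == c).sum() >= 2}

comp = compare_groups(groups, reference="TE-down", n_perm=5000, seed=1)
print(comp.groups.round(4).to_string())
print(comp.contrasts.round(5).to_string())
print(f"ANOVA F = {comp.f_stat:.1f}, p = {comp.p_anova:.2e}")
# The TE-down mean exceeds the TE-non mean by about the planted margin
# (0.1); the adjusted p-values test each class against the TE-down reference.
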