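"""Generator determinism, planted signal, and truth consistency."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from tracm7g import (
    ConfigurationError, SimConfig, simulate_cleavage_libraries,
    simulate_rnc_counts, simulate_transcriptome, simulate_trna_set,
)
from tracm7g import build_te_table, codon_frequency
from tracm7g._seq import iupac_matches
from tracm7g.trnaref import mature_set


def test_fixed_seed_determinism(small_sim):
    cfg = small_sim["config"]
    genes2, truth2 = simulate_trna_set(cfg)
    assert genes2 == small_sim["genes"]
    assert truth2.site_positions == small_sim["truth"].site_positions
    reads2, sidecar2 = simulate_cleavage_libraries(genes2, truth2, cfg)
    assert reads2 == small_sim["reads"]
    assert sidecar2.equals(small_sim["sidecar"])


def test_no_modified_trnas_is_empty_truth():
    cfg = SimConfig(seed=3, n_trnas=10, n_modified=0, n_genes=20)
    _, truth = simulate_trna_set(cfg)
    assert truth.modified_trna_ids == set()
    with pytest.raises(ConfigurationError):
        simulate_transcriptome(cfg, truth)  # empty m7G codon set


def test_planted_sites_have_g_and_durgy_context(small_sim):
    truth, matures = small_sim["truth"], small_sim["matures"]
    assert len(truth.modified_trna_ids) == 8
    for rid in truth.modified_trna_ids:
        pos = truth.site_positions[rid]
        seq = matures[rid]
        assert seq[pos] == "G"
        assert iupac_matches("DURGY", seq[pos - 2:pos + 3])


@pytest.mark.parametrize(
    "field,value",
    [
        ("cleavage_prob_site", 1.5),
        ("n_modified", 99),
        ("knockdown_fc", 0.0),
        ("m7g_position", 1),
        ("reads_per_library", 0),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = dataclasses.replace(SimConfig(n_trnas=10, n_modified=4), **{field: value})
    with pytest.raises(ConfigurationError, match=field):
        cfg.validate()


def test_no_cleavage_signal_null(small_sim):
    """With cleavage_prob_site=0 the treated and untreated site-start rates
    are statistically indistinguishable (pooled over 10 seeds)."""
    pvals = []
    for seed in range(10):
        cfg = SimConfig(seed=seed, n_trnas=10, n_modified=4,
                        reads_per_library=2000, cleavage_prob_site=0.0)
        genes, truth = simulate_trna_set(cfg)
        _, sidecar = simulate_cleavage_libraries(genes, truth, cfg)
        mod = sidecar[sidecar.trna_id.isin(truth.modified_trna_ids)]
        tab = []
        for chem in ("treated", "untreated"):
            sub = mod[mod.library == f"{chem}_ctrl_rep1"]
            site = sub.n_site_starts.sum()
            tab.append([site, sub.n_reads.sum() - site])
        pvals.append(stats.chi2_contingency(np.array(tab) + 1)[1])
    assert min(pvals) > 0.01 / 10  # Bonferroni-style guard at alpha=0.01


def test_no_knockdown_effect_null():
    cfg = SimConfig(seed=5, n_trnas=10, n_modified=4, reads_per_library=20000,
                    knockdown_fc=1.0)
    genes, truth = simulate_trna_set(cfg)
    _, sidecar = simulate_cleavage_libraries(genes, truth, cfg)
    mod = sidecar[sidecar.trna_id.isin(truth.modified_trna_ids)]
    shares = {}
    for cond in ("ctrl", "kd"):
        sub = mod[mod.library == f"untreated_{cond}_rep1"]
        shares[cond] = sub.n_reads.sum() / cfg.reads_per_library
    p = 4 / 10
    sd = np.sqrt(p * (1 - p) / cfg.reads_per_library)
    assert abs(shares["kd"] - shares["ctrl"]) < 4 * sd


def test_site_start_fraction_matches_binomial(small_sim):
    """Fraction of treated reads from modified tRNAs starting at the site
    is within 3 SD of cleavage_prob_site."""
    cfg, truth, sidecar = small_sim["config"], small_sim["truth"], small_sim["sidecar"]
    mod = sidecar[(sidecar.library == "treated_ctrl_rep1")
                  & sidecar.trna_id.isin(truth.modified_trna_ids)]
    n = mod.n_reads.sum()
    frac = mod.n_site_starts.sum() / n
    sd = np.sqrt(cfg.cleavage_prob_site * (1 - cfg.cleavage_prob_site) / n)
    # background starts can add a whisker above the planted probability
    assert abs(frac - cfg.cleavage_prob_site) < 3 * sd + cfg.background_cleavage


def test_reads_are_mature_substrings(small_sim):
    matures = small_sim["matures"]
    dna = {rid: seq.replace("U", "T") for rid, seq in matures.items()}
    for _, seq in small_sim["reads"]["treated_ctrl_rep1"][:200]:
        assert any(seq in s for s in dna.values())


def test_transcriptome_structure_and_enrichment():
    cfg = SimConfig(seed=4, n_trnas=20, n_modified=8, n_genes=400, codon_margin=0.1)
    genes, truth = simulate_trna_set(cfg)
    cds, truth = simulate_transcriptome(cfg, truth)
    stops = {"TAA", "TAG", "TGA"}
    for seq in list(cds.values())[:50]:
        assert len(seq) % 3 == 0
        assert seq.startswith("ATG")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        assert codons[-1] in stops
        assert all(c not in stops for c in codons[:-1])
    # recompute frequencies from the emitted sequences: truth must agree exactly
    for gid in list(cds)[:50]:
        assert codon_frequency(cds[gid], truth.m7g_codons) == pytest.approx(
            truth.true_codon_freq[gid], abs=1e-12
        )
    freq = np.array([truth.true_codon_freq[g] for g in cds])
    cls = np.array([truth.te_class_truth[g] for g in cds])
    diff = freq[cls == "down"].mean() - freq[cls == "non"].mean()
    assert diff == pytest.approx(cfg.codon_margin, abs=0.02)


def test_unenriched_transcriptome_has_no_down_class():
    cfg = SimConfig(seed=4, n_trnas=20, n_modified=8, n_genes=100, enriched_fraction=0.0)
    genes, truth = simulate_trna_set(cfg)
    _, truth = simulate_transcriptome(cfg, truth)
    assert "down" not in set(truth.te_class_truth.values())


def test_count_tables_deterministic_and_depth_conserving():
    cfg = SimConfig(seed=6, n_trnas=20, n_modified=8, n_genes=300,
                    depth_per_library=300_000)
    genes, truth = simulate_trna_set(cfg)
    cds, truth = simulate_transcriptome(cfg, truth)
    lengths = {g: len(s) for g, s in cds.items()}
    inp1, rnc1 = simulate_rnc_counts(cfg, truth, lengths)
    inp2, rnc2 = simulate_rnc_counts(cfg, truth, lengths)
    assert inp1.equals(inp2) and rnc1.equals(rnc2)
    for df in (inp1, rnc1):
        assert np.allclose(df.sum(), cfg.depth_per_library, rtol=0.05)


def test_null_te_effect_classifies_almost_everything_te_non():
    cfg = SimConfig(seed=8, n_trnas=20, n_modified=8, n_genes=500,
                    depth_per_library=500_000, te_effect_fc=1.0)
    genes, truth = simulate_trna_set(cfg)
    cds, truth = simulate_transcriptome(cfg, truth)
    lengths = {g: len(s) for g, s in cds.items()}
    inp, rnc = simulate_rnc_counts(cfg, truth, lengths)
    te = build_te_table(inp, rnc, lengths)
    assert (te["te_class"] == "TE-non").mean() >= 0.99
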