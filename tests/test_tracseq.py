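"""Mapper, cleavage statistics, site calling, motif and expression."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tracm7g import (
    ConfigurationError, build_cleavage_table, call_sites, cleavage_ratio,
    cleavage_score, consensus_motif, count_modified_trnas, iupac_matches,
    map_reads, quantify_expression,
)
from tracm7g.tracseq import SiteCall

from _oracles import brute_profiles


# ---------------------------------------------------------------------------
# mapping

def test_full_length_unique_read():
    refs = {"a": "ACGUACGUACGUACGUACGUA", "b": "GGGGGGGGGGGGGGGGGGGGG"}
    prof = map_reads([refs["a"]], refs)
    assert prof.starts["a"][0] == 1.0
    assert prof.total_mapped == 1.0
    assert prof.depth["a"].tolist() == [1.0] * 21


def test_tie_split_between_identical_refs():
    seq = "ACGUACGUACGUACGUACGUA"
    prof = map_reads([seq], {"a": seq, "b": seq})
    assert prof.starts["a"][0] == 0.5 and prof.starts["b"][0] == 0.5
    assert prof.total_mapped == 1.0


def test_unmapped_read_does_not_count():
    refs = {"a": "ACGUACGUACGUACGUACGUA"}
    prof = map_reads(["UUUUUUUUUUUUUUUUUUUU"], refs)
    assert prof.total_mapped == 0.0 and prof.n_unmapped == 1


def test_short_read_unmapped():
    refs = {"a": "ACGUACGUACGUACGUACGUA"}
    prof = map_reads(["ACGUACGU"], refs)  # below the 18 nt seed
    assert prof.n_unmapped == 1


def test_mismatched_read_mapped_with_tolerance():
    ref = "ACGUACGUACGUACGUACGUACGUA"
    read = ref[:22] + "A"  # one mismatch in the extension
    assert map_reads([read], {"a": ref + "AA"}, max_mismatches=0).total_mapped == 0
    assert map_reads([read], {"a": ref + "AA"}, max_mismatches=1).total_mapped == 1


def test_empty_reference_set_rejected():
    with pytest.raises(ConfigurationError):
        map_reads(["ACGU"], {})


def test_profile_invariants_on_simulated_library(small_sim):
    reads = [s for _, s in small_sim["reads"]["treated_ctrl_rep1"]]
    prof = map_reads(reads, small_sim["matures"])
    total_w = 0.0
    for rid in prof.depth:
        assert (prof.starts[rid] <= prof.depth[rid] + 1e-9).all()
        total_w += prof.starts[rid].sum()
    assert total_w == pytest.approx(prof.total_mapped, abs=1e-9)
    assert prof.total_mapped + prof.n_unmapped == prof.n_reads


# ---------------------------------------------------------------------------
# cleavage statistics

def test_cleavage_ratio_arithmetic():
    r = cleavage_ratio(np.array([10.0]), np.array([50.0]), pseudocount=0, min_depth=0)
    assert r[0] == pytest.approx(0.2)
    r = cleavage_ratio(np.array([7.0]), np.array([7.0]), pseudocount=0, min_depth=0)
    assert r[0] == pytest.approx(1.0)


def test_cleavage_ratio_depth_mask_and_validation():
    r = cleavage_ratio(np.array([1.0, 10.0]), np.array([5.0, 100.0]), min_depth=20)
    assert np.isnan(r[0]) and not np.isnan(r[1])
    with pytest.raises(ValueError):
        cleavage_ratio(np.array([-1.0]), np.array([5.0]))
    with pytest.raises(ValueError):
        cleavage_ratio(np.array([1.0, 2.0]), np.array([5.0]))


def test_cleavage_score_modes():
    eq = cleavage_score(np.array([0.3]), np.array([0.3]))
    assert eq[0] == pytest.approx(0.0)
    eq = cleavage_score(np.array([0.3]), np.array([0.3]), mode="as_printed")
    assert eq[0] == pytest.approx(1.0)
    lq = cleavage_score(np.array([0.8]), np.array([0.1]))
    assert lq[0] == pytest.approx(3.0)
    ap = cleavage_score(np.array([0.8]), np.array([0.9]), mode="as_printed")
    assert ap[0] == pytest.approx(np.log2(0.8) / np.log2(0.9))
    assert ap[0] == pytest.approx(2.118, abs=1e-3)
    # untreated ratio of exactly 1 stays finite under the printed formula
    assert np.isfinite(cleavage_score(np.array([0.8]), np.array([1.0]), mode="as_printed")[0])
    with pytest.raises(ConfigurationError):
        cleavage_score(np.array([0.5]), np.array([0.5]), mode="nope")


@given(
    rt1=st.floats(0.01, 1.0), rt2=st.floats(0.01, 1.0), rn=st.floats(0.01, 1.0)
)
def test_log_quotient_monotone_in_treated_ratio(rt1, rt2, rn):
    lo, hi = sorted([rt1, rt2])
    s_lo = cleavage_score(np.array([lo]), np.array([rn]))[0]
    s_hi = cleavage_score(np.array([hi]), np.array([rn]))[0]
    assert s_hi >= s_lo - 1e-12


def _toy_table():
    import pandas as pd
    return pd.DataFrame(
        {
            "trna_id": ["t1"] * 3 + ["t2"],
            "position": [2, 5, 8, 2],
            "base": ["G", "G", "C", "G"],
            "ratio_treat": [0.5, 0.05, 0.5, 0.2],
            "ratio_nontreat": [0.02, 0.02, 0.02, 0.025],
            "rate": [0.5, 0.05, 0.5, 0.2],
            "score": [3.5, 3.5, 3.5, 3.0],
            "depth_treat": [100.0] * 4,
            "depth_nontreat": [100.0] * 4,
            "starts_treat": [50.0, 5.0, 50.0, 20.0],
            "starts_nontreat": [2.0] * 4,
        }
    )


def test_call_thresholds_and_g_restriction():
    refs = {"t1": "AUGUAGUACUA", "t2": "AUGUAGUACUA"}
    calls = call_sites(_toy_table(), refs)
    # pos 5 fails rate, pos 8 is not G, t2 pos 2 fails the strict score > 3
    assert [(c.trna_id, c.position) for c in calls] == [("t1", 2)]
    calls_nog = call_sites(_toy_table(), refs, require_g=False)
    assert [(c.trna_id, c.position) for c in calls_nog] == [("t1", 2), ("t1", 8)]
    assert calls[0].context == "AUGUA"


def test_boundary_score_not_called():
    refs = {"t1": "AUGUAGUACUA", "t2": "AUGUAGUACUA"}
    tab = _toy_table()
    tab.loc[0, "score"] = 3.0  # exactly at the threshold: strict inequality
    assert call_sites(tab, refs) == []


def test_context_padding_at_reference_edges():
    refs = {"t": "GAAAG"}
    tab = _toy_table().iloc[:1].assign(trna_id="t", position=0)
    (call,) = call_sites(tab, refs)
    assert call.context == "NNGAA"


# ---------------------------------------------------------------------------
# motif

def test_consensus_motif_worked_example():
    assert consensus_motif(["AUAGC", "GUGGU", "UUAGU"]) == "DURGY"


def test_consensus_motif_singleton_and_errors():
    assert consensus_motif(["AUGGC"]) == "AUGGC"
    with pytest.raises(ValueError):
        consensus_motif([])
    with pytest.raises(ValueError):
        consensus_motif(["AUGGC", "AU"])


def test_consensus_motif_floor_drops_rare_base():
    contexts = ["AUGGC"] * 99 + ["CUGGC"]
    assert consensus_motif(contexts, freq_floor=0.05) == "AUGGC"
    assert consensus_motif(contexts, freq_floor=0.0) == "MUGGC"


@given(st.lists(st.text(alphabet="ACGU", min_size=5, max_size=5), min_size=1, max_size=12))
def test_consensus_with_zero_floor_matches_every_context(contexts):
    motif = consensus_motif(contexts, freq_floor=0.0)
    assert all(iupac_matches(motif, c) for c in contexts)


# ---------------------------------------------------------------------------
# expression

def _profile_from_counts(counts, length=30):
    from tracm7g.tracseq import AlignmentProfile
    refs = {k: "A" * length for k in counts}
    prof = AlignmentProfile.empty(refs)
    for k, c in counts.items():
        prof.starts[k][0] = c
        prof.depth[k][:] = c
        prof.total_mapped += c
    return prof


def test_cpm_arithmetic():
    prof = _profile_from_counts({"A": 300, "B": 100})
    expr = quantify_expression(prof, prof)
    assert expr.loc["A", "cpm_control"] == pytest.approx(750_000)
    assert expr.loc["B", "cpm_control"] == pytest.approx(250_000)
    assert (expr["log2fc"] == 0).all()


def test_expression_requires_mapped_reads():
    empty = _profile_from_counts({"A": 0})
    with pytest.raises(ValueError):
        quantify_expression(empty, _profile_from_counts({"A": 10}))


def test_modified_flag_from_calls():
    prof = _profile_from_counts({"A": 10, "B": 10})
    call = SiteCall("A", 3, 5.0, 0.5, "AUGGC", True)
    expr = quantify_expression(prof, prof, [call])
    assert expr.loc["A", "is_m7g"] and not expr.loc["B", "is_m7g"]


def test_count_modified_trnas_distinct_ids():
    assert count_modified_trnas([])[0] == 0
    calls = [
        SiteCall("tRNA-Gly-GCC-1-1", 3, 5.0, 0.5, "AUGGC", True),
        SiteCall("tRNA-Gly-GCC-1-1", 9, 4.0, 0.4, "GUGGU", True),
        SiteCall("tRNA-Phe-GAA-2-1", 3, 5.0, 0.5, "UUGGC", True),
    ]
    n, summary = count_modified_trnas(calls)
    assert n == 2
    assert summary.set_index("trna_id").loc["tRNA-Gly-GCC-1-1", "n_sites"] == 2
    assert summary.set_index("trna_id").loc["tRNA-Gly-GCC-1-1", "isoacceptor"] == "Gly-GCC"


# ---------------------------------------------------------------------------
# pipeline statistics agree with the brute-force oracle on a small instance

def test_profile_matches_brute_force_oracle(small_sim):
    matures = dict(list(small_sim["matures"].items())[:4])
    reads = [s for _, s in small_sim["reads"]["treated_ctrl_rep1"]][:300]
    prof = map_reads(reads, matures)
    depth_o, starts_o, mapped_o = brute_profiles(reads, matures)
    assert prof.total_mapped == pytest.approx(mapped_o, abs=1e-9)
    for rid in matures:
        assert np.allclose(prof.depth[rid], depth_o[rid], atol=1e-12)
        assert np.allclose(prof.starts[rid], starts_o[rid], atol=1e-12)
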