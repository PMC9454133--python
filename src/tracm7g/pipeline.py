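"""End-to-end orchestration: simulate -> buildref -> callm7g -> expression
-> te -> codonfreq, driven by a single YAML config with one section per
stage.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so a run can be resumed: with ``resume=True`` a stage whose
outputs already exist (and whose upstream stages were not re-run) is
skipped. All randomness derives from the single config seed, so a run is
reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seq import ConfigurationError
from .synthdata import SimConfig, simulate_all
from .trnaref import build_precursor, mature_set, read_annotation, read_fasta, write_fasta
from .tracseq import (
    AlignmentProfile, build_cleavage_table, call_sites, consensus_motif,
    count_modified_trnas, map_reads, quantify_expression, read_fastq_seqs,
    site_calls_frame, SiteCall,
)
from .transeff import build_te_table, read_count_table
from .codonfreq import codon_frequency_table, compare_groups, decode_codons
from .trnaref import anticodon_from_name

logger = logging.getLogger(__name__)

_SIM_FIELDS = {f.name: f.default for f in dataclasses.fields(SimConfig) if f.name != "seed"}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": dict(_SIM_FIELDS),
    "mapping": {"max_mismatches": 0, "seed_len": 18},
    "calling": {
        "pseudocount": 0.5, "min_depth": 20, "score_mode": "log_quotient",
        "min_score": 3.0, "min_rate": 0.1, "require_g": True,
        "motif_freq_floor": 0.05,
    },
    "te": {"log2fc_threshold": 1.0, "min_input_fpkm": 1.0},
    "codon": {"wobble": "strict", "method": "permutation", "n_perm": 10000},
}

_CHECKS = {
    ("mapping", "max_mismatches"): lambda v: isinstance(v, int) and v >= 0,
    ("mapping", "seed_len"): lambda v: isinstance(v, int) and v >= 8,
    ("calling", "pseudocount"): lambda v: isinstance(v, (int, float)) and v >= 0,
    ("calling", "min_depth"): lambda v: isinstance(v, (int, float)) and v >= 0,
    ("calling", "score_mode"): lambda v: v in ("log_quotient", "as_printed"),
    ("calling", "min_score"): lambda v: isinstance(v, (int, float)),
    ("calling", "min_rate"): lambda v: isinstance(v, (int, float)) and 0 <= v <= 1,
    ("calling", "require_g"): lambda v: isinstance(v, bool),
    ("calling", "motif_freq_floor"): lambda v: isinstance(v, (int, float)) and 0 <= v <= 1,
    ("te", "log2fc_threshold"): lambda v: isinstance(v, (int, float)) and v > 0,
    ("te", "min_input_fpkm"): lambda v: isinstance(v, (int, float)) and v >= 0,
    ("codon", "wobble"): lambda v: v in ("strict", "wobble34"),
    ("codon", "method"): lambda v: v in ("permutation", "dunnett"),
    ("codon", "n_perm"): lambda v: isinstance(v, int) and v >= 100,
}


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config: top level must be a mapping")
    return data


def validate_config(config: dict) -> tuple[dict, list[str]]:
    """Merge a user config over the defaults; returns ``(materialized,
    violations)``. Unknown keys are violations (strict mode)."""
    violations: list[str] = []
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for section, value in config.items():
        if section == "seed":
            if not isinstance(value, int) or value < 0:
                violations.append("seed: must be a non-negative integer")
            else:
                merged["seed"] = value
            continue
        if section not in DEFAULT_CONFIG:
            violations.append(f"{section}: unknown section")
            continue
        if not isinstance(value, dict):
            violations.append(f"{section}: must be a mapping")
            continue
        for key, v in value.items():
            if key not in DEFAULT_CONFIG[section]:
                violations.append(f"{section}.{key}: unknown key")
                continue
            merged[section][key] = v
    # simulate section is validated through SimConfig itself
    try:
        SimConfig(seed=merged["seed"] if isinstance(merged["seed"], int) else 0,
                  **merged["simulate"]).validate()
    except (ConfigurationError, TypeError) as exc:
        violations.append(f"simulate.{exc}")
    for (section, key), check in _CHECKS.items():
        if not check(merged[section][key]):
            violations.append(f"{section}.{key}: invalid value {merged[section][key]!r}")
    return merged, violations


def demo_config() -> dict:
    """A small, fast configuration exercising every stage."""
    return {
        "seed": 7,
        "simulate": {
            "n_trnas": 30, "n_modified": 8, "reads_per_library": 6000,
            "n_genes": 200, "depth_per_library": 200_000,
        },
        "codon": {"n_perm": 500},
    }


def _pooled_profile(outdir: Path, pattern: str, refs) -> AlignmentProfile:
    paths = sorted(outdir.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no FASTQ matching {pattern} under {outdir}")
    prof = None
    for p in paths:
        one = map_reads(read_fastq_seqs(p), refs)
        prof = one if prof is None else prof + one
    return prof


def run_pipeline(config: dict, outdir, resume: bool = False) -> dict:
    """Execute all stages into ``outdir``; returns (and writes) the JSON summary."""
    cfg, violations = validate_config(config)
    if violations:
        raise ConfigurationError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    summary: dict = {"version": __version__, "seed": seed, "config": cfg, "stages": {}}
    upstream_ran = False

    def stage(name: str, outputs: list[Path], fn) -> dict:
        nonlocal upstream_ran
        if resume and not upstream_ran and all(p.exists() for p in outputs):
            logger.info("stage %s: outputs present, skipped (resume)", name)
            block = fn(skip=True) or {}
            block["skipped"] = True
        else:
            try:
                block = fn(skip=False) or {}
            except Exception as exc:
                raise RuntimeError(
                    f"stage {name!r} failed (inputs under {outdir}): {exc}"
                ) from exc
            block["skipped"] = False
            upstream_ran = True
        summary["stages"][name] = block
        return block

    sim_dir = outdir / "01_simulate"
    ref_dir = outdir / "02_ref"
    sites_dir = outdir / "03_sites"
    expr_dir = outdir / "04_expression"
    te_dir = outdir / "05_te"
    codon_dir = outdir / "06_codon"
    for d in (ref_dir, sites_dir, expr_dir, te_dir, codon_dir):
        d.mkdir(exist_ok=True)

    # 1. simulate ----------------------------------------------------------
    sim_cfg = SimConfig(seed=seed, **cfg["simulate"])

    def do_simulate(skip):
        if not skip:
            simulate_all(sim_cfg, sim_dir)
        return {
            "n_trnas": sim_cfg.n_trnas, "n_modified": sim_cfg.n_modified,
            "reads_per_library": sim_cfg.reads_per_library, "n_genes": sim_cfg.n_genes,
        }

    stage("simulate", [sim_dir / "truth.json", sim_dir / "cds.fa"], do_simulate)

    # 2. buildref ----------------------------------------------------------
    mature_fa = ref_dir / "mature.fa"
    precursor_fa = ref_dir / "precursor.fa"

    def do_buildref(skip):
        if not skip:
            genes = read_annotation(sim_dir / "trna_annotation.bed", sim_dir / "trna_genome.fa")
            matures = mature_set(genes)
            write_fasta(matures.values(), mature_fa)
            write_fasta({g.id: build_precursor(g) for g in genes}, precursor_fa)
            return {"n_references": len(matures)}
        return {"n_references": len(read_fasta(mature_fa))}

    stage("buildref", [mature_fa, precursor_fa], do_buildref)
    refs = read_fasta(mature_fa)

    # 3. callm7g -----------------------------------------------------------
    cal = cfg["calling"]
    table_tsv = sites_dir / "cleavage_table.tsv"
    calls_tsv = sites_dir / "site_calls.tsv"
    motif_txt = sites_dir / "motif.txt"

    def do_callm7g(skip):
        if not skip:
            treated = _pooled_profile(sim_dir, "treated_ctrl_rep*.fastq", refs)
            untreated = _pooled_profile(sim_dir, "untreated_ctrl_rep*.fastq", refs)
            table = build_cleavage_table(
                treated, untreated, refs, pseudocount=cal["pseudocount"],
                min_depth=cal["min_depth"], mode=cal["score_mode"],
            )
            calls = call_sites(
                table, refs, min_score=cal["min_score"], min_rate=cal["min_rate"],
                require_g=cal["require_g"],
            )
            table.to_csv(table_tsv, sep="\t", index=False)
            site_calls_frame(calls).to_csv(calls_tsv, sep="\t", index=False)
            motif = consensus_motif(calls, cal["motif_freq_floor"]) if calls else ""
            motif_txt.write_text(motif + "\n")
        calls_df = pd.read_csv(calls_tsv, sep="\t")
        n_mod = calls_df["trna_id"].nunique() if len(calls_df) else 0
        return {
            "n_sites": int(len(calls_df)), "n_modified_trnas": int(n_mod),
            "motif": motif_txt.read_text().strip(),
        }

    stage("callm7g", [table_tsv, calls_tsv, motif_txt], do_callm7g)

    # 4. expression --------------------------------------------------------
    expr_tsv = expr_dir / "expression.tsv"

    def do_expression(skip):
        if not skip:
            calls_df = pd.read_csv(calls_tsv, sep="\t")
            calls = [
                SiteCall(r.trna_id, int(r.position), float(r.score), float(r.rate),
                         str(r.context), bool(r.is_g))
                for r in calls_df.itertuples(index=False)
            ] if len(calls_df) else []
            prof_kd = _pooled_profile(sim_dir, "untreated_kd_rep*.fastq", refs)
            prof_ctrl = _pooled_profile(sim_dir, "untreated_ctrl_rep*.fastq", refs)
            expr = quantify_expression(prof_kd, prof_ctrl, calls)
            expr.to_csv(expr_tsv, sep="\t")
        expr = pd.read_csv(expr_tsv, sep="\t", index_col="trna_id")
        mod = expr[expr["is_m7g"]]
        return {
            "n_trnas": int(len(expr)),
            "mean_log2fc_m7g": float(mod["log2fc"].mean()) if len(mod) else None,
            "mean_log2fc_other": float(expr[~expr["is_m7g"]]["log2fc"].mean()),
        }

    stage("expression", [expr_tsv], do_expression)

    # 5. te ----------------------------------------------------------------
    te_tsv = te_dir / "te_table.tsv"

    def do_te(skip):
        if not skip:
            input_df, lengths = read_count_table(sim_dir / "input_counts.tsv")
            rnc_df, _ = read_count_table(sim_dir / "rnc_counts.tsv")
            te = build_te_table(
                input_df, rnc_df, lengths,
                log2fc_threshold=cfg["te"]["log2fc_threshold"],
                min_input_fpkm=cfg["te"]["min_input_fpkm"],
            )
            te.to_csv(te_tsv, sep="\t", index_label="gene_id")
        te = pd.read_csv(te_tsv, sep="\t", index_col="gene_id")
        counts = te["te_class"].value_counts().to_dict()
        return {"class_counts": {k: int(v) for k, v in sorted(counts.items())}}

    stage("te", [te_tsv], do_te)

    # 6. codonfreq ---------------------------------------------------------
    freq_tsv = codon_dir / "codon_freq.tsv"
    comp_json = codon_dir / "comparison.json"

    def do_codon(skip):
        if not skip:
            calls_df = pd.read_csv(calls_tsv, sep="\t")
            anticodons = {
                tid: anticodon_from_name(tid)
                for tid in (calls_df["trna_id"].unique() if len(calls_df) else [])
            }
            anticodons = {t: a for t, a in anticodons.items() if a}
            codon_set = decode_codons(anticodons, wobble=cfg["codon"]["wobble"])
            cds = read_fasta(sim_dir / "cds.fa")
            freqs = codon_frequency_table(cds, codon_set)
            te = pd.read_csv(te_tsv, sep="\t", index_col="gene_id")
            df = pd.DataFrame({"m7g_codon_freq": freqs, "te_class": te["te_class"]})
            df.to_csv(freq_tsv, sep="\t", index_label="gene_id")
            by_class = {
                str(c): sub["m7g_codon_freq"].to_numpy()
                for c, sub in df[df["te_class"] != "filtered"].groupby("te_class")
                if len(sub) >= 2
            }
            if "TE-down" in by_class and len(by_class) >= 2:
                comp = compare_groups(
                    by_class, reference="TE-down", method=cfg["codon"]["method"],
                    n_perm=cfg["codon"]["n_perm"], seed=seed + 7,
                )
                payload = comp.to_dict()
            else:
                payload = {"note": "too few classes with n >= 2 for a comparison"}
            with open(comp_json, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
        with open(comp_json) as fh:
            payload = json.load(fh)
        return {"comparison": payload}

    stage("codonfreq", [freq_tsv, comp_json], do_codon)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
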