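"""Translation-efficiency analysis from input and RNC count tables.

TE of a gene is the ratio of its FPKM in the ribosome nascent-chain (RNC)
fraction to its FPKM in total (input) RNA; the knockdown/control log2 TE
change classifies genes into TE-down / TE-up / TE-non. Genes with input FPKM
below a floor in any condition, or with an undefined TE, are set aside as
"filtered".
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TE_CLASSES = ("TE-down", "TE-up", "TE-non", "filtered")
DEFAULT_LOG2FC_THRESHOLD = 1.0
DEFAULT_MIN_INPUT_FPKM = 1.0


def fpkm(counts, lengths, library_total: float) -> np.ndarray | pd.Series:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``FPKM = counts * 1e9 / (library_total * length)`` with lengths in nt.
    """
    counts = np.asarray(counts, dtype=float) if not isinstance(counts, pd.Series) else counts.astype(float)
    lengths = np.asarray(lengths, dtype=float) if not isinstance(lengths, pd.Series) else lengths.astype(float)
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if np.any(np.asarray(lengths) <= 0):
        raise ValueError("transcript lengths must be positive")
    return counts * 1e9 / (library_total * lengths)


def translation_efficiency(fpkm_rnc, fpkm_input, min_input_fpkm: float = DEFAULT_MIN_INPUT_FPKM):
    """TE = FPKM(RNC) / FPKM(input); returns ``(te, filtered_mask)``.

    Genes with input FPKM below ``min_input_fpkm`` (or zero) are flagged
    filtered; their TE is NaN.
    """
    fpkm_rnc = np.asarray(fpkm_rnc, dtype=float)
    fpkm_input = np.asarray(fpkm_input, dtype=float)
    filtered = (fpkm_input < min_input_fpkm) | (fpkm_input <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(filtered, np.nan, fpkm_rnc / np.where(fpkm_input > 0, fpkm_input, np.nan))
    return te, filtered


def classify_te(te_kd, te_ctrl, log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD) -> np.ndarray:
    """TE-down if log2(te_kd/te_ctrl) <= -threshold, TE-up if >= +threshold,
    else TE-non; non-finite log2 changes are labelled filtered."""
    te_kd = np.asarray(te_kd, dtype=float)
    te_ctrl = np.asarray(te_ctrl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(te_kd / te_ctrl)
    labels = np.full(lfc.shape, "TE-non", dtype=object)
    labels[lfc <= -log2fc_threshold] = "TE-down"
    labels[lfc >= log2fc_threshold] = "TE-up"
    labels[~np.isfinite(lfc)] = "filtered"
    return labels


def _condition_columns(df: pd.DataFrame, cond: str) -> list[str]:
    cols = [c for c in df.columns if c == cond or c.startswith(f"{cond}_")]
    if not cols:
        raise ValueError(f"no columns for condition {cond!r} in {list(df.columns)}")
    return cols


def build_te_table(
    input_counts: pd.DataFrame,
    rnc_counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    conditions: tuple[str, str] = ("ctrl", "kd"),
    log2fc_threshold: float = DEFAULT_LOG2FC_THRESHOLD,
    min_input_fpkm: float = DEFAULT_MIN_INPUT_FPKM,
) -> pd.DataFrame:
    """Full per-gene TE table for a knockdown/control comparison.

    Count tables are gene-indexed with one column per library named
    ``<condition>`` or ``<condition>_rep<k>``; replicate FPKMs are averaged
    per condition. Library totals are the column sums (mapped fragments).
    """
    genes = input_counts.index
    if not genes.equals(rnc_counts.index):
        raise ValueError("input and RNC tables must share the same gene universe")
    lengths = pd.Series(lengths).reindex(genes)
    if lengths.isna().any():
        raise ValueError("missing transcript lengths for some genes")
    ctrl, kd = conditions

    def mean_fpkm(df: pd.DataFrame, cond: str) -> pd.Series:
        cols = _condition_columns(df, cond)
        vals = [fpkm(df[c], lengths, float(df[c].sum())) for c in cols]
        return pd.Series(np.mean(vals, axis=0), index=genes)

    out = pd.DataFrame(index=genes)
    out["length"] = lengths
    out["fpkm_input_ctrl"] = mean_fpkm(input_counts, ctrl)
    out["fpkm_input_kd"] = mean_fpkm(input_counts, kd)
    out["fpkm_rnc_ctrl"] = mean_fpkm(rnc_counts, ctrl)
    out["fpkm_rnc_kd"] = mean_fpkm(rnc_counts, kd)

    te_ctrl, filt_c = translation_efficiency(out["fpkm_rnc_ctrl"], out["fpkm_input_ctrl"], min_input_fpkm)
    te_kd, filt_k = translation_efficiency(out["fpkm_rnc_kd"], out["fpkm_input_kd"], min_input_fpkm)
    out["te_ctrl"] = te_ctrl
    out["te_kd"] = te_kd
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_te_change"] = np.log2(out["te_kd"] / out["te_ctrl"])
    labels = classify_te(out["te_kd"], out["te_ctrl"], log2fc_threshold)
    labels[np.asarray(filt_c | filt_k)] = "filtered"
    out["te_class"] = labels
    return out


def intersect_te_down(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[set, dict]:
    """Overlap of two TE-down gene sets plus Venn counts."""
    a, b = set(set_a), set(set_b)
    both = a & b
    venn = {"only_a": len(a - b), "only_b": len(b - a), "both": len(both)}
    return both, venn


def write_count_table(counts: pd.DataFrame, lengths: Mapping[str, int], path) -> None:
    df = counts.copy()
    df.insert(0, "length", pd.Series(lengths).reindex(df.index))
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_count_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a TSV count table; returns ``(counts, lengths)``."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise ValueError(f"{path}: count table lacks a 'length' column")
    lengths = df.pop("length")
    if (lengths <= 0).any():
        raise ValueError(f"{path}: non-positive transcript length")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df, lengths
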