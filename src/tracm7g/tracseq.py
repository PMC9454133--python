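"""TRAC-seq analysis: read mapping, cleavage statistics, m7G site calling,
consensus motif extraction and tRNA expression quantification.

The chemistry leaves a signature at methylated positions: in treated
libraries the tRNA is cleaved at the m7G site, so sequencing reads pile up
*starting* exactly there. Per position we form the cleavage ratio
(reads starting at the site / read depth at the site, pseudocounted) in the
treated and untreated libraries and score the contrast; sites with
score > 3 and a treated cleavage rate > 0.1 at a reference G are called.

Two score modes are provided:

* ``log_quotient`` (default): ``log2(ratio_treat / ratio_nontreat)`` — large
  when treatment induces cleavage, as the assay intends;
* ``as_printed``: ``log2(ratio_treat) / log2(ratio_nontreat)``, the quotient
  of logarithms, retained for fidelity to the published formula.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import ConfigurationError, transcribe
from .trnaref import MatureTRNA

logger = logging.getLogger(__name__)

SCORE_MODES = ("log_quotient", "as_printed")
DEFAULT_MIN_SCORE = 3.0
DEFAULT_MIN_RATE = 0.1
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_DEPTH = 20


# ---------------------------------------------------------------------------
# mapping

@dataclass
class AlignmentProfile:
    """Per-tRNA read-depth and read-start pileups for one library.

    Multi-mapping reads contribute fractional weight 1/k to each of their k
    equally best placements, so ``sum of starts over all tRNAs ==
    total_mapped`` and ``starts[i] <= depth[i]`` everywhere.
    """

    depth: dict[str, np.ndarray]
    starts: dict[str, np.ndarray]
    total_mapped: float = 0.0
    n_reads: int = 0
    n_unmapped: int = 0

    @classmethod
    def empty(cls, refs: Mapping[str, str]) -> "AlignmentProfile":
        return cls(
            depth={r: np.zeros(len(s)) for r, s in refs.items()},
            starts={r: np.zeros(len(s)) for r, s in refs.items()},
        )

    def __add__(self, other: "AlignmentProfile") -> "AlignmentProfile":
        if set(self.depth) != set(other.depth):
            raise ValueError("profiles cover different reference sets")
        return AlignmentProfile(
            depth={r: self.depth[r] + other.depth[r] for r in self.depth},
            starts={r: self.starts[r] + other.starts[r] for r in self.starts},
            total_mapped=self.total_mapped + other.total_mapped,
            n_reads=self.n_reads + other.n_reads,
            n_unmapped=self.n_unmapped + other.n_unmapped,
        )

    def trna_weights(self) -> pd.Series:
        """Total assigned read weight per tRNA (each read has one start)."""
        return pd.Series({r: float(s.sum()) for r, s in self.starts.items()}).sort_index()


def read_fastq_seqs(path) -> list[str]:
    """Sequences from an uncompressed FASTQ file (qualities ignored)."""
    seqs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip())
    return seqs


def _normalize_refs(refs) -> dict[str, str]:
    if hasattr(refs, "items"):
        items = refs.items()
    else:
        items = ((m.id, m.seq) for m in refs)
    return {rid: transcribe(str(seq)) for rid, seq in items}


def _placements(seq: str, refs: dict[str, str], max_mismatches: int, seed_len: int):
    """All equally best (ref, offset) placements of one read, or []."""
    n = len(seq)
    exact = []
    for rid, ref in refs.items():
        at = ref.find(seq)
        while at != -1:
            exact.append((rid, at))
            at = ref.find(seq, at + 1)
    if exact or max_mismatches == 0:
        return exact, 0
    # seed-and-extend: exact seed, mismatches tolerated in the extension
    seed = seq[:seed_len]
    best_mm, best = max_mismatches + 1, []
    for rid, ref in refs.items():
        at = ref.find(seed)
        while at != -1:
            if at + n <= len(ref):
                mm = 0
                for a, b in zip(seq[seed_len:], ref[at + seed_len:at + n]):
                    if a != b:
                        mm += 1
                        if mm > max_mismatches:
                            break
                if mm <= max_mismatches:
                    if mm < best_mm:
                        best_mm, best = mm, [(rid, at)]
                    elif mm == best_mm:
                        best.append((rid, at))
            at = ref.find(seed, at + 1)
    return (best, best_mm) if best else ([], 0)


def map_reads(
    reads: Iterable[str],
    refs: Mapping[str, str] | Sequence[MatureTRNA],
    max_mismatches: int = 0,
    seed_len: int = 18,
) -> AlignmentProfile:
    """Map small-RNA reads to mature tRNA references.

    ``reads`` is an iterable of sequences (DNA or RNA; T/U interchangeable).
    Reads shorter than ``seed_len`` are unmapped. Ties are split fractionally
    across all equally best placements.
    """
    refs = _normalize_refs(refs)
    if not refs:
        raise ConfigurationError("refs: empty reference set")
    prof = AlignmentProfile.empty(refs)
    counts = Counter(transcribe(r) for r in reads)
    prof.n_reads = sum(counts.values())
    for seq, c in counts.items():
        if len(seq) < seed_len:
            prof.n_unmapped += c
            continue
        places, _ = _placements(seq, refs, max_mismatches, seed_len)
        if not places:
            prof.n_unmapped += c
            continue
        w = c / len(places)
        for rid, at in places:
            prof.depth[rid][at:at + len(seq)] += w
            prof.starts[rid][at] += w
        prof.total_mapped += c
    if prof.n_unmapped:
        logger.info("map_reads: %d/%d reads unmapped", prof.n_unmapped, prof.n_reads)
    return prof


# ---------------------------------------------------------------------------
# cleavage statistics

def cleavage_ratio(
    starts: np.ndarray,
    depth: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_depth: float = DEFAULT_MIN_DEPTH,
) -> np.ndarray:
    """Pseudocounted reads-starting / read-depth per position.

    Positions with depth below ``min_depth`` are masked (NaN) and excluded
    from calling.
    """
    starts = np.asarray(starts, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if starts.shape != depth.shape:
        raise ValueError("starts and depth must have the same length")
    if (starts < 0).any() or (depth < 0).any():
        raise ValueError("negative counts in starts/depth")
    ratio = (starts + pseudocount) / (depth + pseudocount)
    ratio[depth < min_depth] = np.nan
    return ratio


def cleavage_score(
    ratio_treat: np.ndarray,
    ratio_nontreat: np.ndarray,
    mode: str = "log_quotient",
) -> np.ndarray:
    """Per-site contrast of treated vs untreated cleavage ratios.

    NaN ratios (masked positions) propagate. Under ``as_printed`` an
    untreated ratio of exactly 1 is clamped to 1 - 1e-9 to keep the
    denominator finite.
    """
    if mode not in SCORE_MODES:
        raise ConfigurationError(f"mode: unknown score mode {mode!r}; choose from {SCORE_MODES}")
    rt = np.asarray(ratio_treat, dtype=float)
    rn = np.asarray(ratio_nontreat, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "log_quotient":
            return np.log2(rt / rn)
        rn = np.where(rn >= 1.0, 1.0 - 1e-9, rn)
        return np.log2(rt) / np.log2(rn)


def build_cleavage_table(
    treated: AlignmentProfile,
    untreated: AlignmentProfile,
    refs: Mapping[str, str] | Sequence[MatureTRNA],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_depth: float = DEFAULT_MIN_DEPTH,
    mode: str = "log_quotient",
) -> pd.DataFrame:
    """Per-site cleavage table over all positions passing the depth filter
    in both libraries. The cleavage *rate* used for calling is the treated
    cleavage ratio."""
    refs = _normalize_refs(refs)
    frames = []
    for rid in sorted(refs):
        seq = refs[rid]
        rt = cleavage_ratio(treated.starts[rid], treated.depth[rid], pseudocount, min_depth)
        rn = cleavage_ratio(untreated.starts[rid], untreated.depth[rid], pseudocount, min_depth)
        score = cleavage_score(rt, rn, mode)
        keep = ~np.isnan(rt) & ~np.isnan(rn)
        if not keep.any():
            continue
        idx = np.nonzero(keep)[0]
        frames.append(
            pd.DataFrame(
                {
                    "trna_id": rid,
                    "position": idx,
                    "base": [seq[i] for i in idx],
                    "ratio_treat": rt[idx],
                    "ratio_nontreat": rn[idx],
                    "rate": rt[idx],
                    "score": score[idx],
                    "depth_treat": treated.depth[rid][idx],
                    "depth_nontreat": untreated.depth[rid][idx],
                    "starts_treat": treated.starts[rid][idx],
                    "starts_nontreat": untreated.starts[rid][idx],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "trna_id", "position", "base", "ratio_treat", "ratio_nontreat",
                "rate", "score", "depth_treat", "depth_nontreat",
                "starts_treat", "starts_nontreat",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# site calling and motif

@dataclass(frozen=True)
class SiteCall:
    """A called candidate m7G site."""

    trna_id: str
    position: int
    score: float
    rate: float
    context: str  # 5-mer centered on the site, N-padded at reference ends
    is_g: bool
    depth_treat: float = 0.0
    depth_nontreat: float = 0.0


def _context(seq: str, pos: int, half: int = 2) -> str:
    left = seq[max(0, pos - half):pos]
    right = seq[pos + 1:pos + 1 + half]
    return "N" * (half - len(left)) + left + seq[pos] + right + "N" * (half - len(right))


def call_sites(
    table: pd.DataFrame,
    refs: Mapping[str, str] | Sequence[MatureTRNA],
    min_score: float = DEFAULT_MIN_SCORE,
    min_rate: float = DEFAULT_MIN_RATE,
    require_g: bool = True,
) -> list[SiteCall]:
    """Apply the calling thresholds (strict inequalities: score > 3, rate > 0.1).

    With ``require_g`` (default) only reference G positions are eligible,
    matching the m7G chemistry; disable to audit off-G signal.
    """
    refs = _normalize_refs(refs)
    hits = table[(table["score"] > min_score) & (table["rate"] > min_rate)]
    calls = []
    for row in hits.itertuples(index=False):
        seq = refs[row.trna_id]
        is_g = seq[row.position] == "G"
        if require_g and not is_g:
            continue
        calls.append(
            SiteCall(
                trna_id=row.trna_id,
                position=int(row.position),
                score=float(row.score),
                rate=float(row.rate),
                context=_context(seq, int(row.position)),
                is_g=is_g,
                depth_treat=float(row.depth_treat),
                depth_nontreat=float(row.depth_nontreat),
            )
        )
    return sorted(calls, key=lambda c: (c.trna_id, c.position))


def site_calls_frame(calls: Sequence[SiteCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls]) if calls else pd.DataFrame(
        columns=["trna_id", "position", "score", "rate", "context", "is_g",
                 "depth_treat", "depth_nontreat"]
    )


from ._seq import BASES_TO_IUPAC  # noqa: E402  (kept near its single use)


def consensus_motif(calls: Sequence[SiteCall] | Sequence[str], freq_floor: float = 0.05) -> str:
    """Minimal IUPAC consensus over the call contexts.

    Per position, every base observed at frequency >= ``freq_floor`` is
    admitted and the smallest covering IUPAC code is reported. With a floor
    of 0 the consensus is guaranteed to match every input context; a positive
    floor may drop rare bases (and hence rare contexts).
    """
    if len(calls) == 0:
        raise ValueError("consensus_motif needs at least one call")
    contexts = [c.context if isinstance(c, SiteCall) else str(c).upper() for c in calls]
    width = len(contexts[0])
    if any(len(c) != width for c in contexts):
        raise ValueError("contexts differ in length")
    out = []
    for i in range(width):
        col = [c[i] for c in contexts if c[i] != "N"]
        if not col:
            out.append("N")
            continue
        counts = Counter(col)
        total = sum(counts.values())
        admitted = {b for b, k in counts.items() if k / total >= freq_floor}
        if not admitted:  # floor above every frequency; keep the modal base
            admitted = {counts.most_common(1)[0][0]}
        out.append(BASES_TO_IUPAC[frozenset(admitted)])
    return "".join(out)


# ---------------------------------------------------------------------------
# expression

def quantify_expression(
    profile_kd: AlignmentProfile,
    profile_ctrl: AlignmentProfile,
    calls: Sequence[SiteCall] = (),
    pseudo_cpm: float = 0.5,
) -> pd.DataFrame:
    """tRNA abundance (CPM over tRNA-mapped weight) and knockdown log2FC.

    Uses the chemically untreated (input) libraries. CPM sums to 1e6 per
    library; ``log2fc = log2((cpm_kd + c) / (cpm_ctrl + c))`` with c = 0.5 CPM.
    A tRNA is flagged m7G-modified when it owns at least one called site.
    """
    out = {}
    for name, prof in (("knockdown", profile_kd), ("control", profile_ctrl)):
        w = prof.trna_weights()
        total = w.sum()
        if total <= 0:
            raise ValueError(f"no mapped reads in {name} library")
        out[f"cpm_{name}"] = 1e6 * w / total
    df = pd.DataFrame(out)
    df.index.name = "trna_id"
    df["log2fc"] = np.log2((df["cpm_knockdown"] + pseudo_cpm) / (df["cpm_control"] + pseudo_cpm))
    modified = {c.trna_id for c in calls}
    df["is_m7g"] = df.index.isin(modified)
    return df


def count_modified_trnas(calls: Sequence[SiteCall]) -> tuple[int, pd.DataFrame]:
    """Number of distinct tRNAs with >= 1 called site, plus a per-tRNA summary."""
    if not calls:
        return 0, pd.DataFrame(columns=["trna_id", "isoacceptor", "n_sites", "positions"])
    rows: dict[str, dict] = {}
    for c in calls:
        entry = rows.setdefault(
            c.trna_id,
            {"trna_id": c.trna_id, "isoacceptor": "-".join(c.trna_id.split("-")[1:3]),
             "n_sites": 0, "positions": []},
        )
        entry["n_sites"] += 1
        entry["positions"].append(c.position)
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["trna_id"]))
    df["positions"] = df["positions"].map(lambda p: ",".join(map(str, p)))
    return len(rows), df
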