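"""Independent brute-force oracles for mapping and cleavage statistics.

Everything here is written for transparency, not speed: full scans over all
references and offsets, and plain-Python arithmetic, deliberately sharing no
code with the package implementation.
"""

from __future__ import annotations

import math


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def brute_placements(read: str, refs: dict[str, str], max_mismatches: int = 0):
    """All equally best (ref_id, offset) placements by exhaustive scan."""
    read = _rna(read)
    n = len(read)
    best_mm = max_mismatches + 1
    best = []
    for rid in refs:
        ref = _rna(refs[rid])
        for off in range(0, len(ref) - n + 1):
            mm = sum(1 for a, b in zip(read, ref[off:off + n]) if a != b)
            if mm < best_mm:
                best_mm, best = mm, [(rid, off)]
            elif mm == best_mm and mm <= max_mismatches:
                best.append((rid, off))
    return best if best_mm <= max_mismatches else []


def brute_profiles(reads, refs: dict[str, str], min_len: int = 18, max_mismatches: int = 0):
    """Depth/starts pileups per reference from brute-force placements."""
    depth = {r: [0.0] * len(refs[r]) for r in refs}
    starts = {r: [0.0] * len(refs[r]) for r in refs}
    mapped = 0.0
    cache: dict[str, list] = {}
    for read in reads:
        read = _rna(read)
        if len(read) < min_len:
            continue
        if read not in cache:
            cache[read] = brute_placements(read, refs, max_mismatches)
        places = cache[read]
        if not places:
            continue
        w = 1.0 / len(places)
        mapped += 1.0
        for rid, off in places:
            starts[rid][off] += w
            for i in range(off, off + len(read)):
                depth[rid][i] += w
    return depth, starts, mapped


def brute_ratio(starts, depth, pseudocount=0.5, min_depth=20):
    out = []
    for s, d in zip(starts, depth):
        out.append(float("nan") if d < min_depth else (s + pseudocount) / (d + pseudocount))
    return out


def brute_score(ratio_treat, ratio_nontreat, mode="log_quotient"):
    out = []
    for rt, rn in zip(ratio_treat, ratio_nontreat):
        if math.isnan(rt) or math.isnan(rn):
            out.append(float("nan"))
        elif mode == "log_quotient":
            out.append(math.log2(rt / rn))
        else:
            rn_ = min(rn, 1.0 - 1e-9)
            out.append(math.log2(rt) / math.log2(rn_))
    return out
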