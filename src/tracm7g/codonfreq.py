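"""Codons decoded by m7G tRNAs, per-CDS codon frequency, and the TE-class
comparison statistic.

The anticodon of each m7G tRNA determines the codon(s) it decodes: by
default the strict Watson-Crick reverse complement; optionally wobble at
position 34 (the anticodon 5' base pairing with the codon 3' base), where
G34 also reads the U-ending codon and U34 also reads the G-ending codon.

Per-gene frequencies of m7G-decoded codons are compared across TE classes
with a one-way ANOVA omnibus test and contrasts of every class against a
reference class (TE-down), family-wise adjusted either by a seeded
permutation max-|t| null (default) or by classical Dunnett critical values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import ConfigurationError, STOP_CODONS, revcomp_rna, transcribe

logger = logging.getLogger(__name__)

WOBBLE_MODES = ("strict", "wobble34")


@dataclass(frozen=True)
class CodonSet:
    """Sense codons (RNA alphabet) decoded by a set of tRNAs."""

    codons: frozenset[str]
    provenance: tuple[tuple[str, str, str], ...]  # (trna_id, anticodon, rule)

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons

    def __len__(self) -> int:
        return len(self.codons)


def decode_codons(
    anticodons: Mapping[str, str] | Iterable[tuple[str, str]],
    wobble: str = "strict",
) -> CodonSet:
    """Codons decoded by the given anticodons (``{trna_id: anticodon}``).

    ``strict``: codon = reverse complement of the anticodon. ``wobble34``
    additionally admits third-position pairings (G34 reads both Y-ending
    codons, U34 both R-ending codons); inosine is out of scope.
    """
    if wobble not in WOBBLE_MODES:
        raise ConfigurationError(f"wobble: unknown mode {wobble!r}; choose from {WOBBLE_MODES}")
    items = anticodons.items() if hasattr(anticodons, "items") else anticodons
    codons: set[str] = set()
    prov: list[tuple[str, str, str]] = []
    for tid, ac in items:
        ac = transcribe(str(ac).upper())
        if len(ac) != 3 or any(b not in "ACGU" for b in ac):
            raise ValueError(f"{tid}: invalid anticodon {ac!r}")
        wc = revcomp_rna(ac)
        codons.add(wc)
        prov.append((tid, ac, "watson-crick"))
        if wobble == "wobble34":
            extra = {"G": "U", "U": "G"}.get(ac[0])  # wobble codon third base
            if extra:
                codons.add(wc[:2] + extra)
                prov.append((tid, ac, f"wobble34:{ac[0]}34"))
    codons -= STOP_CODONS
    return CodonSet(codons=frozenset(codons), provenance=tuple(prov))


def codon_frequency(cds: str, codon_set: CodonSet | Iterable[str], exclude_stop: bool = True) -> float:
    """Fraction of codons of a CDS that belong to ``codon_set``.

    The CDS may be DNA or RNA; its length must be divisible by 3. The
    terminal stop codon is excluded from the denominator when flagged.
    """
    seq = transcribe(str(cds).upper())
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if exclude_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        return 0.0
    members = codon_set.codons if isinstance(codon_set, CodonSet) else frozenset(
        transcribe(c.upper()) for c in codon_set
    )
    return sum(c in members for c in codons) / len(codons)


def codon_frequency_table(
    cds_seqs: Mapping[str, str], codon_set: CodonSet, exclude_stop: bool = True
) -> pd.Series:
    """Per-gene frequencies; genes with length not divisible by 3 are logged
    and excluded."""
    out = {}
    for gid, seq in cds_seqs.items():
        try:
            out[gid] = codon_frequency(seq, codon_set, exclude_stop)
        except ValueError as exc:
            logger.warning("skipping %s: %s", gid, exc)
    s = pd.Series(out, name="m7g_codon_freq")
    s.index.name = "gene_id"
    return s


# ---------------------------------------------------------------------------
# group comparison

@dataclass
class GroupComparison:
    """Per-class summaries, omnibus ANOVA and contrasts vs the reference class."""

    groups: pd.DataFrame        # index class; columns n, mean, sd
    f_stat: float
    p_anova: float
    contrasts: pd.DataFrame     # index class; columns t, p_raw, p_adj
    reference: str
    method: str

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "method": self.method,
            "f_stat": self.f_stat,
            "p_anova": self.p_anova,
            "groups": {k: row.to_dict() for k, row in self.groups.iterrows()},
            "contrasts": {k: row.to_dict() for k, row in self.contrasts.iterrows()},
        }


def _contrast_t(y: np.ndarray, slices: list[slice], ref_idx: int) -> np.ndarray:
    """Pooled-variance t statistics of each non-reference group vs the reference.

    ``y`` may be (n,) or (B, n) for B permutations; returns (k-1,) or (B, k-1).
    """
    y2 = np.atleast_2d(y)
    k = len(slices)
    n_total = y2.shape[1]
    means = np.stack([y2[:, s].mean(axis=1) for s in slices], axis=1)
    ssw = np.stack(
        [((y2[:, s] - means[:, [i]]) ** 2).sum(axis=1) for i, s in enumerate(slices)], axis=1
    ).sum(axis=1)
    df = n_total - k
    s2 = ssw / df
    ns = np.array([s.stop - s.start for s in slices], dtype=float)
    ts = []
    for i in range(k):
        if i == ref_idx:
            continue
        se = np.sqrt(s2 * (1.0 / ns[i] + 1.0 / ns[ref_idx]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (means[:, i] - means[:, ref_idx]) / se
        ts.append(np.where(se > 0, t, 0.0))
    out = np.stack(ts, axis=1)
    return out[0] if y.ndim == 1 else out


def compare_groups(
    freq_by_class: Mapping[str, Sequence[float]],
    reference: str = "TE-down",
    method: str = "permutation",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> GroupComparison:
    """Compare per-gene codon frequencies across TE classes.

    ``permutation`` (default): family-wise adjusted p-values from a seeded
    label-permutation max-|t| null; raw p-values use each contrast's own
    permutation distribution, so adjusted >= raw by construction.
    ``dunnett``: classical many-to-one comparisons (scipy), raw p from the
    pooled t distribution.
    """
    if method not in ("permutation", "dunnett"):
        raise ConfigurationError(f"method: unknown comparison method {method!r}")
    classes = list(freq_by_class)
    if reference not in classes:
        raise ValueError(f"reference class {reference!r} not among {classes}")
    if len(classes) < 2:
        raise ValueError("need at least two classes to compare")
    arrays = {c: np.asarray(freq_by_class[c], dtype=float) for c in classes}
    for c, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"class {c!r} has n={a.size} < 2 observations")

    groups = pd.DataFrame(
        {
            "n": {c: int(a.size) for c, a in arrays.items()},
            "mean": {c: float(a.mean()) for c, a in arrays.items()},
            "sd": {c: float(a.std(ddof=1)) for c, a in arrays.items()},
        }
    ).loc[classes]

    y = np.concatenate([arrays[c] for c in classes])
    slices, pos = [], 0
    for c in classes:
        slices.append(slice(pos, pos + arrays[c].size))
        pos += arrays[c].size
    ref_idx = classes.index(reference)
    others = [c for c in classes if c != reference]

    if np.allclose(y, y[0]):
        # degenerate: no variation anywhere
        contrasts = pd.DataFrame({"t": 0.0, "p_raw": 1.0, "p_adj": 1.0}, index=others)
        contrasts.index.name = "class"
        return GroupComparison(groups, 0.0, 1.0, contrasts, reference, method)

    f_stat, p_anova = stats.f_oneway(*(arrays[c] for c in classes))
    t_obs = _contrast_t(y, slices, ref_idx)

    if method == "dunnett":
        df = y.size - len(classes)
        p_raw = 2.0 * stats.t.sf(np.abs(t_obs), df)
        res = stats.dunnett(
            *(arrays[c] for c in others), control=arrays[reference],
        )
        p_adj = np.maximum(np.asarray(res.pvalue), p_raw)
    else:
        rng = np.random.default_rng(seed)
        exceed_own = np.zeros(len(others))
        exceed_max = np.zeros(len(others))
        done = 0
        while done < n_perm:
            block = min(2000, n_perm - done)
            perm = rng.permuted(np.tile(y, (block, 1)), axis=1)
            t_perm = np.abs(_contrast_t(perm, slices, ref_idx))
            exceed_own += (t_perm >= np.abs(t_obs)).sum(axis=0)
            exceed_max += (t_perm.max(axis=1)[:, None] >= np.abs(t_obs)).sum(axis=0)
            done += block
        p_raw = (1.0 + exceed_own) / (1.0 + n_perm)
        p_adj = (1.0 + exceed_max) / (1.0 + n_perm)

    contrasts = pd.DataFrame(
        {"t": t_obs, "p_raw": p_raw, "p_adj": p_adj}, index=pd.Index(others, name="class")
    )
    return GroupComparison(groups, float(f_stat), float(p_anova), contrasts, reference, method)
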