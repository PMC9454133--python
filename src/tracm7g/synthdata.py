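"""Synthetic inputs for every pipeline stage, with machine-readable ground truth.

The generator emulates the statistical structure the analyses assume:

* a tRNA gene set (some intron-containing, both strands, gtRNAdb-style names)
  in which a chosen subset carries an m7G site at a fixed mature position
  whose +/-2 context is drawn from the DURGY pattern (with G at the site);
* four small-RNA libraries (chemically treated / untreated x knockdown /
  control): treated libraries gain read starts exactly at planted sites,
  untreated libraries have background starts only, and modified tRNAs are
  down-weighted under knockdown;
* a coding transcriptome in which a fraction of genes is enriched for codons
  decoded by the m7G tRNAs; exactly those genes lose translation efficiency
  under knockdown in the simulated input/RNC count tables.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._seq import (
    ConfigurationError,
    DNA_BASES,
    SENSE_CODONS,
    reverse_transcribe,
    revcomp_dna,
    revcomp_rna,
    transcribe,
)
from .trnaref import TRNAGeneRecord, build_mature, write_annotation

logger = logging.getLogger(__name__)


class GenerationError(RuntimeError):
    """Raised when a simulation request is internally inconsistent."""


LIBRARY_CHEMISTRIES = ("treated", "untreated")
LIBRARY_CONDITIONS = ("ctrl", "kd")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults define the study conditions.

    ``m7g_position`` is 0-based on the mature tRNA (45 = position 46 in
    conventional 1-based tRNA numbering). Fold changes are multiplicative
    factors in (0, 1] applied under knockdown.
    """

    seed: int = 0
    # tRNA set
    n_trnas: int = 150
    n_modified: int = 21
    m7g_position: int = 45
    min_mature_len: int = 70
    max_mature_len: int = 90
    intron_fraction: float = 0.25
    flank_len: int = 100
    # cleavage libraries
    cleavage_prob_site: float = 0.6
    background_cleavage: float = 0.005
    reads_per_library: int = 50_000
    knockdown_fc: float = 0.5
    replicates: int = 1
    max_read_len: int = 75
    # transcriptome / counts
    n_genes: int = 2000
    enriched_fraction: float = 0.1
    te_up_fraction: float = 0.05
    te_effect_fc: float = 0.5
    codon_margin: float = 0.1
    depth_per_library: int = 2_000_000
    nb_dispersion: float = 0.01

    def validate(self) -> None:
        def bad(name, why):
            raise ConfigurationError(f"{name}: {why} (got {getattr(self, name)!r})")

        for name in ("n_trnas", "reads_per_library", "n_genes", "depth_per_library", "replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                bad(name, "must be a positive integer")
        if not isinstance(self.n_modified, (int, np.integer)) or not 0 <= self.n_modified <= self.n_trnas:
            bad("n_modified", "must be an integer in [0, n_trnas]")
        for name in ("cleavage_prob_site", "background_cleavage", "enriched_fraction", "te_up_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, "must be a probability in [0, 1]")
        if self.enriched_fraction + self.te_up_fraction > 1.0:
            bad("te_up_fraction", "enriched_fraction + te_up_fraction must be <= 1")
        for name in ("knockdown_fc", "te_effect_fc"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                bad(name, "must be in (0, 1]")
        if self.nb_dispersion < 0:
            bad("nb_dispersion", "must be >= 0")
        if self.codon_margin < 0:
            bad("codon_margin", "must be >= 0")
        if not 60 <= self.min_mature_len <= self.max_mature_len:
            bad("min_mature_len", "need 60 <= min_mature_len <= max_mature_len")
        if self.flank_len < 0:
            bad("flank_len", "must be >= 0")
        if self.max_read_len < 30:
            bad("max_read_len", "must be >= 30")
        if not 2 <= self.m7g_position <= self.min_mature_len - 18:
            bad("m7g_position", "must satisfy 2 <= position <= min_mature_len - 18 so that "
                "the DURGY context fits and site-start fragments remain mappable")
        if self.n_modified > len(SENSE_CODONS):
            bad("n_modified", "cannot exceed the number of distinct sense codons")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, recomputable from emitted files."""

    modified_trna_ids: set[str] = field(default_factory=set)
    site_positions: dict[str, int] = field(default_factory=dict)
    true_abundance_fc: dict[str, float] = field(default_factory=dict)
    modified_anticodons: dict[str, str] = field(default_factory=dict)
    te_class_truth: dict[str, str] = field(default_factory=dict)
    true_codon_freq: dict[str, float] = field(default_factory=dict)
    m7g_codons: tuple[str, ...] = ()

    def to_json(self, path) -> None:
        data = dataclasses.asdict(self)
        data["modified_trna_ids"] = sorted(self.modified_trna_ids)
        data["m7g_codons"] = sorted(self.m7g_codons)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["modified_trna_ids"] = set(data["modified_trna_ids"])
        data["m7g_codons"] = tuple(data["m7g_codons"])
        return cls(**data)


# standard-code translation for naming simulated tRNAs
_AA3 = {
    "UUU": "Phe", "UUC": "Phe", "UUA": "Leu", "UUG": "Leu", "CUU": "Leu",
    "CUC": "Leu", "CUA": "Leu", "CUG": "Leu", "AUU": "Ile", "AUC": "Ile",
    "AUA": "Ile", "AUG": "Met", "GUU": "Val", "GUC": "Val", "GUA": "Val",
    "GUG": "Val", "UCU": "Ser", "UCC": "Ser", "UCA": "Ser", "UCG": "Ser",
    "CCU": "Pro", "CCC": "Pro", "CCA": "Pro", "CCG": "Pro", "ACU": "Thr",
    "ACC": "Thr", "ACA": "Thr", "ACG": "Thr", "GCU": "Ala", "GCC": "Ala",
    "GCA": "Ala", "GCG": "Ala", "UAU": "Tyr", "UAC": "Tyr", "CAU": "His",
    "CAC": "His", "CAA": "Gln", "CAG": "Gln", "AAU": "Asn", "AAC": "Asn",
    "AAA": "Lys", "AAG": "Lys", "GAU": "Asp", "GAC": "Asp", "GAA": "Glu",
    "GAG": "Glu", "UGU": "Cys", "UGC": "Cys", "UGG": "Trp", "CGU": "Arg",
    "CGC": "Arg", "CGA": "Arg", "CGG": "Arg", "AGU": "Ser", "AGC": "Ser",
    "AGA": "Arg", "AGG": "Arg", "GGU": "Gly", "GGC": "Gly", "GGA": "Gly",
    "GGG": "Gly",
}


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = DNA_BASES) -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), size=n)])


def simulate_trna_set(config: SimConfig) -> tuple[list[TRNAGeneRecord], PlantedTruth]:
    """Generate the tRNA gene set and the planted m7G truth.

    Modified tRNAs carry a G at the planted mature position with a +/-2
    context drawn from DURGY (D-U-G-G-Y with the central R realized as G, the
    methylated base). Each modified tRNA gets a distinct anticodon so the
    decoded codon set is well defined; unmodified tRNAs draw anticodons from
    the complement.
    """
    config.validate()
    rng = config.rng(0)
    n, k = config.n_trnas, config.n_modified
    modified_idx = set(rng.choice(n, size=k, replace=False).tolist())

    codon_order = rng.permutation(len(SENSE_CODONS))
    modified_codons = [SENSE_CODONS[i] for i in codon_order[:k]]
    other_codons = [SENSE_CODONS[i] for i in codon_order[k:]]

    records: list[TRNAGeneRecord] = []
    truth = PlantedTruth()
    mod_iter = iter(modified_codons)
    pos = config.m7g_position
    for i in range(n):
        is_mod = i in modified_idx
        codon = next(mod_iter) if is_mod else other_codons[rng.integers(0, len(other_codons))]
        anticodon = revcomp_rna(codon)
        mature_len = int(rng.integers(config.min_mature_len, config.max_mature_len + 1))
        body_len = mature_len - 3  # CCA appended at reference build time
        body = list(_random_seq(rng, body_len, "ACGU"))
        # keep an anticodon triplet at the canonical 34-36 region when it
        # does not collide with the planted site context
        ac_start = 33
        if not (ac_start + 3 > pos - 2 and ac_start < pos + 3):
            body[ac_start:ac_start + 3] = list(anticodon)
        if is_mod:
            body[pos - 2] = "AGU"[rng.integers(0, 3)]   # D
            body[pos - 1] = "U"
            body[pos] = "G"                              # the m7G site
            body[pos + 1] = "G"
            body[pos + 2] = "CU"[rng.integers(0, 2)]     # Y
        sense_dna = reverse_transcribe("".join(body))

        introns: tuple[tuple[int, int], ...] = ()
        gene = sense_dna
        if rng.random() < config.intron_fraction:
            ilen = int(rng.integers(10, 21))
            at = int(rng.integers(36, 41))
            gene = sense_dna[:at] + _random_seq(rng, ilen) + sense_dna[at:]
            introns = ((at, at + ilen),)

        up = _random_seq(rng, config.flank_len)
        down = _random_seq(rng, config.flank_len)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            L = len(gene)
            gene_stored = revcomp_dna(gene)
            introns = tuple(sorted((L - e, L - s) for s, e in introns))
            up, down = revcomp_dna(down), revcomp_dna(up)
        else:
            gene_stored = gene

        rid = f"tRNA-{_AA3[codon]}-{reverse_transcribe(anticodon)}-{i + 1}-1"
        records.append(
            TRNAGeneRecord(
                id=rid, gene_seq=gene_stored, intron_intervals=introns, strand=strand,
                anticodon=anticodon, upstream_flank=up, downstream_flank=down,
            )
        )
        truth.true_abundance_fc[rid] = config.knockdown_fc if is_mod else 1.0
        if is_mod:
            truth.modified_trna_ids.add(rid)
            truth.site_positions[rid] = pos
            truth.modified_anticodons[rid] = anticodon
    return records, truth


def simulate_cleavage_libraries(
    genes: list[TRNAGeneRecord], truth: PlantedTruth, config: SimConfig
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Sample the four small-RNA libraries (x replicates).

    Returns ``(reads, counts)`` where ``reads[library]`` is a list of
    ``(name, DNA sequence)`` and ``counts`` is the truth-consistent sidecar
    (library, trna_id, n_reads, n_site_starts). Fragment convention: cleavage
    at mature position i yields a read whose first base is position i; intact
    fragments start at position 0; all reads run toward the 3' end, capped at
    ``max_read_len``.
    """
    if not genes:
        raise GenerationError("empty gene set")
    config.validate()
    rng = config.rng(1)
    matures = {rec.id: build_mature(rec).seq for rec in genes}
    ids = [rec.id for rec in genes]
    for rid in truth.modified_trna_ids:
        site = truth.site_positions[rid]
        if not 0 <= site < len(matures[rid]):
            raise GenerationError(
                f"{rid}: planted site {site} outside mature length {len(matures[rid])}"
            )

    base_w = np.ones(len(ids))
    kd_w = np.array([truth.true_abundance_fc.get(r, 1.0) for r in ids])

    reads: dict[str, list[tuple[str, str]]] = {}
    rows = []
    for rep in range(1, config.replicates + 1):
        for cond in LIBRARY_CONDITIONS:
            for chem in LIBRARY_CHEMISTRIES:
                lib = f"{chem}_{cond}_rep{rep}"
                w = base_w * (kd_w if cond == "kd" else 1.0)
                counts = rng.multinomial(config.reads_per_library, w / w.sum())
                out: list[tuple[str, str]] = []
                serial = 0
                for rid, c in zip(ids, counts):
                    mat = matures[rid]
                    L = len(mat)
                    c = int(c)
                    n_site = 0
                    site = truth.site_positions.get(rid, -1)
                    if chem == "treated" and rid in truth.modified_trna_ids:
                        n_site = int(rng.binomial(c, config.cleavage_prob_site))
                    rest = c - n_site
                    p_int = min(1.0, config.background_cleavage * (L - 1))
                    n_int = int(rng.binomial(rest, p_int))
                    internal = rng.integers(1, L, size=n_int)
                    starts = np.concatenate(
                        [np.full(n_site, site, dtype=int), internal,
                         np.zeros(rest - n_int, dtype=int)]
                    )
                    for s in starts:
                        seq = reverse_transcribe(mat[s:s + config.max_read_len])
                        out.append((f"read_{lib}_{serial:07d}", seq))
                        serial += 1
                    rows.append(
                        {
                            "library": lib, "trna_id": rid, "n_reads": c,
                            "n_site_starts": n_site + int(np.count_nonzero(internal == site)),
                        }
                    )
                reads[lib] = out
    return reads, pd.DataFrame(rows)


def simulate_transcriptome(config: SimConfig, truth: PlantedTruth) -> tuple[dict[str, str], PlantedTruth]:
    """Generate CDS sequences and assign TE-class truth.

    Genes truly losing TE under knockdown ("down") are exactly the genes built
    with elevated m7G-codon content: their per-codon probability of drawing a
    codon from the m7G set is the background rate plus ``codon_margin``.
    """
    config.validate()
    from .codonfreq import decode_codons  # local import to avoid a cycle

    if not truth.modified_anticodons:
        raise ConfigurationError(
            "n_modified: transcriptome simulation needs a non-empty m7G codon set "
            "(no modified tRNAs were planted)"
        )
    codon_set = decode_codons(truth.modified_anticodons, wobble="strict")
    truth.m7g_codons = tuple(sorted(codon_set.codons))

    set_dna = sorted(reverse_transcribe(c) for c in codon_set.codons)
    all_dna = [reverse_transcribe(c) for c in SENSE_CODONS]
    nonset_dna = [c for c in all_dna if c not in set(set_dna)]
    f0 = len(set_dna) / len(all_dna)
    q = f0 + config.codon_margin
    if q > 1.0:
        raise ConfigurationError("codon_margin: background frequency + margin exceeds 1")

    rng = config.rng(2)
    n = config.n_genes
    order = rng.permutation(n)
    n_down = int(round(config.enriched_fraction * n))
    n_up = int(round(config.te_up_fraction * n))
    classes = np.full(n, "non", dtype=object)
    classes[order[:n_down]] = "down"
    classes[order[n_down:n_down + n_up]] = "up"

    stops = np.array(["TAA", "TAG", "TGA"])
    all_arr = np.array(all_dna)
    set_arr = np.array(set_dna)
    nonset_arr = np.array(nonset_dna)
    atg_in_set = "ATG" in set(set_dna)

    cds: dict[str, str] = {}
    for i in range(n):
        gid = f"gene{i + 1:05d}"
        n_int = int(rng.integers(100, 401))
        if classes[i] == "down":
            mask = rng.random(n_int) < q
            codons = np.where(
                mask,
                set_arr[rng.integers(0, len(set_arr), size=n_int)],
                nonset_arr[rng.integers(0, len(nonset_arr), size=n_int)],
            )
            n_in_set = int(mask.sum())
        else:
            idx = rng.integers(0, len(all_arr), size=n_int)
            codons = all_arr[idx]
            n_in_set = int(np.isin(codons, set_arr).sum())
        seq = "ATG" + "".join(codons) + str(stops[rng.integers(0, 3)])
        cds[gid] = seq
        truth.te_class_truth[gid] = str(classes[i])
        # same convention as codon_frequency: start codon counted, stop excluded
        truth.true_codon_freq[gid] = (n_in_set + (1 if atg_in_set else 0)) / (n_int + 1)
    return cds, truth


def simulate_rnc_counts(
    config: SimConfig, truth: PlantedTruth, lengths: Mapping[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw input and RNC count tables (negative binomial) for both conditions.

    Input expression is unchanged between conditions; the expected RNC share
    of a gene is scaled by ``te_effect_fc`` (down) or its inverse (up) under
    knockdown only. Expected counts in every library sum to
    ``depth_per_library``.
    """
    config.validate()
    if not truth.te_class_truth:
        raise GenerationError("transcriptome must be simulated before counts")
    if config.depth_per_library <= 0:
        raise ConfigurationError("depth_per_library: must be positive")
    genes = list(lengths.keys())
    n = len(genes)
    rng = config.rng(3)
    expr = np.exp(rng.normal(0.0, 1.0, size=n))
    te_base = np.exp(rng.normal(0.0, 0.25, size=n))
    cls = np.array([truth.te_class_truth[g] for g in genes])
    fc = np.where(cls == "down", config.te_effect_fc,
                  np.where(cls == "up", 1.0 / config.te_effect_fc, 1.0))

    depth = float(config.depth_per_library)
    mu_input = depth * expr / expr.sum()
    rnc_ctrl_rel = expr * te_base
    rnc_kd_rel = expr * te_base * fc
    mu_rnc = {
        "ctrl": depth * rnc_ctrl_rel / rnc_ctrl_rel.sum(),
        "kd": depth * rnc_kd_rel / rnc_kd_rel.sum(),
    }

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion == 0:
            return rng.poisson(mu)
        size = 1.0 / config.nb_dispersion
        return rng.negative_binomial(size, size / (size + mu))

    input_cols, rnc_cols = {}, {}
    for cond in LIBRARY_CONDITIONS:
        for rep in range(1, config.replicates + 1):
            input_cols[f"{cond}_rep{rep}"] = draw(mu_input)
            rnc_cols[f"{cond}_rep{rep}"] = draw(mu_rnc[cond])
    input_df = pd.DataFrame(input_cols, index=pd.Index(genes, name="gene_id"))
    rnc_df = pd.DataFrame(rnc_cols, index=pd.Index(genes, name="gene_id"))
    return input_df, rnc_df


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Plain-text FASTQ with a constant quality string ('I')."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_all(config: SimConfig, outdir) -> dict[str, object]:
    """Run every generator stage and write all pipeline inputs to ``outdir``.

    Emits the annotation (BED + locus FASTA), the four FASTQ libraries per
    replicate plus the truth-consistent read-count sidecar, the CDS FASTA,
    the input/RNC count tables and the planted-truth JSON. Returns the
    in-memory objects keyed by name.
    """
    from .transeff import write_count_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_trna_set(config)
    write_annotation(genes, outdir / "trna_annotation.bed", outdir / "trna_genome.fa")
    reads, sidecar = simulate_cleavage_libraries(genes, truth, config)
    for lib, rd in reads.items():
        write_fastq(rd, outdir / f"{lib}.fastq")
    sidecar.to_csv(outdir / "read_counts.tsv", sep="\t", index=False)
    cds, truth = simulate_transcriptome(config, truth)
    with open(outdir / "cds.fa", "w") as fh:
        for gid, seq in cds.items():
            fh.write(f">{gid}\n{seq}\n")
    lengths = {g: len(s) for g, s in cds.items()}
    input_df, rnc_df = simulate_rnc_counts(config, truth, lengths)
    write_count_table(input_df, lengths, outdir / "input_counts.tsv")
    write_count_table(rnc_df, lengths, outdir / "rnc_counts.tsv")
    truth.to_json(outdir / "truth.json")
    return {
        "genes": genes, "truth": truth, "reads": reads, "sidecar": sidecar,
        "cds": cds, "input_counts": input_df, "rnc_counts": rnc_df,
    }
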