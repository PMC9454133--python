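"""Mature and precursor tRNA reference construction.

Mature references are built from genomic tRNA gene records by splicing out
annotated introns, transcribing to the RNA alphabet and appending the CCA
tail that mature tRNAs acquire post-transcriptionally. Precursor references
keep the unspliced gene with 100 nt of genomic flank on each side.

Annotation I/O uses a BED12-like dialect (0-based, half-open; blocks encode
exons) with gtRNAdb-style record names (``tRNA-Ala-AGC-1-1``) carrying the
anticodon, alongside a genome FASTA supplying gene and flank sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

from Bio import SeqIO

from ._seq import revcomp_dna, transcribe

logger = logging.getLogger(__name__)

DEFAULT_FLANK_LEN = 100


@dataclass(frozen=True)
class TRNAGeneRecord:
    """A tRNA gene on the genome.

    ``gene_seq`` and flanks are stored on the genomic plus strand in the DNA
    alphabet; ``intron_intervals`` are 0-based half-open intervals on
    ``gene_seq``. ``anticodon`` is the 5'->3' anticodon in the RNA alphabet.
    """

    id: str
    gene_seq: str
    intron_intervals: tuple[tuple[int, int], ...] = ()
    strand: str = "+"
    anticodon: str = ""
    upstream_flank: str = ""
    downstream_flank: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.anticodon and (len(self.anticodon) != 3 or any(b not in "ACGU" for b in self.anticodon)):
            raise ValueError(f"{self.id}: anticodon must be a 3-mer over ACGU, got {self.anticodon!r}")


@dataclass(frozen=True)
class MatureTRNA:
    """A spliced, CCA-tailed mature tRNA in the RNA alphabet."""

    id: str
    seq: str
    anticodon: str = ""
    m7g_candidate_positions: tuple[int, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.seq)


def _check_intervals(record: TRNAGeneRecord) -> None:
    n = len(record.gene_seq)
    prev_end = 0
    for s, e in record.intron_intervals:
        if not (0 <= s < e <= n):
            raise ValueError(f"{record.id}: intron interval ({s}, {e}) outside gene bounds [0, {n})")
        if s < prev_end:
            raise ValueError(f"{record.id}: intron intervals overlap or are unsorted at ({s}, {e})")
        prev_end = e


def sense_gene(record: TRNAGeneRecord) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Gene sequence and intron intervals in transcription (sense) orientation."""
    _check_intervals(record)
    if record.strand == "+":
        return record.gene_seq.upper(), tuple(record.intron_intervals)
    n = len(record.gene_seq)
    seq = revcomp_dna(record.gene_seq.upper())
    introns = tuple(sorted((n - e, n - s) for s, e in record.intron_intervals))
    return seq, introns


def build_mature(record: TRNAGeneRecord) -> MatureTRNA:
    """Splice introns out, transcribe to RNA and append the 3' CCA tail.

    The mature length is gene length minus total intron length plus 3.
    """
    seq, introns = sense_gene(record)
    pieces, pos = [], 0
    for s, e in introns:
        pieces.append(seq[pos:s])
        pos = e
    pieces.append(seq[pos:])
    mature = transcribe("".join(pieces)) + "CCA"
    gs = tuple(i for i, b in enumerate(mature) if b == "G")
    return MatureTRNA(id=record.id, seq=mature, anticodon=record.anticodon, m7g_candidate_positions=gs)


def build_precursor(record: TRNAGeneRecord, flank_len: int = DEFAULT_FLANK_LEN) -> str:
    """Unspliced gene with ``flank_len`` nt of genomic context on each side.

    Short flanks are N-padded to ``flank_len`` with a logged warning, so the
    length identity ``len(precursor) == len(gene) + 2 * flank_len`` always holds.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    up = record.upstream_flank.upper()[-flank_len:] if flank_len else ""
    down = record.downstream_flank.upper()[:flank_len] if flank_len else ""
    if len(up) < flank_len or len(down) < flank_len:
        logger.warning(
            "%s: flank shorter than %d nt (up=%d, down=%d); padding with N",
            record.id, flank_len, len(up), len(down),
        )
        up = "N" * (flank_len - len(up)) + up
        down = down + "N" * (flank_len - len(down))
    return up + record.gene_seq.upper() + down


def anticodon_from_name(name: str) -> str:
    """Anticodon (RNA) from a gtRNAdb-style name such as ``tRNA-Ala-AGC-1-1``."""
    for token in name.split("-"):
        if len(token) == 3 and all(b in "ACGTU" for b in token.upper()):
            return transcribe(token.upper())
    return ""


def read_annotation(bed_path, fasta_path, flank_len: int = DEFAULT_FLANK_LEN) -> list[TRNAGeneRecord]:
    """Read gene records from a BED12-like annotation plus a genome FASTA.

    Blocks encode exons; the gap between consecutive blocks is recovered as an
    intron interval on the gene sequence. Flanks are taken from the genome
    (clipped at contig ends).
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records: list[TRNAGeneRecord] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 6 BED fields, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if chrom not in genome:
                raise ValueError(f"{bed_path}:{lineno}: contig {chrom!r} absent from FASTA")
            contig = genome[chrom]
            if not (0 <= start < end <= len(contig)):
                raise ValueError(
                    f"{bed_path}:{lineno}: interval [{start}, {end}) outside contig of length {len(contig)}"
                )
            introns: list[tuple[int, int]] = []
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != len(offsets):
                    raise ValueError(f"{bed_path}:{lineno}: blockSizes/blockStarts length mismatch")
                for (o1, s1), o2 in zip(zip(offsets, sizes), offsets[1:]):
                    if o1 + s1 > o2:
                        raise ValueError(f"{bed_path}:{lineno}: overlapping exon blocks")
                    introns.append((o1 + s1, o2))
            records.append(
                TRNAGeneRecord(
                    id=name,
                    gene_seq=contig[start:end],
                    intron_intervals=tuple(introns),
                    strand=strand,
                    anticodon=anticodon_from_name(name),
                    upstream_flank=contig[max(0, start - flank_len):start],
                    downstream_flank=contig[end:end + flank_len],
                )
            )
    return records


def write_annotation(records: Iterable[TRNAGeneRecord], bed_path, fasta_path) -> None:
    """Write records as one contig per gene (flank+gene+flank) plus a BED12 file."""
    records = list(records)
    with open(fasta_path, "w") as fa, open(bed_path, "w") as bed:
        for rec in records:
            contig_id = f"{rec.id}_locus"
            contig = rec.upstream_flank + rec.gene_seq + rec.downstream_flank
            fa.write(f">{contig_id}\n{contig}\n")
            start = len(rec.upstream_flank)
            end = start + len(rec.gene_seq)
            exons, pos = [], 0
            for s, e in rec.intron_intervals:
                exons.append((pos, s))
                pos = e
            exons.append((pos, len(rec.gene_seq)))
            exons = [(s, e) for s, e in exons if e > s]
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s) for s, _ in exons)
            bed.write(
                "\t".join(
                    [
                        contig_id, str(start), str(end), rec.id, "0", rec.strand,
                        str(start), str(end), "0", str(len(exons)), sizes, offsets,
                    ]
                )
                + "\n"
            )


def write_fasta(seqs, path) -> None:
    """Write ``{id: sequence}`` or an iterable of MatureTRNA/records to FASTA."""
    with open(path, "w") as fh:
        if hasattr(seqs, "items"):
            items = seqs.items()
        else:
            items = ((s.id, s.seq) for s in seqs)
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def mature_set(records: Iterable[TRNAGeneRecord]) -> dict[str, MatureTRNA]:
    """Build the mature reference set keyed by tRNA id."""
    out = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate tRNA id {rec.id!r}")
        out[rec.id] = build_mature(rec)
    return out
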