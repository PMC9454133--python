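"""Small nucleotide-string helpers shared across modules.

All sequences are plain upper-case Python strings. Genomic/CDS material is
kept in the DNA alphabet, mature tRNA references and anticodons in the RNA
alphabet; the two meet only through :func:`transcribe` / :func:`reverse_transcribe`.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

#: RNA stop codons (standard code).
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: The 61 sense codons of the standard code, RNA alphabet, lexicographic.
SENSE_CODONS = tuple(
    a + b + c
    for a in RNA_BASES
    for b in RNA_BASES
    for c in RNA_BASES
    if a + b + c not in STOP_CODONS
)

# IUPAC degenerate nucleotide codes over the RNA alphabet.
IUPAC_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_BASES.items()}


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA of the same (sense) strand."""
    return seq.upper().replace("T", "U")


def reverse_transcribe(seq: str) -> str:
    """RNA -> DNA of the same strand."""
    return seq.upper().replace("U", "T")


def iupac_matches(pattern: str, seq: str) -> bool:
    """True if ``seq`` (concrete RNA) is admitted position-wise by ``pattern``."""
    if len(pattern) != len(seq):
        return False
    return all(b in IUPAC_TO_BASES[p] for p, b in zip(pattern, seq))


def iupac_subsumes(outer: str, inner: str) -> bool:
    """True if every base admitted by ``inner`` is admitted by ``outer``."""
    if len(outer) != len(inner):
        return False
    return all(
        set(IUPAC_TO_BASES[i]) <= set(IUPAC_TO_BASES[o])
        for o, i in zip(outer, inner)
    )


class ConfigurationError(ValueError):
    """Invalid configuration value; the message names the offending field."""
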