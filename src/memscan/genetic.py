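"""Genetic-code helpers shared across the package.

Thin wrappers around Biopython plus the degenerate-codon bookkeeping needed
for NNS site-saturation libraries.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: IUPAC degenerate nucleotide expansions used in primer design.
DEGENERATE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate(dna: str) -> str:
    """Translate an in-frame DNA string; stop codons become ``*``."""
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate())


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC degenerate codes (N<->N, S<->S)."""
    return str(Seq(seq).reverse_complement())


def codon_for(aa: str) -> str:
    """A fixed representative codon for an amino acid (deterministic)."""
    return _PREFERRED_CODONS[aa]


@lru_cache(maxsize=None)
def nns_codons() -> dict[str, str]:
    """Map each of the 32 NNS codons to its translation (``*`` for stop)."""
    out = {}
    for n1 in "ACGT":
        for n2 in "ACGT":
            for s in "CG":
                codon = n1 + n2 + s
                out[codon] = translate(codon)
    return out


@lru_cache(maxsize=None)
def nns_codons_for(aa: str) -> tuple[str, ...]:
    """All NNS codons translating to ``aa``, sorted."""
    return tuple(sorted(c for c, a in nns_codons().items() if a == aa))


# One unambiguous codon per amino acid; chosen once so that synthetic
# sequences are reproducible. All are members of the NNS set.
_PREFERRED_CODONS = {aa: nns_codons_for(aa)[0] for aa in AMINO_ACIDS}


def reverse_translate(protein: str) -> str:
    """Deterministic reverse translation using the preferred codons."""
    return "".join(codon_for(aa) for aa in protein)
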