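"""Expression constructs, NNS saturation libraries, and mutagenic primers.

A :class:`Construct` describes the membrane-span cassette that is scanned:
its DNA, the residue numbering of the encoded protein, the half-open span of
scanned residues, and the constant flanking sequences used to locate the
amplicon in sequencing reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genetic import (
    AMINO_ACIDS,
    nns_codons,
    reverse_complement,
    translate,
)

ORIENTATION = "N-cytoplasmic"


class ConstructError(ValueError):
    """Raised when a construct definition violates its invariants."""


class PrimerDesignError(ValueError):
    """Raised when no primer satisfying the length policy exists."""


@dataclass(frozen=True)
class Construct:
    """A membrane-span expression cassette.

    Parameters
    ----------
    name:
        Identifier used in outputs.
    dna:
        In-frame coding sequence of the scanned segment.
    numbering_start:
        Residue number of the first codon of ``dna``; all positions in the
        public API use this numbering.
    span:
        Half-open ``(start, end)`` interval of scanned residue numbers.
    upstream_flank, downstream_flank:
        Constant sequences abutting ``dna`` in the sequenced amplicon.
    """

    name: str
    dna: str
    span: tuple[int, int]
    upstream_flank: str
    downstream_flank: str
    numbering_start: int = 1
    orientation: str = ORIENTATION

    def __post_init__(self) -> None:
        if len(self.dna) % 3 != 0:
            raise ConstructError(f"{self.name}: DNA length not a multiple of 3")
        protein = translate(self.dna)
        if "*" in protein:
            raise ConstructError(f"{self.name}: stop codon in coding sequence")
        start, end = self.span
        first = self.numbering_start
        last = first + len(protein)
        if not (first <= start < end <= last):
            raise ConstructError(
                f"{self.name}: span {self.span} outside protein "
                f"[{first}, {last})"
            )
        if not self.upstream_flank or not self.downstream_flank:
            raise ConstructError(f"{self.name}: flanks must be non-empty")
        amplicon = self.amplicon
        for flank in (self.upstream_flank, self.downstream_flank):
            if amplicon.count(flank) != 1:
                raise ConstructError(
                    f"{self.name}: flank {flank!r} does not occur exactly "
                    "once in the amplicon"
                )

    @property
    def protein(self) -> str:
        return translate(self.dna)

    @property
    def amplicon(self) -> str:
        """Constant context + coding sequence as seen by the sequencer."""
        return self.upstream_flank + self.dna + self.downstream_flank

    # -- residue/nucleotide coordinate helpers ------------------------------

    def residue_index(self, position: int) -> int:
        """0-based protein index of a residue number."""
        idx = position - self.numbering_start
        if not 0 <= idx < len(self.protein):
            raise IndexError(f"position {position} outside {self.name}")
        return idx

    def codon_slice(self, position: int) -> slice:
        i = 3 * self.residue_index(position)
        return slice(i, i + 3)

    def wildtype_aa(self, position: int) -> str:
        return self.protein[self.residue_index(position)]

    @property
    def span_positions(self) -> range:
        return range(self.span[0], self.span[1])

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def span_protein(self) -> str:
        a = self.residue_index(self.span[0])
        return self.protein[a : a + self.span_length]

    @property
    def span_dna(self) -> str:
        a = 3 * self.residue_index(self.span[0])
        return self.dna[a : a + 3 * self.span_length]

    def span_nt_offset_in_amplicon(self) -> int:
        """Offset of the first scanned codon within :attr:`amplicon`."""
        return len(self.upstream_flank) + 3 * self.residue_index(self.span[0])

    def wildtype_map(self) -> dict[int, str]:
        return {p: self.wildtype_aa(p) for p in self.span_positions}


@dataclass(frozen=True, order=True)
class VariantId:
    """A single amino-acid identity at a scanned position."""

    position: int
    aa: str
    is_wildtype: bool = False


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse mutagenic oligos carrying one degenerate codon."""

    forward: str
    reverse: str
    position: int

    def __post_init__(self) -> None:
        if reverse_complement(self.forward) != self.reverse:
            raise PrimerDesignError(
                "reverse is not the degenerate reverse complement of forward"
            )
        for oligo in (self.forward, self.reverse):
            if not 40 <= len(oligo) <= 85:
                raise PrimerDesignError(
                    f"oligo length {len(oligo)} outside [40, 85]"
                )


@dataclass(frozen=True)
class ArmPolicy:
    """How much constant sequence to copy on each side of the NNS codon."""

    total_length: int = 48
    min_total: int = 40
    max_total: int = 85

    def __post_init__(self) -> None:
        if not self.min_total <= self.total_length <= self.max_total:
            raise PrimerDesignError(
                f"target length {self.total_length} outside "
                f"[{self.min_total}, {self.max_total}]"
            )


def enumerate_library(construct: Construct) -> list[VariantId]:
    """All 20 amino-acid identities at every scanned position.

    Wild-type identities are included (and flagged), so a span of length L
    yields exactly ``20 * L`` variants.
    """
    if construct.span_length == 0:
        raise ConstructError("span is empty")
    variants = []
    for pos in construct.span_positions:
        wt = construct.wildtype_aa(pos)
        for aa in AMINO_ACIDS:
            variants.append(VariantId(pos, aa, is_wildtype=(aa == wt)))
    return variants


def nns_translation_census() -> tuple[int, int]:
    """(number of distinct amino acids, number of stop codons) over NNS."""
    products = list(nns_codons().values())
    aas = {p for p in products if p != "*"}
    return len(aas), products.count("*")


def design_primers(
    construct: Construct, position: int, policy: ArmPolicy = ArmPolicy()
) -> PrimerPair:
    """Design a forward/reverse oligo pair replacing one codon by NNS.

    Arms are copied verbatim from the construct DNA, symmetric around the
    degenerate codon where possible; near the sequence ends the short arm
    borrows length from the other side so the total stays on target.
    """
    if position not in construct.span_positions:
        raise PrimerDesignError(
            f"position {position} not in scanned span {construct.span}"
        )
    codon = construct.codon_slice(position)
    up_avail = codon.start
    down_avail = len(construct.dna) - codon.stop

    arm_total = policy.total_length - 3
    up = arm_total // 2
    down = arm_total - up
    # borrow from the other arm when one side runs out of template
    if up > up_avail:
        down += up - up_avail
        up = up_avail
    if down > down_avail:
        up += down - down_avail
        down = down_avail
    if up > up_avail or up + down + 3 < policy.min_total:
        raise PrimerDesignError(
            f"position {position}: insufficient template for a "
            f"{policy.min_total}-nt oligo"
        )
    forward = (
        construct.dna[codon.start - up : codon.start]
        + "NNS"
        + construct.dna[codon.stop : codon.stop + down]
    )
    return PrimerPair(forward, reverse_complement(forward), position)


def check_printed_oligo(construct: Construct, position: int, forward: str) -> bool:
    """Whether a supplied forward oligo's arms match the construct exactly.

    Returns True when the oligo contains a single NNS codon and both arms
    align with zero mismatches to the DNA around ``position``'s codon.
    Vendor-supplied oligos that fail this check should be rejected.
    """
    if forward.count("NNS") != 1:
        return False
    up, down = forward.split("NNS")
    codon = construct.codon_slice(position)
    return construct.dna[codon.start - len(up) : codon.start] == up and (
        construct.dna[codon.stop : codon.stop + len(down)] == down
    )


# ---------------------------------------------------------------------------
# Built-in constructs
# ---------------------------------------------------------------------------

# Constant amplicon context shared by the built-in cassettes (restriction
# sites of the expression vector's multiple-cloning region).
_UP_FLANK = "CTTGGGGAATCGACTCGAG"
_DOWN_FLANK = "ACTAGTCATCACCATCAC"

#: Monomeric C-terminal span of human L-Selectin; residue numbering places
#: the membrane mid-plane alanine at 311.
HUMAN_CLS = Construct(
    name="human_CLS",
    dna=(
        "CCGCTGTTCATCCCGGTTGCAGTTATGGTTACCGCTTTTAGTGGATTGGCG"
        "TTTATCATCTGGCTGGCT"
    ),
    numbering_start=295,
    span=(295, 318),
    upstream_flank=_UP_FLANK,
    downstream_flank=_DOWN_FLANK,
)

#: Glycophorin A membrane domain (GxxxG homodimer).
GPA = Construct(
    name="GpA",
    dna="CTCATTATTTTTGGGGTGATGGCTGGTGTTATTGGAACGATCCTGATC",
    numbering_start=75,
    span=(75, 91),
    upstream_flank=_UP_FLANK,
    downstream_flank=_DOWN_FLANK,
)

#: ErbB2 receptor membrane domain.
ERBB2 = Construct(
    name="ErbB2",
    dna=(
        "CTGACGTCTATCATCTCTGCGGTGGTTGGCATTCTGCTGGTCGTGGTC"
        "TTGGGCGTGGTCTTTGGCATCCTGATC"
    ),
    numbering_start=652,
    span=(652, 677),
    upstream_flank=_UP_FLANK,
    downstream_flank=_DOWN_FLANK,
)

BUILTIN_CONSTRUCTS = {c.name: c for c in (HUMAN_CLS, GPA, ERBB2)}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_construct(source: str | Path) -> Construct:
    """Load a construct from a YAML file, or look up a built-in by name."""
    if str(source) in BUILTIN_CONSTRUCTS:
        return BUILTIN_CONSTRUCTS[str(source)]
    with open(source) as fh:
        raw = yaml.safe_load(fh)
    raw["span"] = tuple(raw["span"])
    known = {f.name for f in dataclasses.fields(Construct)}
    return Construct(**{k: v for k, v in raw.items() if k in known})


def save_construct(construct: Construct, path: str | Path) -> None:
    data = dataclasses.asdict(construct)
    data["span"] = list(construct.span)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_library_tsv(variants: list[VariantId], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\taa\tis_wildtype\n")
        for v in variants:
            fh.write(f"{v.position}\t{v.aa}\t{int(v.is_wildtype)}\n")


def write_primers_fasta(
    construct: Construct, path: str | Path, policy: ArmPolicy = ArmPolicy()
) -> None:
    """One forward/reverse record pair per scanned position."""
    with open(path, "w") as fh:
        for pos in construct.span_positions:
            pair = design_primers(construct, pos, policy)
            fh.write(f">{construct.name}_pos{pos}_fwd\n{pair.forward}\n")
            fh.write(f">{construct.name}_pos{pos}_rev\n{pair.reverse}\n")
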