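"""Synthetic-data generation for the full scanning pipeline.

Produces reference/selected count tables (and optionally FASTQ read pairs)
from a known ground-truth energy landscape, so every downstream stage can be
tested without external data. Selection is modelled as a single Boltzmann
reweighting of the reference population.
"""

from __future__ import annotations

import json
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constructs import Construct, VariantId, enumerate_library
from .genetic import AMINO_ACIDS, nns_codons_for, reverse_translate

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.9872e-3


def rt_kcal(temperature: float = 310.0) -> float:
    """RT in kcal/mol (0.6160 at 310 K)."""
    return R_KCAL * temperature


@dataclass
class TruthLandscape:
    """Ground-truth apparent free-energy landscape for simulation.

    ``table`` maps (position, aa) -> ddG in kcal/mol relative to the
    wild-type identity at that position (wild type is 0 by construction).
    """

    table: dict[tuple[int, str], float]
    wildtype: dict[int, str]
    midplane: float | None = None
    rise: float = 1.5

    def __post_init__(self) -> None:
        for pos, wt in self.wildtype.items():
            wt_val = self.table.get((pos, wt), 0.0)
            if wt_val != 0.0:
                raise ValueError(f"wild-type ddG at {pos} is {wt_val}, not 0")
            self.table[(pos, wt)] = 0.0
        for key, val in self.table.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite ddG at {key}")

    def ddg(self, position: int, aa: str) -> float:
        """ddG of a variant; identities absent from the table are neutral."""
        if position not in self.wildtype:
            raise KeyError(f"position {position} not covered by the truth")
        return self.table.get((position, aa), 0.0)

    @classmethod
    def from_polynomials(
        cls,
        coefficients: Mapping[str, Sequence[float]],
        wildtype: Mapping[int, str],
        midplane: float,
        rise: float = 1.5,
    ) -> "TruthLandscape":
        """Build a per-variant table from per-aa polynomials over depth Z.

        ``coefficients[aa]`` holds ascending coefficients (c0..c4) of the
        amino acid's insertion polynomial relative to a common reference;
        ddG(pos, aa) = poly_aa(Z) - poly_wt(Z) with Z = (pos - midplane) *
        rise, so the wild type is 0 automatically.
        """
        polys = {aa: np.polynomial.Polynomial(c) for aa, c in coefficients.items()}
        table = {}
        for pos, wt in wildtype.items():
            z = (pos - midplane) * rise
            base = polys[wt](z)
            for aa in AMINO_ACIDS:
                table[(pos, aa)] = float(polys[aa](z) - base)
        return cls(dict(table), dict(wildtype), midplane=midplane, rise=rise)

    def to_json(self, path: str | Path) -> None:
        data = {
            "midplane": self.midplane,
            "rise": self.rise,
            "wildtype": {str(k): v for k, v in self.wildtype.items()},
            "ddg": {f"{p}:{a}": v for (p, a), v in sorted(self.table.items())},
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimConfig:
    """Knobs of the synthetic experiment."""

    depth_reference: int = 1_000_000
    depth_selected: int = 1_000_000
    clonal_bias_sigma: float = 0.5
    temperature: float = 310.0
    seq_error_rate: float = 0.0
    seed: int = 0
    read_length: int = 150
    wildtype_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ValueError("seq_error_rate must be in [0, 1]")
        if self.depth_reference < 0 or self.depth_selected < 0:
            raise ValueError("depths must be non-negative")
        if self.clonal_bias_sigma < 0:
            raise ValueError("clonal_bias_sigma must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# Stream identifiers; one master seed fans out to independent generators in
# a documented order.
_STREAM_REFERENCE = 1
_STREAM_SELECTED = 2
_STREAM_FASTQ = 3

# Late import: CountTable lives with the counting code.
from .readcount import CountTable  # noqa: E402


def _member_universe(
    library: Sequence[VariantId],
) -> tuple[list[VariantId], dict[int, str]]:
    members = sorted(library)
    wildtype = {v.position: v.aa for v in members if v.is_wildtype}
    return members, wildtype


def simulate_reference_counts(
    library: Sequence[VariantId], config: SimConfig
) -> CountTable:
    """Multinomial reference counts with log-normal clonal weights.

    All wild-type identity members collapse into the table's single
    wild-type count, mirroring how sequencing cannot distinguish them at
    the amino-acid level.
    """
    members, wildtype = _member_universe(library)
    rng = config.rng(_STREAM_REFERENCE)
    weights = rng.lognormal(mean=0.0, sigma=config.clonal_bias_sigma,
                            size=len(members))
    for i, v in enumerate(members):
        if v.is_wildtype:
            weights[i] *= config.wildtype_multiplier
    if config.depth_reference == 0:
        draws = np.zeros(len(members), dtype=int)
    else:
        draws = rng.multinomial(config.depth_reference,
                                weights / weights.sum())
    counts: dict[tuple[int, str], int] = {}
    wt_count = 0
    for v, c in zip(members, draws):
        if v.is_wildtype:
            wt_count += int(c)
        elif c:
            counts[(v.position, v.aa)] = int(c)
    return CountTable(
        population="reference",
        counts=counts,
        wildtype_count=wt_count,
        wildtype=wildtype,
        n_reads_total=config.depth_reference,
        n_reads_passing=config.depth_reference,
    )


def expected_selected_frequencies(
    reference: CountTable, truth: TruthLandscape, temperature: float = 310.0
) -> dict[tuple[int, str] | str, float]:
    """Noise-free post-selection frequencies (Boltzmann reweighting).

    The wild-type pool is keyed ``"WT"``; frequencies sum to 1.
    """
    if set(reference.wildtype) != set(truth.wildtype):
        raise ValueError("reference and truth cover different positions")
    rt = rt_kcal(temperature)
    weights: dict[tuple[int, str] | str, float] = {
        "WT": float(reference.wildtype_count)  # ddG(wt) = 0
    }
    for (pos, aa), c in reference.counts.items():
        weights[(pos, aa)] = c * math.exp(-truth.ddg(pos, aa) / rt)
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


def simulate_selected_counts(
    reference: CountTable, truth: TruthLandscape, config: SimConfig
) -> CountTable:
    """Multinomial selected counts under the Boltzmann selection model."""
    freqs = expected_selected_frequencies(
        reference, truth, config.temperature
    )
    keys = sorted(
        (k for k in freqs if k != "WT"),
    ) + ["WT"]
    probs = np.array([freqs[k] for k in keys])
    rng = config.rng(_STREAM_SELECTED)
    if config.depth_selected == 0:
        draws = np.zeros(len(keys), dtype=int)
    else:
        draws = rng.multinomial(config.depth_selected, probs / probs.sum())
    counts = {
        k: int(c) for k, c in zip(keys, draws) if k != "WT" and c
    }
    return CountTable(
        population="selected",
        counts=counts,  # type: ignore[arg-type]
        wildtype_count=int(draws[-1]),
        wildtype=dict(reference.wildtype),
        n_reads_total=config.depth_selected,
        n_reads_passing=config.depth_selected,
    )


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def _variant_amplicon(
    construct: Construct, position: int, aa: str, rng: np.random.Generator
) -> str:
    """Amplicon DNA carrying one NNS codon substitution."""
    codons = nns_codons_for(aa)
    codon = codons[rng.integers(len(codons))]
    sl = construct.codon_slice(position)
    dna = construct.dna[: sl.start] + codon + construct.dna[sl.stop :]
    return construct.upstream_flank + dna + construct.downstream_flank


def _quality_char(error_rate: float) -> str:
    if error_rate <= 0:
        return "I"  # Q40
    q = min(40, max(2, round(-10 * math.log10(error_rate))))
    return chr(q + 33)


_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        base = arr[i].decode()
        arr[i] = _OTHER_BASES[base][rng.integers(3)].encode()
    return arr.tobytes().decode()


def emit_fastq(
    counts: CountTable,
    construct: Construct,
    config: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Write one read pair per counted molecule.

    Read 1 is the first ``read_length`` bases of the amplicon's forward
    strand; read 2 the first ``read_length`` bases of the reverse strand.
    Substitution errors are applied per base at ``seq_error_rate``.
    """
    amp_len = len(construct.amplicon)
    rlen = min(config.read_length, amp_len)
    if 2 * rlen < amp_len:
        raise ValueError(
            f"amplicon ({amp_len} nt) longer than combined read coverage "
            f"({2 * rlen} nt)"
        )
    rng = config.rng(_STREAM_FASTQ)

    molecules: list[str] = []
    wt_amplicon = construct.amplicon
    molecules.extend([wt_amplicon] * counts.wildtype_count)
    for (pos, aa) in sorted(counts.counts):
        n = counts.counts[(pos, aa)]
        for _ in range(n):
            molecules.append(_variant_amplicon(construct, pos, aa, rng))
    order = rng.permutation(len(molecules))

    qual = _quality_char(config.seq_error_rate) * rlen
    comp = str.maketrans("ACGT", "TGCA")

    def _open(path):
        p = str(path)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for i, idx in enumerate(order):
            amp = molecules[idx]
            r1 = _apply_errors(amp[:rlen], config.seq_error_rate, rng)
            rev = amp.translate(comp)[::-1]
            r2 = _apply_errors(rev[:rlen], config.seq_error_rate, rng)
            name = f"SIM:{counts.population}:{i}"
            f1.write(f"@{name} 1:N:0:1\n{r1}\n+\n{qual}\n")
            f2.write(f"@{name} 2:N:0:1\n{r2}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Reusable synthetic ground truths
# ---------------------------------------------------------------------------

def demo_polynomials() -> dict[str, tuple[float, ...]]:
    """Plausible per-aa quartic insertion polynomials (relative to Ala).

    Hydrophobics show troughs at Z=0, polars/charged peaks, Arg and Lys an
    asymmetry favouring the cytoplasmic (negative-Z) side. Purely synthetic
    shapes for testing; ascending coefficients (c0..c4).
    """

    def bowl(depth: float, edge: float, z_edge: float = 18.0) -> tuple:
        # quartic trough: f(0)=depth (negative), f(+-z_edge)=edge
        c4 = 1.0e-5
        c2 = (edge - depth - c4 * z_edge**4) / z_edge**2
        return (depth, 0.0, c2, 0.0, c4)

    def hill(height: float, edge: float, tilt: float = 0.0,
             z_edge: float = 18.0) -> tuple:
        c4 = -1.0e-5
        c2 = (edge - height - c4 * z_edge**4) / z_edge**2
        return (height, tilt, c2, 0.0, c4)

    return {
        "A": (0.0, 0.0, 0.0, 0.0, 0.0),
        "L": bowl(-1.9, 0.8),
        "I": bowl(-1.8, 0.8),
        "M": bowl(-1.6, 0.6),
        "F": bowl(-2.0, 0.7),
        "V": bowl(-0.5, 0.3),
        "W": bowl(-1.2, 0.2),
        "Y": hill(0.1, -0.2),
        "S": hill(0.4, 0.0),
        "T": hill(0.5, 0.0),
        "C": hill(0.3, 0.1),
        "G": hill(1.9, 0.3),
        "P": hill(2.1, 0.8),
        "N": hill(2.6, 0.2),
        "Q": hill(2.7, 0.3),
        "H": hill(2.2, -0.1, tilt=0.02),
        "D": hill(3.0, 0.5),
        "E": hill(3.1, 0.4),
        "K": hill(2.8, -0.3, tilt=0.09),
        "R": hill(2.4, -0.6, tilt=0.11),
    }


def make_scan_construct(
    span_length: int = 27,
    seed: int = 0,
    name: str = "synthetic_scan",
    numbering_start: int = 298,
) -> Construct:
    """A synthetic membrane-span construct with a scanned span.

    The span is mostly hydrophobic with a couple of polar positions; two
    extra residues pad each side so primer arms and numbering edge cases
    are exercised.
    """
    rng = np.random.default_rng([seed, 99])
    pool = list("LIVAFM")
    span = [pool[rng.integers(len(pool))] for _ in range(span_length)]
    span[span_length // 3] = "S"
    span[2 * span_length // 3] = "T"
    protein = "GS" + "".join(span) + "GK"
    dna = reverse_translate(protein)
    return Construct(
        name=name,
        dna=dna,
        numbering_start=numbering_start - 2,
        span=(numbering_start, numbering_start + span_length),
        upstream_flank="CTTGGGGAATCGACTCGAG",
        downstream_flank="ACTAGTCATCACCATCAC",
    )


def make_demo_truth(
    construct: Construct,
    midplane: float | None = None,
    rise: float = 1.5,
    scale: float = 1.0,
) -> TruthLandscape:
    """Demo quartic truth landscape centred on the span midpoint.

    ``scale`` multiplies every polynomial, letting tests trade dynamic
    range against sampling noise at a given sequencing depth.
    """
    if midplane is None:
        midplane = (construct.span[0] + construct.span[1] - 1) / 2
    coeffs = {
        aa: tuple(scale * c for c in cs)
        for aa, cs in demo_polynomials().items()
    }
    return TruthLandscape.from_polynomials(
        coeffs, construct.wildtype_map(), midplane, rise
    )
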