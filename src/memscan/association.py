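"""Self-association landscapes corrected for insertion effects.

A mutation changes homodimer-reporter viability both through dimer-interface
energetics and through the membrane concentration of the two monomers; the
insertion contribution is therefore subtracted twice. Positions are then
labelled by how consistently substitutions disrupt binding, and candidate
C2 homodimer structures are filtered against those labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

from .energetics import EnergyLandscape, InsertionProfile

LIKELY = "likely_mediating_binding"
UNLIKELY = "unlikely_mediating_binding"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ZFrame:
    """Mapping from residue position to membrane depth Z (A)."""

    midplane: float
    rise: float = 1.5

    def z(self, position: int) -> float:
        return (position - self.midplane) * self.rise

    @classmethod
    def geometric_center(cls, span: tuple[int, int], rise: float = 1.5):
        """Fallback frame when no insertion selection exists for the
        construct: mid-plane at the span's geometric centre."""
        return cls(midplane=(span[0] + span[1] - 1) / 2, rise=rise)


@dataclass
class DimerLandscape:
    """Measured, insertion, and corrected self-association ddG tables."""

    ddg_measured: dict[tuple[int, str], float]
    ddg_insertion_used: dict[tuple[int, str], float]
    ddg_dimerization: dict[tuple[int, str], float]
    wildtype: dict[int, str]
    mask: frozenset[tuple[int, str]]
    censored: frozenset[tuple[int, str]]
    extrapolated: frozenset[tuple[int, str]]
    frame: ZFrame

    def __post_init__(self) -> None:
        for key, dim in self.ddg_dimerization.items():
            expect = self.ddg_measured[key] - 2.0 * self.ddg_insertion_used[key]
            if dim != expect:
                raise ValueError(f"correction identity violated at {key}")

    @property
    def positions(self) -> list[int]:
        return sorted(self.wildtype)


@dataclass(frozen=True)
class PositionLabel:
    position: int
    label: str
    n_disrupting: int
    n_neutral_or_better: int


def correct_dimerization(
    measured: EnergyLandscape,
    insertion_profile: InsertionProfile,
    frame: ZFrame,
) -> DimerLandscape:
    """Subtract twice the per-monomer insertion contribution.

    The insertion contribution of mutating wild type i -> j at depth Z is
    poly_j(Z) - poly_i(Z) from the fitted insertion polynomials (their
    common alanine reference cancels). Points whose Z lies outside the
    fitted range are corrected anyway but flagged as extrapolated.
    """
    z_lo, z_hi = insertion_profile.z_range
    meas = {}
    ins = {}
    dim = {}
    extrapolated = set()
    for (pos, aa), val in measured.ddg.items():
        wt = measured.wildtype[pos]
        z = frame.z(pos)
        try:
            contribution = insertion_profile.insertion_ddg(wt, aa, z)
        except KeyError:
            warnings.warn(
                f"no insertion profile for {wt}->{aa}; skipped {(pos, aa)}",
                stacklevel=2,
            )
            continue
        meas[(pos, aa)] = val
        ins[(pos, aa)] = contribution
        dim[(pos, aa)] = val - 2.0 * contribution
        if not z_lo <= z <= z_hi:
            extrapolated.add((pos, aa))
    return DimerLandscape(
        ddg_measured=meas,
        ddg_insertion_used=ins,
        ddg_dimerization=dim,
        wildtype=dict(measured.wildtype),
        mask=measured.mask,
        censored=measured.censored,
        extrapolated=frozenset(extrapolated),
        frame=frame,
    )


def classify_positions(
    dimer: DimerLandscape,
    disrupt_threshold: float = 2.0,
    min_substitutions: int = 4,
    neutral_tolerance: float = 0.2,
) -> list[PositionLabel]:
    """Label positions by how substitutions affect corrected binding.

    likely: at least ``min_substitutions`` substitutions disrupt binding by
    at least ``disrupt_threshold`` kcal/mol. unlikely: at least
    ``min_substitutions`` substitutions improve or do not change binding
    (ddG <= +neutral_tolerance). A position meeting both (or neither)
    criterion is indeterminate.
    """
    labels = []
    for pos in dimer.positions:
        wt = dimer.wildtype[pos]
        vals = [
            v for (p, aa), v in dimer.ddg_dimerization.items()
            if p == pos and aa != wt
        ]
        n_disrupt = sum(v >= disrupt_threshold for v in vals)
        n_neutral = sum(v <= neutral_tolerance for v in vals)
        likely = n_disrupt >= min_substitutions
        unlikely = n_neutral >= min_substitutions
        if likely and not unlikely:
            label = LIKELY
        elif unlikely and not likely:
            label = UNLIKELY
        else:
            label = INDETERMINATE
        labels.append(PositionLabel(pos, label, n_disrupt, n_neutral))
    return labels


# ---------------------------------------------------------------------------
# Structure filtering
# ---------------------------------------------------------------------------

class DimerModelError(ValueError):
    pass


@dataclass(frozen=True)
class FilterDecision:
    name: str
    accepted: bool
    n_likely_in_contact: int
    unlikely_violations: tuple[int, ...]


def _chain_sequences(atoms: struc.AtomArray) -> dict[str, list[str]]:
    out = {}
    for chain in np.unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == chain]
        ids, names = struc.get_residues(sub)
        out[str(chain)] = list(names)
    return out


def min_interchain_distances(
    atoms: struc.AtomArray, positions: Sequence[int]
) -> dict[int, float]:
    """Minimum heavy-atom distance from each labelled residue (on either
    chain) to any atom of the partner chain."""
    chains = np.unique(atoms.chain_id)
    heavy = atoms[atoms.element != "H"]
    trees = {
        c: cKDTree(heavy.coord[heavy.chain_id == c]) for c in chains
    }
    out = {}
    for pos in positions:
        best = np.inf
        for c in chains:
            partner = chains[chains != c][0]
            res = heavy.coord[(heavy.chain_id == c) & (heavy.res_id == pos)]
            if len(res) == 0:
                continue
            d, _ = trees[partner].query(res)
            best = min(best, float(np.min(d)))
        out[pos] = best
    return out


def filter_dimer_model(
    atoms: struc.AtomArray,
    labels: Sequence[PositionLabel],
    name: str = "model",
    likely_cutoff: float = 5.0,
    unlikely_cutoff: float = 4.0,
    min_likely_contacts: int = 2,
) -> FilterDecision:
    """Accept a C2 homodimer model iff at least ``min_likely_contacts``
    likely-binding positions touch the partner chain within
    ``likely_cutoff`` A and no unlikely-binding position comes within
    ``unlikely_cutoff`` A."""
    atoms = atoms[atoms.hetero == False]  # noqa: E712
    chains = np.unique(atoms.chain_id)
    if len(chains) != 2:
        raise DimerModelError(
            f"{name}: expected 2 chains, found {len(chains)}"
        )
    seqs = list(_chain_sequences(atoms).values())
    if seqs[0] != seqs[1]:
        raise DimerModelError(f"{name}: chain sequences differ")

    likely = [l.position for l in labels if l.label == LIKELY]
    unlikely = [l.position for l in labels if l.label == UNLIKELY]
    dists = min_interchain_distances(atoms, likely + unlikely)
    n_contact = sum(
        1 for p in likely if dists.get(p, np.inf) <= likely_cutoff
    )
    violations = tuple(
        p for p in unlikely if dists.get(p, np.inf) <= unlikely_cutoff
    )
    accepted = n_contact >= min_likely_contacts and not violations
    return FilterDecision(name, accepted, n_contact, violations)


def filter_dimer_models(
    model_paths: Sequence[str | Path],
    labels: Sequence[PositionLabel],
    likely_cutoff: float = 5.0,
    unlikely_cutoff: float = 4.0,
    min_likely_contacts: int = 2,
) -> list[FilterDecision]:
    """Apply the mutational-constraint filter to PDB files of C2 dimers."""
    decisions = []
    for path in model_paths:
        atoms = PDBFile.read(str(path)).get_structure(model=1)
        decisions.append(
            filter_dimer_model(
                atoms,
                labels,
                name=Path(path).stem,
                likely_cutoff=likely_cutoff,
                unlikely_cutoff=unlikely_cutoff,
                min_likely_contacts=min_likely_contacts,
            )
        )
    return decisions


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dimer_tsv(dimer: DimerLandscape, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# midplane={dimer.frame.midplane:g}\n")
        fh.write(f"# rise={dimer.frame.rise:g}\n")
        fh.write(
            "position\twt_aa\tmut_aa\tddg_measured\tddg_insertion\t"
            "ddg_dimerization\tcensored\textrapolated\n"
        )
        for (pos, aa) in sorted(dimer.ddg_dimerization):
            fh.write(
                f"{pos}\t{dimer.wildtype[pos]}\t{aa}\t"
                f"{dimer.ddg_measured[(pos, aa)]:.6f}\t"
                f"{dimer.ddg_insertion_used[(pos, aa)]:.6f}\t"
                f"{dimer.ddg_dimerization[(pos, aa)]:.6f}\t"
                f"{int((pos, aa) in dimer.censored)}\t"
                f"{int((pos, aa) in dimer.extrapolated)}\n"
            )


def write_labels_tsv(
    labels: Sequence[PositionLabel], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("position\tlabel\tn_disrupting\tn_neutral_or_better\n")
        for l in labels:
            fh.write(
                f"{l.position}\t{l.label}\t{l.n_disrupting}\t"
                f"{l.n_neutral_or_better}\n"
            )


def read_labels_tsv(path: str | Path) -> list[PositionLabel]:
    labels = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            pos, label, nd, nn = line.rstrip("\n").split("\t")
            labels.append(PositionLabel(int(pos), label, int(nd), int(nn)))
    return labels
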