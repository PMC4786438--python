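"""Atomic-solvation parameter inference.

Builds ideal alpha-helix models (canonical backbone dihedrals, sidechains in
the idealised template conformation), computes solvent-accessible surface
areas, the per-substitution change in SASA, and the ordinary-least-squares
regression of apparent insertion ddG against delta-SASA whose slope is the
apparent atomic-solvation parameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile
from scipy import stats

from .energetics import EnergyLandscape, InsertionProfile
from .genetic import AMINO_ACIDS

#: Identities treated as aliphatic in the core-substitution selection.
ALIPHATIC = ("A", "V", "I", "L", "M", "F")

#: Membrane-core depth window (A) used when selecting regression points;
#: asymmetric because the scanned span sits asymmetrically in the bilayer.
CORE_Z_WINDOW = (-9.0, 13.0)

#: Shrake-Rupley sphere sample count (deterministic Fibonacci spiral).
SASA_POINTS = 960

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# Canonical alpha-helix dihedrals (deg) and ideal backbone geometry.
PHI, PSI, OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


class HelixModelError(ValueError):
    pass


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float):
    """NeRF: position a new atom from three reference atoms + internal
    coordinates (angle/dihedral in degrees)."""
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _ideal_backbone(n_res: int) -> np.ndarray:
    """(n_res, 3, 3) coordinates of N, CA, C on a canonical helix."""
    coords = np.zeros((n_res, 3, 3))
    # seed residue: N at origin, CA along x, C in the xy plane
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [_B_N_CA, 0.0, 0.0]
    ang = np.deg2rad(_A_N_CA_C)
    coords[0, 2] = coords[0, 1] + _B_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1]
        coords[i, 0] = _place_atom(
            n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, PSI
        )
        coords[i, 1] = _place_atom(
            ca_prev, c_prev, coords[i, 0], _B_N_CA, _A_C_N_CA, OMEGA
        )
        coords[i, 2] = _place_atom(
            c_prev, coords[i, 0], coords[i, 1], _B_CA_C, _A_N_CA_C, PHI
        )
    return coords


@lru_cache(maxsize=None)
def _residue_template(aa: str) -> struc.AtomArray:
    res = struc_info.residue(_ONE_TO_THREE[aa])
    keep = (res.element != "H") & (res.atom_name != "OXT")
    return res[keep]


_B_C_O, _A_CA_C_O = 1.231, 120.8


def _fit_residue(aa: str, backbone_nca: np.ndarray) -> struc.AtomArray:
    """Superimpose a residue template onto a backbone N/CA/C frame.

    The backbone trace (N, CA, C) is pinned exactly to the ideal helix and
    the carbonyl O is rebuilt trans to the following amide so that the
    helical hydrogen-bonding geometry is sound; sidechain atoms keep the
    template's default conformation.
    """
    tmpl = _residue_template(aa).copy()
    idx = [int(np.where(tmpl.atom_name == nm)[0][0]) for nm in ("N", "CA", "C")]
    fixed = struc.AtomArray(3)
    fixed.coord = backbone_nca
    _, transform = struc.superimpose(fixed, tmpl[idx])
    fitted = transform.apply(tmpl)
    for j, nm in enumerate(("N", "CA", "C")):
        fitted.coord[fitted.atom_name == nm] = backbone_nca[j]
    n, ca, c = backbone_nca
    fitted.coord[fitted.atom_name == "O"] = _place_atom(
        n, ca, c, _B_C_O, _A_CA_C_O, PSI - 180.0
    )
    return fitted


@dataclass
class HelixModel:
    """An ideal alpha-helical model with heavy-atom coordinates."""

    sequence: str
    atoms: struc.AtomArray
    first_position: int = 1

    @property
    def positions(self) -> range:
        return range(
            self.first_position, self.first_position + len(self.sequence)
        )

    def residue_atoms(self, position: int) -> struc.AtomArray:
        return self.atoms[self.atoms.res_id == position]

    def aa_at(self, position: int) -> str:
        return self.sequence[position - self.first_position]

    def ca_coords(self) -> np.ndarray:
        return self.atoms.coord[self.atoms.atom_name == "CA"]

    def to_pdb(self, path: str | Path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.atoms)
        pdb.write(str(path))


def build_helix(sequence: str, first_position: int = 1) -> HelixModel:
    """Thread a sequence onto a canonical alpha helix.

    Backbone dihedrals are (phi, psi, omega) = (-57, -47, 180) degrees;
    sidechains adopt the idealised template conformation (a fixed default
    rotamer). Only heavy atoms are kept.
    """
    if not sequence:
        raise HelixModelError("empty sequence")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise HelixModelError(f"non-standard residues: {sorted(bad)}")
    backbone = _ideal_backbone(len(sequence))
    parts = []
    for i, aa in enumerate(sequence):
        res = _fit_residue(aa, backbone[i])
        res.res_id[:] = first_position + i
        res.chain_id[:] = "A"
        parts.append(res)
    atoms = struc.concatenate(parts)
    atoms.hetero[:] = False
    _warn_on_clashes(atoms)
    return HelixModel(sequence=sequence, atoms=atoms,
                      first_position=first_position)


def _warn_on_clashes(atoms: struc.AtomArray, cutoff: float = 0.5) -> None:
    coords = atoms.coord
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    # bonded neighbours are ~1.2-1.8 A apart; only sub-0.5 A is pathological
    if (dist < cutoff).any():
        warnings.warn("atoms closer than 0.5 A in helix model", stacklevel=3)


def sasa(
    model: HelixModel | struc.AtomArray,
    probe: float = 1.4,
    point_number: int = SASA_POINTS,
) -> dict[int, float]:
    """Per-residue solvent-accessible surface area (A^2).

    Shrake-Rupley style numerical SASA with the ProtOr united-atom radii
    and a deterministic Fibonacci point distribution.
    """
    atoms = model.atoms if isinstance(model, HelixModel) else model
    per_atom = struc.sasa(
        atoms, probe_radius=probe, point_number=point_number,
        vdw_radii="ProtOr",
    )
    out: dict[int, float] = {}
    for res_id in np.unique(atoms.res_id):
        vals = per_atom[atoms.res_id == res_id]
        out[int(res_id)] = float(np.nansum(vals))
    return out


def mutate(model: HelixModel, position: int, to_aa: str) -> HelixModel:
    """Replace one residue's sidechain, keeping the ideal backbone frame."""
    if to_aa not in _ONE_TO_THREE:
        raise HelixModelError(f"non-standard residue {to_aa!r}")
    res = model.residue_atoms(position)
    frame = np.stack(
        [res.coord[res.atom_name == nm][0] for nm in ("N", "CA", "C")]
    )
    new_res = _fit_residue(to_aa, frame)
    new_res.res_id[:] = position
    new_res.chain_id[:] = "A"
    parts = []
    for p in model.positions:
        parts.append(new_res if p == position else model.residue_atoms(p))
    atoms = struc.concatenate(parts)
    atoms.hetero[:] = False
    i = position - model.first_position
    seq = model.sequence[:i] + to_aa + model.sequence[i + 1 :]
    return HelixModel(sequence=seq, atoms=atoms,
                      first_position=model.first_position)


def delta_sasa(
    model: HelixModel,
    position: int,
    from_aa: str,
    to_aa: str,
    probe: float = 1.4,
    point_number: int = SASA_POINTS,
) -> float:
    """SASA(mutant) - SASA(wild) over the mutated residue's atoms (A^2)."""
    if model.aa_at(position) != from_aa:
        raise HelixModelError(
            f"model has {model.aa_at(position)} at {position}, not {from_aa}"
        )
    if from_aa == to_aa:
        return 0.0
    wild = sasa(model, probe, point_number)[position]
    mutant_model = mutate(model, position, to_aa)
    mut = sasa(mutant_model, probe, point_number)[position]
    return mut - wild


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionPoint:
    position: int
    from_aa: str
    to_aa: str
    z: float
    ddg: float  # kcal/mol
    dsasa: float | None = None  # A^2
    label: str = ""


@dataclass(frozen=True)
class SolvationFit:
    """OLS fit of ddG (kcal/mol) against delta-SASA (A^2)."""

    slope: float  # cal/mol/A^2
    intercept: float  # cal/mol
    r2: float
    slope_stderr: float  # cal/mol/A^2
    pvalue: float
    n: int
    points: tuple[SubstitutionPoint, ...]

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("at least 3 points are required")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 outside [0, 1]")

    @property
    def solvation_parameter(self) -> float:
        """Magnitude of the slope, cal/mol/A^2."""
        return abs(self.slope)

    def to_json(self, path: str | Path) -> None:
        data = {
            "slope_cal_per_mol_A2": self.slope,
            "intercept_cal_per_mol": self.intercept,
            "r2": self.r2,
            "slope_stderr": self.slope_stderr,
            "pvalue": self.pvalue,
            "n": self.n,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")


def fit_solvation(points: Sequence[SubstitutionPoint]) -> SolvationFit:
    """Ordinary least squares of ddG on delta-SASA.

    Burial of nonpolar surface stabilises insertion, so the slope is
    negative as plotted; report its magnitude as the atomic-solvation
    parameter. Units: input kcal/mol and A^2, output cal/mol/A^2.
    """
    pts = [p for p in points if p.dsasa is not None]
    if len(pts) < 3:
        raise ValueError("at least 3 points with delta-SASA are required")
    x = np.array([p.dsasa for p in pts])
    y = np.array([p.ddg for p in pts])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate delta-SASA variance; cannot fit")
    res = stats.linregress(x, y)
    return SolvationFit(
        slope=float(res.slope) * 1000.0,
        intercept=float(res.intercept) * 1000.0,
        r2=float(res.rvalue) ** 2,
        slope_stderr=float(res.stderr) * 1000.0,
        pvalue=float(res.pvalue),
        n=len(pts),
        points=tuple(pts),
    )


def core_substitution_points(
    landscape: EnergyLandscape,
    midplane: float,
    rise: float = 1.5,
    z_window: tuple[float, float] = CORE_Z_WINDOW,
    identities: Sequence[str] = ALIPHATIC,
) -> list[SubstitutionPoint]:
    """Aliphatic-to-aliphatic substitutions inside the membrane core.

    Selects unmasked variants whose wild-type and substituted identities
    both belong to ``identities`` and whose depth Z lies strictly inside
    ``z_window``. ddG values are apparent insertion energies (kcal/mol).
    """
    ids = set(identities)
    out = []
    for pos in landscape.positions:
        wt = landscape.wildtype[pos]
        if wt not in ids:
            continue
        z = (pos - midplane) * rise
        if not z_window[0] < z < z_window[1]:
            continue
        for aa in ids:
            if aa == wt:
                continue
            val = landscape.ddg.get((pos, aa))
            if val is None:
                continue
            out.append(SubstitutionPoint(pos, wt, aa, z, val))
    return out


def attach_delta_sasa(
    points: Iterable[SubstitutionPoint],
    model: HelixModel,
    probe: float = 1.4,
    point_number: int = SASA_POINTS,
) -> list[SubstitutionPoint]:
    """Compute delta-SASA on a helix model for each substitution point."""
    cache: dict[tuple[int, str, str], float] = {}
    out = []
    for p in points:
        key = (p.position, p.from_aa, p.to_aa)
        if key not in cache:
            cache[key] = delta_sasa(
                model, p.position, p.from_aa, p.to_aa, probe, point_number
            )
        out.append(
            SubstitutionPoint(
                p.position, p.from_aa, p.to_aa, p.z, p.ddg,
                dsasa=cache[key], label=p.label,
            )
        )
    return out


def midplane_aliphatic_points(
    profile: InsertionProfile,
    identities: Sequence[str] = ALIPHATIC,
    host_length: int = 23,
    probe: float = 1.4,
    point_number: int = SASA_POINTS,
) -> list[SubstitutionPoint]:
    """Mid-plane (Z=0) insertion energies of the aliphatics vs delta-SASA
    of an Ala->X substitution at the centre of a poly-Ala helix."""
    host = build_helix("A" * host_length)
    centre = host_length // 2 + 1
    out = []
    for aa in identities:
        if aa == "A" or aa in profile.unfit:
            continue
        ddg = profile.evaluate(aa, 0.0)
        ds = delta_sasa(host, centre, "A", aa, probe, point_number)
        out.append(
            SubstitutionPoint(centre, "A", aa, 0.0, ddg, dsasa=ds,
                              label="midplane")
        )
    return out


def write_points_tsv(
    points: Sequence[SubstitutionPoint], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("position\tfrom_aa\tto_aa\tz\tddg_kcal\tdsasa_A2\tlabel\n")
        for p in points:
            ds = "" if p.dsasa is None else f"{p.dsasa:.3f}"
            fh.write(
                f"{p.position}\t{p.from_aa}\t{p.to_aa}\t{p.z:.2f}\t"
                f"{p.ddg:.6f}\t{ds}\t{p.label}\n"
            )
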