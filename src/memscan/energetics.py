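"""Count tables -> apparent free-energy landscapes and insertion profiles.

The chain is: per-variant frequencies relative to wild type, selection
coefficients (selected/reference frequency ratio), Boltzmann conversion to
apparent ddG, alanine-referenced profiles smoothed along the span, mid-plane
estimation from the hydrophobic troughs, quartic profile fits over membrane
depth, and Boltzmann per-position amino-acid propensities.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic import AMINO_ACIDS
from .readcount import CountTable, apply_reference_filter
from .simulate import rt_kcal

HYDROPHOBIC_PROFILE_AAS = ("L", "I", "M", "F")


@dataclass
class EnergyLandscape:
    """Apparent ddG (kcal/mol) per (position, aa) with masking/censoring.

    ``ddg`` contains every unmasked variant plus the wild-type identities
    (exactly 0 in the raw landscape). ``censored`` variants had zero
    selected reads; their stored value is a pseudocount-based lower bound.
    """

    ddg: dict[tuple[int, str], float]
    mask: frozenset[tuple[int, str]]
    censored: frozenset[tuple[int, str]]
    wildtype: dict[int, str]
    temperature: float = 310.0
    reference_population: str = "reference"
    selected_population: str = "selected"
    reference_aa: str | None = None  # set to "A" after relative_to_ala

    def __post_init__(self) -> None:
        if not self.censored <= set(self.ddg):
            raise ValueError("censored variants must be unmasked")
        if self.mask & set(self.ddg):
            raise ValueError("masked variants must not carry values")
        if self.reference_aa is None:
            for pos, wt in self.wildtype.items():
                if self.ddg.get((pos, wt), 0.0) != 0.0:
                    raise ValueError(f"wild-type ddG at {pos} is not 0")

    @property
    def positions(self) -> list[int]:
        return sorted(self.wildtype)

    def value(self, position: int, aa: str) -> float | None:
        return self.ddg.get((position, aa))


@dataclass
class InsertionProfile:
    """Smoothed per-aa insertion values and quartic fits over depth Z (A).

    Coefficients are ascending (c0..c4); values are relative to alanine,
    whose profile is identically zero.
    """

    coefficients: dict[str, tuple[float, float, float, float, float]]
    points: dict[str, list[tuple[float, float]]]  # aa -> [(z, value)]
    residuals: dict[str, float]
    midplane: float
    rise: float
    excluded_positions: tuple[int, ...]
    unfit: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for aa, c in self.coefficients.items():
            if len(c) != 5:
                raise ValueError(f"{aa}: polynomial degree must be 4")

    @property
    def z_range(self) -> tuple[float, float]:
        zs = [z for pts in self.points.values() for z, _ in pts]
        return (min(zs), max(zs)) if zs else (0.0, 0.0)

    def evaluate(self, aa: str, z: float) -> float:
        if aa in self.unfit or aa not in self.coefficients:
            raise KeyError(f"no fitted profile for {aa!r}")
        return float(np.polynomial.Polynomial(self.coefficients[aa])(z))

    def insertion_ddg(self, from_aa: str, to_aa: str, z: float) -> float:
        """ddG of mutating ``from_aa`` -> ``to_aa`` at depth ``z``."""
        return self.evaluate(to_aa, z) - self.evaluate(from_aa, z)

    def z_of_position(self, position: float) -> float:
        return (position - self.midplane) * self.rise

    def to_json(self, path: str | Path) -> None:
        data = {
            "midplane": self.midplane,
            "rise": self.rise,
            "excluded_positions": list(self.excluded_positions),
            "z_range": list(self.z_range),
            "unfit": sorted(self.unfit),
            "coefficients": {
                aa: list(c) for aa, c in sorted(self.coefficients.items())
            },
            "residuals": dict(sorted(self.residuals.items())),
            "points": {
                aa: [[z, v] for z, v in pts]
                for aa, pts in sorted(self.points.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "InsertionProfile":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            coefficients={
                aa: tuple(c) for aa, c in data["coefficients"].items()
            },
            points={
                aa: [(z, v) for z, v in pts]
                for aa, pts in data["points"].items()
            },
            residuals=data["residuals"],
            midplane=data["midplane"],
            rise=data["rise"],
            excluded_positions=tuple(data["excluded_positions"]),
            unfit=frozenset(data["unfit"]),
        )


# ---------------------------------------------------------------------------
# Frequencies, selection coefficients, ddG (the core conversion)
# ---------------------------------------------------------------------------

def frequencies(table: CountTable) -> dict[tuple[int, str], float]:
    """Per-variant frequency relative to wild type.

    Wild-type identities get frequency 1 by definition.
    """
    if table.wildtype_count == 0:
        raise ValueError(
            f"population {table.population!r} has no wild-type reads; "
            "no landscape can be derived"
        )
    wt = float(table.wildtype_count)
    freqs = {}
    for pos in table.wildtype:
        for aa in AMINO_ACIDS:
            if aa == table.wildtype[pos]:
                freqs[(pos, aa)] = 1.0
            else:
                freqs[(pos, aa)] = table.counts.get((pos, aa), 0) / wt
    return freqs


def selection_coefficients(
    selected: CountTable,
    reference: CountTable,
    mask: Iterable[tuple[int, str]] = (),
) -> dict[tuple[int, str], float]:
    """Ratio of wild-type-normalized frequencies, selected over reference.

    Wild-type identities map to exactly 1. Variants whose selected count is
    zero get s = 0 (callers flag these as censored).
    """
    if set(selected.wildtype) != set(reference.wildtype):
        raise ValueError("populations cover different spans")
    mask = set(mask)
    f_sel = frequencies(selected)
    f_ref = frequencies(reference)
    s = {}
    for key, fr in f_ref.items():
        if key in mask:
            continue
        if fr == 0:
            raise ValueError(
                f"reference frequency is 0 for unmasked variant {key}; "
                "apply the reference-count filter first"
            )
        s[key] = f_sel[key] / fr
    return s


def to_ddg(
    s: Mapping[tuple[int, str], float],
    wildtype: Mapping[int, str],
    temperature: float = 310.0,
    censored_floor: Mapping[tuple[int, str], float] | None = None,
    mask: Iterable[tuple[int, str]] = (),
    reference_population: str = "reference",
    selected_population: str = "selected",
) -> EnergyLandscape:
    """Boltzmann conversion ddG = -RT ln(s).

    Variants with s = 0 are censored: the stored value is -RT ln of the
    corresponding entry in ``censored_floor`` (a pseudocount-based stand-in
    selection coefficient) and is only a lower bound on the true ddG.
    """
    rt = rt_kcal(temperature)
    ddg: dict[tuple[int, str], float] = {}
    censored = set()
    for key, val in s.items():
        if val < 0:
            raise ValueError(f"negative selection coefficient at {key}")
        if val == 0:
            if censored_floor is None or key not in censored_floor:
                raise ValueError(
                    f"selected count is 0 for {key} and no censoring floor "
                    "was provided"
                )
            ddg[key] = -rt * math.log(censored_floor[key])
            censored.add(key)
        else:
            ddg[key] = -rt * math.log(val)
    return EnergyLandscape(
        ddg=ddg,
        mask=frozenset(mask),
        censored=frozenset(censored),
        wildtype=dict(wildtype),
        temperature=temperature,
        reference_population=reference_population,
        selected_population=selected_population,
    )


def landscape_from_counts(
    reference: CountTable,
    selected: CountTable,
    min_count: int = 100,
    temperature: float = 310.0,
    pseudocount: float = 1.0,
) -> EnergyLandscape:
    """Full conversion: filter, selection coefficients, Boltzmann ddG.

    Censored variants (selected count 0) are assigned the selection
    coefficient they would have had with ``pseudocount`` selected reads,
    and flagged as lower bounds.
    """
    mask = apply_reference_filter(reference, min_count=min_count)
    s = selection_coefficients(selected, reference, mask=mask)
    wt_sel = float(selected.wildtype_count)
    wt_ref = float(reference.wildtype_count)
    floor = {
        key: (pseudocount / wt_sel)
        / (reference.counts.get(key, 0) / wt_ref)
        for key, val in s.items()
        if val == 0
    }
    return to_ddg(
        s,
        wildtype=reference.wildtype,
        temperature=temperature,
        censored_floor=floor,
        mask=mask,
        reference_population=reference.population,
        selected_population=selected.population,
    )


def relative_to_ala(landscape: EnergyLandscape) -> EnergyLandscape:
    """Re-reference every value to the alanine substitution at its position.

    Positions where alanine is masked are dropped entirely (with a
    warning), since no reference value exists there.
    """
    dropped = [
        pos for pos in landscape.positions
        if (pos, "A") not in landscape.ddg
    ]
    if dropped:
        warnings.warn(
            f"alanine masked at positions {dropped}; dropped from profiles",
            stacklevel=2,
        )
    keep = set(landscape.positions) - set(dropped)
    ddg = {
        (pos, aa): val - landscape.ddg[(pos, "A")]
        for (pos, aa), val in landscape.ddg.items()
        if pos in keep
    }
    return EnergyLandscape(
        ddg=ddg,
        mask=frozenset(k for k in landscape.mask if k[0] in keep),
        censored=frozenset(k for k in landscape.censored if k[0] in keep),
        wildtype={p: a for p, a in landscape.wildtype.items() if p in keep},
        temperature=landscape.temperature,
        reference_population=landscape.reference_population,
        selected_population=landscape.selected_population,
        reference_aa="A",
    )


# ---------------------------------------------------------------------------
# Smoothing, mid-plane, profile fitting
# ---------------------------------------------------------------------------

def smooth_profile(
    series: Mapping[int, float], window: int = 5
) -> dict[int, float]:
    """Centered running average over available neighbours.

    The window covers ``window`` consecutive positions (two on each side
    for the default). Near the span ends the window shrinks symmetrically;
    positions missing from ``series`` (masked/excluded) simply do not
    contribute. A position whose whole window is empty is omitted.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if not series:
        return {}
    half = window // 2
    lo, hi = min(series), max(series)
    out = {}
    for pos in sorted(series):
        h = min(half, pos - lo, hi - pos)
        vals = [
            series[p] for p in range(pos - h, pos + h + 1) if p in series
        ]
        if vals:
            out[pos] = float(np.mean(vals))
    return out


def profile_series(
    landscape: EnergyLandscape, aa: str,
    excluded_positions: Iterable[int] = (),
) -> dict[int, float]:
    """Alanine-referenced values of one amino acid along the span."""
    rel = landscape if landscape.reference_aa == "A" else relative_to_ala(
        landscape
    )
    excluded = set(excluded_positions)
    return {
        pos: rel.ddg[(pos, aa)]
        for pos in rel.positions
        if pos not in excluded and (pos, aa) in rel.ddg
    }


def estimate_midplane(
    landscape: EnergyLandscape,
    window: int = 5,
    hydrophobics: Sequence[str] = HYDROPHOBIC_PROFILE_AAS,
    excluded_positions: Iterable[int] = (),
) -> int:
    """Membrane mid-plane residue: trough of the hydrophobic profiles.

    Smoothes the alanine-referenced profiles of the hydrophobic residues
    and returns the position minimising their mean.
    """
    smoothed = []
    for aa in hydrophobics:
        series = profile_series(landscape, aa, excluded_positions)
        sm = smooth_profile(series, window=window)
        if sm:
            smoothed.append(sm)
    if len(smoothed) < 2:
        raise ValueError(
            "fewer than 2 hydrophobic profiles available; cannot estimate "
            "the mid-plane"
        )
    positions = sorted(set().union(*smoothed))
    means = {
        pos: np.mean([sm[pos] for sm in smoothed if pos in sm])
        for pos in positions
    }
    return min(means, key=lambda p: (means[p], p))


def fit_profiles(
    landscape: EnergyLandscape,
    midplane: float,
    rise: float = 1.5,
    window: int = 5,
    excluded_positions: Iterable[int] = (),
    min_points: int = 6,
) -> InsertionProfile:
    """Quartic least-squares fit of each smoothed profile over depth Z.

    Z = (position - midplane) * rise, negative on the cytoplasmic
    (N-terminal) side. Amino acids with fewer than ``min_points`` usable
    points are flagged unfit instead of being fitted.
    """
    excluded = tuple(sorted(set(excluded_positions)))
    coefficients = {}
    points: dict[str, list[tuple[float, float]]] = {}
    residuals = {}
    unfit = set()
    for aa in AMINO_ACIDS:
        series = profile_series(landscape, aa, excluded)
        sm = smooth_profile(series, window=window)
        pts = [((pos - midplane) * rise, val) for pos, val in sorted(sm.items())]
        points[aa] = pts
        if len(pts) < min_points:
            unfit.add(aa)
            continue
        z = np.array([p[0] for p in pts])
        v = np.array([p[1] for p in pts])
        poly = np.polynomial.Polynomial.fit(z, v, deg=4).convert()
        coefficients[aa] = tuple(float(c) for c in poly.coef) + (0.0,) * (
            5 - len(poly.coef)
        )
        residuals[aa] = float(np.sqrt(np.mean((poly(z) - v) ** 2)))
    return InsertionProfile(
        coefficients=coefficients,
        points=points,
        residuals=residuals,
        midplane=float(midplane),
        rise=rise,
        excluded_positions=excluded,
        unfit=frozenset(unfit),
    )


# ---------------------------------------------------------------------------
# Propensities
# ---------------------------------------------------------------------------

def propensities(
    energies: EnergyLandscape | Mapping[tuple[int, str], float],
    temperature: float = 310.0,
) -> dict[tuple[int, str], float]:
    """Boltzmann-weighted amino-acid probabilities at each position.

    Censored energies enter through their stored lower bounds. At each
    position the probabilities are normalised over the amino acids with a
    defined energy.
    """
    table = energies.ddg if isinstance(energies, EnergyLandscape) else energies
    rt = rt_kcal(temperature)
    by_pos: dict[int, dict[str, float]] = {}
    for (pos, aa), e in table.items():
        by_pos.setdefault(pos, {})[aa] = e
    out = {}
    for pos, es in by_pos.items():
        arr = np.array(list(es.values()))
        w = np.exp(-(arr - arr.min()) / rt)  # shift-invariant, overflow-safe
        w /= w.sum()
        for aa, p in zip(es, w):
            out[(pos, aa)] = float(p)
    return out


def propensities_from_profile(
    profile: InsertionProfile,
    positions: Sequence[int],
    temperature: float = 310.0,
) -> dict[tuple[int, str], float]:
    """Propensities evaluated from the fitted polynomials at each position."""
    table = {
        (pos, aa): profile.evaluate(aa, profile.z_of_position(pos))
        for pos in positions
        for aa in AMINO_ACIDS
        if aa not in profile.unfit
    }
    return propensities(table, temperature)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_landscape_tsv(landscape: EnergyLandscape, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature={landscape.temperature:g}\n")
        fh.write(f"# reference={landscape.reference_population}\n")
        fh.write(f"# selected={landscape.selected_population}\n")
        if landscape.reference_aa:
            fh.write(f"# reference_aa={landscape.reference_aa}\n")
        fh.write("position\twt_aa\tmut_aa\tddg\tmasked\tcensored\n")
        for pos in landscape.positions:
            wt = landscape.wildtype[pos]
            for aa in AMINO_ACIDS:
                key = (pos, aa)
                masked = key in landscape.mask
                val = "" if masked else f"{landscape.ddg[key]:.6f}"
                fh.write(
                    f"{pos}\t{wt}\t{aa}\t{val}\t{int(masked)}\t"
                    f"{int(key in landscape.censored)}\n"
                )


def read_landscape_tsv(path: str | Path) -> EnergyLandscape:
    meta: dict[str, str] = {}
    ddg: dict[tuple[int, str], float] = {}
    mask = set()
    censored = set()
    wildtype: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
                continue
            if not line or line.startswith("position\t"):
                continue
            pos_s, wt, aa, val, masked, cens = line.split("\t")
            pos = int(pos_s)
            wildtype[pos] = wt
            key = (pos, aa)
            if int(masked):
                mask.add(key)
            else:
                ddg[key] = float(val)
                if int(cens):
                    censored.add(key)
    return EnergyLandscape(
        ddg=ddg,
        mask=frozenset(mask),
        censored=frozenset(censored),
        wildtype=wildtype,
        temperature=float(meta.get("temperature", 310.0)),
        reference_population=meta.get("reference", "reference"),
        selected_population=meta.get("selected", "selected"),
        reference_aa=meta.get("reference_aa") or None,
    )


def write_propensity_matrix(
    props: Mapping[tuple[int, str], float], path: str | Path
) -> None:
    """Position-weight-matrix layout: rows are positions, columns the 20 aa."""
    positions = sorted({pos for pos, _ in props})
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\n")
        for pos in positions:
            row = [f"{props.get((pos, aa), 0.0):.6f}" for aa in AMINO_ACIDS]
            fh.write(f"{pos}\t" + "\t".join(row) + "\n")
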