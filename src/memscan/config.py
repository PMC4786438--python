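"""Run configuration and the two end-to-end pipelines.

The insertion pipeline turns a reference population (non-selective plates)
and an insertion-selected population into a ddG landscape, depth profiles,
and propensities. The association pipeline uses the insertion-selected
population as its reference, corrects the measured landscape with an
insertion profile, and labels candidate interface positions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .association import (
    ZFrame,
    classify_positions,
    correct_dimerization,
    write_dimer_tsv,
    write_labels_tsv,
)
from .constructs import Construct, load_construct
from .energetics import (
    InsertionProfile,
    estimate_midplane,
    fit_profiles,
    landscape_from_counts,
    propensities,
    relative_to_ala,
    write_landscape_tsv,
    write_propensity_matrix,
)
from .readcount import (
    CountTable,
    count_population,
    read_counts_tsv,
    write_counts_tsv,
    write_qc_json,
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    construct: str
    populations: dict[str, dict[str, str]]  # role -> {r1,r2} or {counts}
    outdir: str = "memscan_out"
    min_count: int = 100
    window: int = 5
    poly_order: int = 4
    temperature: float = 310.0
    rise: float = 1.5
    pseudocount: float = 1.0
    excluded_positions: list[int] = field(default_factory=list)
    insertion_profile: str | None = None
    disrupt_threshold: float = 2.0
    min_substitutions: int = 4
    neutral_tolerance: float = 0.2
    likely_cutoff: float = 5.0
    unlikely_cutoff: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.window < 1 or self.window % 2 == 0:
            raise ConfigError("invalid min_count/window")
        if self.poly_order != 4:
            raise ConfigError("profile fits are fixed at polynomial order 4")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        for role, files in self.populations.items():
            for path in files.values():
                if not Path(path).exists():
                    raise ConfigError(f"{role}: missing input file {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def resolve_construct(self) -> Construct:
        return load_construct(self.construct)


def _load_population(
    config: RunConfig, role: str, construct: Construct
) -> CountTable:
    try:
        files = config.populations[role]
    except KeyError:
        raise ConfigError(f"population role {role!r} not configured") from None
    if "counts" in files:
        table = read_counts_tsv(files["counts"])
        table.population = role
        return table
    table = count_population(files["r1"], files["r2"], construct, role)
    return table


def _write_provenance(config: RunConfig, outdir: Path, stage: str) -> None:
    record = {
        "stage": stage,
        "memscan_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    with open(outdir / f"provenance_{stage}.json", "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_insertion_pipeline(config: RunConfig) -> dict[str, object]:
    """Reference + insertion-selected counts -> landscape/profiles bundle."""
    construct = config.resolve_construct()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = _load_population(config, "reference", construct)
    selected = _load_population(config, "selected", construct)
    for table in (reference, selected):
        write_counts_tsv(table, outdir / f"counts_{table.population}.tsv")
        write_qc_json(table, outdir / f"qc_{table.population}.json")

    landscape = landscape_from_counts(
        reference,
        selected,
        min_count=config.min_count,
        temperature=config.temperature,
        pseudocount=config.pseudocount,
    )
    write_landscape_tsv(landscape, outdir / "landscape.tsv")

    midplane = estimate_midplane(
        landscape,
        window=config.window,
        excluded_positions=config.excluded_positions,
    )
    profile = fit_profiles(
        landscape,
        midplane=midplane,
        rise=config.rise,
        window=config.window,
        excluded_positions=config.excluded_positions,
    )
    profile.to_json(outdir / "insertion_profile.json")

    rel = relative_to_ala(landscape)
    props = propensities(rel, temperature=config.temperature)
    write_propensity_matrix(props, outdir / "propensities.tsv")

    _write_provenance(config, outdir, "insertion")
    return {
        "construct": construct,
        "reference": reference,
        "selected": selected,
        "landscape": landscape,
        "midplane": midplane,
        "profile": profile,
        "propensities": props,
    }


def run_association_pipeline(config: RunConfig) -> dict[str, object]:
    """Association-selected counts + insertion profile -> dimer bundle.

    The insertion-selected population plays the reference role here; the
    doubly selected population is the selected one.
    """
    construct = config.resolve_construct()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.insertion_profile is None:
        raise ConfigError("association pipeline needs an insertion_profile")
    profile = InsertionProfile.from_json(config.insertion_profile)

    reference = _load_population(config, "reference", construct)
    selected = _load_population(config, "selected", construct)
    for table in (reference, selected):
        write_counts_tsv(table, outdir / f"counts_{table.population}.tsv")
        write_qc_json(table, outdir / f"qc_{table.population}.json")

    measured = landscape_from_counts(
        reference,
        selected,
        min_count=config.min_count,
        temperature=config.temperature,
        pseudocount=config.pseudocount,
    )
    write_landscape_tsv(measured, outdir / "landscape_measured.tsv")

    frame = ZFrame.geometric_center(construct.span, rise=config.rise)
    dimer = correct_dimerization(measured, profile, frame)
    write_dimer_tsv(dimer, outdir / "landscape_dimerization.tsv")

    labels = classify_positions(
        dimer,
        disrupt_threshold=config.disrupt_threshold,
        min_substitutions=config.min_substitutions,
        neutral_tolerance=config.neutral_tolerance,
    )
    write_labels_tsv(labels, outdir / "position_labels.tsv")

    _write_provenance(config, outdir, "association")
    return {
        "construct": construct,
        "measured": measured,
        "dimer": dimer,
        "labels": labels,
        "frame": frame,
    }
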