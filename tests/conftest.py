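"""Shared fixtures: synthetic constructs and a moderately deep simulated
scan reused by several test modules (session-scoped; ~seconds to build)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from memscan.constructs import enumerate_library
from memscan.energetics import (
    estimate_midplane,
    fit_profiles,
    landscape_from_counts,
)
from memscan.simulate import (
    SimConfig,
    make_demo_truth,
    make_scan_construct,
    simulate_reference_counts,
    simulate_selected_counts,
)

settings.register_profile("ci", deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scan27():
    """27-position synthetic scan construct."""
    return make_scan_construct(span_length=27, seed=1)


@pytest.fixture(scope="session")
def sim_bundle(scan27):
    """Simulated reference/selected populations plus derived landscape."""
    config = SimConfig(
        depth_reference=400_000,
        depth_selected=400_000,
        clonal_bias_sigma=0.4,
        seed=11,
    )
    truth = make_demo_truth(scan27, scale=0.6)
    library = enumerate_library(scan27)
    reference = simulate_reference_counts(library, config)
    selected = simulate_selected_counts(reference, truth, config)
    landscape = landscape_from_counts(reference, selected)
    midplane = estimate_midplane(landscape)
    profile = fit_profiles(landscape, midplane)
    return {
        "construct": scan27,
        "config": config,
        "truth": truth,
        "library": library,
        "reference": reference,
        "selected": selected,
        "landscape": landscape,
        "midplane": midplane,
        "profile": profile,
    }


@pytest.fixture(scope="session")
def polyala_helix():
    from memscan.solvation import build_helix

    return build_helix("A" * 21)
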