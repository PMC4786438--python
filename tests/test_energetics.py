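"""Frequency ratios, Boltzmann ddG, smoothing, mid-plane, profile fits,
and propensities."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from memscan.energetics import (
    EnergyLandscape,
    estimate_midplane,
    fit_profiles,
    frequencies,
    landscape_from_counts,
    propensities,
    read_landscape_tsv,
    relative_to_ala,
    selection_coefficients,
    smooth_profile,
    to_ddg,
    write_landscape_tsv,
)
from memscan.genetic import AMINO_ACIDS
from memscan.readcount import CountTable
from memscan.simulate import rt_kcal

RT = 0.616032  # kcal/mol at 310 K with R = 1.9872e-3


def table(counts, wt_count, population="reference", wildtype=None):
    wildtype = wildtype or {1: "A"}
    return CountTable(
        population=population, counts=counts, wildtype_count=wt_count,
        wildtype=wildtype,
    )


def flat_landscape(values, wildtype, **kw):
    return EnergyLandscape(
        ddg=values, mask=frozenset(), censored=frozenset(),
        wildtype=wildtype, **kw
    )


class TestFrequencies:
    def test_examples(self):
        t = table({(1, "L"): 1000, (1, "K"): 500}, 1000)
        f = frequencies(t)
        assert f[(1, "L")] == 1.0
        assert f[(1, "K")] == 0.5
        assert f[(1, "A")] == 1.0  # wild type by definition

    def test_duplication_invariance(self):
        t1 = table({(1, "L"): 300}, 600)
        t2 = table({(1, "L"): 600}, 1200)
        assert frequencies(t1) == frequencies(t2)

    def test_zero_wildtype_is_hard_error(self):
        with pytest.raises(ValueError, match="wild-type"):
            frequencies(table({(1, "L"): 5}, 0))


class TestSelectionCoefficients:
    def test_identical_populations_give_unity(self):
        t = table({(1, aa): 100 + i for i, aa in enumerate("CDEFG")}, 800)
        mask = {(1, aa) for aa in AMINO_ACIDS if aa not in "ACDEFG"}
        s = selection_coefficients(t, t, mask=mask)
        assert len(s) == 6
        assert all(v == pytest.approx(1.0) for v in s.values())

    def test_halved_frequency(self):
        ref = table({(1, "L"): 200}, 1000)
        sel = table({(1, "L"): 100}, 1000, population="selected")
        mask = {(1, aa) for aa in AMINO_ACIDS if aa not in "AL"}
        assert selection_coefficients(sel, ref, mask=mask)[(1, "L")] == 0.5

    def test_zero_reference_requires_mask(self):
        ref = table({}, 1000)
        sel = table({(1, "L"): 10}, 1000)
        with pytest.raises(ValueError, match="filter"):
            selection_coefficients(sel, ref)
        # masked: fine
        masked = {(1, aa) for aa in AMINO_ACIDS if aa != "A"}
        assert selection_coefficients(sel, ref, mask=masked) == {(1, "A"): 1.0}


class TestToDdg:
    def test_s_one_maps_to_exact_zero(self):
        ls = to_ddg({(1, "L"): 1.0}, {1: "A"})
        assert ls.ddg[(1, "L")] == 0.0

    def test_rt_closed_form(self):
        ls = to_ddg({(1, "L"): math.exp(-1.0)}, {1: "A"})
        assert ls.ddg[(1, "L")] == pytest.approx(RT, abs=1e-9)
        assert rt_kcal(310.0) == pytest.approx(0.616032, abs=1e-12)

    def test_hand_computed_counts(self):
        # ref (mut 1000, wt 1000), sel (mut 100, wt 1000): s = 0.1
        ref = table({(1, "L"): 1000}, 1000)
        sel = table({(1, "L"): 100}, 1000, population="selected")
        ls = landscape_from_counts(ref, sel, min_count=100)
        # oracle: -RT ln 0.1, computed independently
        assert ls.ddg[(1, "L")] == pytest.approx(1.4184668, abs=1e-6)
        assert ls.ddg[(1, "L")] == pytest.approx(
            -RT * math.log(0.1), abs=1e-9
        )

    def test_monotone_decreasing_in_s(self):
        svals = [0.01, 0.1, 0.5, 1.0, 2.0, 10.0]
        ls = to_ddg(
            {(1, aa): s for aa, s in zip("CDEFGH", svals)}, {1: "A"}
        )
        out = [ls.ddg[(1, aa)] for aa in "CDEFGH"]
        assert all(a > b for a, b in zip(out, out[1:]))

    def test_censoring_lower_bound(self):
        ref = table({(1, "K"): 500, (1, "L"): 500}, 1000)
        sel = table({(1, "L"): 400}, 800, population="selected")
        ls = landscape_from_counts(ref, sel, min_count=100, pseudocount=1.0)
        assert (1, "K") in ls.censored
        expected = -RT * math.log((1.0 / 800) / (500 / 1000))
        assert ls.ddg[(1, "K")] == pytest.approx(expected, abs=1e-9)
        assert (1, "L") not in ls.censored

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            to_ddg({(1, "L"): -0.5}, {1: "A"})

    def test_role_swap_negates(self):
        ref = table({(1, aa): 400 for aa in "CDEFG"}, 1000)
        sel = table(
            {(1, aa): c for aa, c in zip("CDEFG", (150, 350, 420, 900, 111))},
            1000, population="selected",
        )
        fwd = landscape_from_counts(ref, sel, min_count=100)
        rev = landscape_from_counts(sel, ref, min_count=100)
        for aa in "CDEFG":
            assert fwd.ddg[(1, aa)] == pytest.approx(-rev.ddg[(1, aa)])


class TestRelativeToAla:
    @pytest.fixture
    def landscape(self):
        wildtype = {1: "L", 2: "V"}
        ddg = {}
        for pos, off in ((1, 0.7), (2, -0.3)):
            for i, aa in enumerate(AMINO_ACIDS):
                ddg[(pos, aa)] = 0.1 * i + off
            ddg[(pos, wildtype[pos])] = 0.0
        return flat_landscape(ddg, wildtype)

    def test_ala_column_zero(self, landscape):
        rel = relative_to_ala(landscape)
        assert all(rel.ddg[(p, "A")] == 0.0 for p in rel.positions)

    def test_add_back_restores(self, landscape):
        rel = relative_to_ala(landscape)
        for key, val in rel.ddg.items():
            ala = landscape.ddg[(key[0], "A")]
            assert val + ala == pytest.approx(landscape.ddg[key])

    def test_constant_offset_annihilated(self, landscape):
        shifted = flat_landscape(
            {k: v + 5.0 for k, v in landscape.ddg.items()},
            landscape.wildtype, reference_aa="raw-shifted",
        )
        a = relative_to_ala(landscape)
        b = relative_to_ala(shifted)
        for key in a.ddg:
            assert a.ddg[key] == pytest.approx(b.ddg[key])

    def test_masked_ala_drops_position(self):
        ddg = {(1, aa): 0.5 for aa in AMINO_ACIDS if aa != "A"}
        ddg[(1, "L")] = 0.0
        ls = EnergyLandscape(
            ddg=ddg, mask=frozenset({(1, "A")}), censored=frozenset(),
            wildtype={1: "L"},
        )
        with pytest.warns(UserWarning, match="alanine"):
            rel = relative_to_ala(ls)
        assert rel.positions == []


class TestSmoothing:
    def test_constant_unchanged(self):
        series = {i: 2.5 for i in range(10)}
        assert smooth_profile(series) == series

    def test_linear_interior_unchanged(self):
        series = {i: 0.5 * i for i in range(11)}
        sm = smooth_profile(series)
        for i in range(2, 9):
            assert sm[i] == pytest.approx(series[i])

    def test_spike_averaged(self):
        sm = smooth_profile({0: 0, 1: 0, 2: 5, 3: 0, 4: 0})
        assert sm[2] == pytest.approx(1.0)

    def test_shrinking_window_at_ends(self):
        sm = smooth_profile({0: 0, 1: 0, 2: 5, 3: 0, 4: 0})
        assert sm[0] == 0.0  # half-width shrinks to 0 at the edge
        assert sm[1] == pytest.approx(5 / 3)

    def test_masked_neighbours_skipped(self):
        # position 2 missing entirely: it contributes nothing and is
        # absent from the output
        sm = smooth_profile({0: 1.0, 1: 1.0, 2: 1.0, 4: 4.0, 5: 4.0,
                             6: 4.0})
        assert 3 not in sm
        assert sm[2] == pytest.approx((1 + 1 + 1 + 4) / 4)
        assert sm[4] == pytest.approx((1 + 4 + 4 + 4) / 4)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile({0: 1.0}, window=4)

    @given(
        st.dictionaries(
            st.integers(min_value=0, max_value=30),
            st.floats(min_value=-5, max_value=5),
            min_size=1,
        )
    )
    def test_smoothing_bounded_by_extremes(self, series):
        sm = smooth_profile(series)
        lo, hi = min(series.values()), max(series.values())
        assert all(lo - 1e-9 <= v <= hi + 1e-9 for v in sm.values())


def trough_landscape(center, positions, wildtype_aa="G"):
    """Symmetric parabolic troughs for the hydrophobics around ``center``."""
    ddg = {}
    wildtype = {p: wildtype_aa for p in positions}
    for p in positions:
        for aa in AMINO_ACIDS:
            if aa in "LIMF":
                ddg[(p, aa)] = 0.05 * (p - center) ** 2 - 2.0
            elif aa != wildtype_aa:
                ddg[(p, aa)] = 0.5
        ddg[(p, wildtype_aa)] = 0.0
        ddg[(p, "A")] = 0.1
    return flat_landscape(ddg, wildtype)


class TestMidplane:
    def test_symmetric_trough_recovered(self):
        ls = trough_landscape(15, range(5, 26))
        assert estimate_midplane(ls) == 15

    def test_shift_equivariance(self):
        a = trough_landscape(15, range(5, 26))
        b = trough_landscape(18, range(8, 29))
        assert estimate_midplane(b) == estimate_midplane(a) + 3

    def test_too_few_profiles_error(self):
        ddg = {(p, "A"): 0.0 for p in range(10)}
        ddg.update({(p, "L"): -1.0 for p in range(10)})
        ls = flat_landscape(ddg, {p: "A" for p in range(10)})
        with pytest.raises(ValueError, match="hydrophobic"):
            estimate_midplane(ls)


class TestFitProfiles:
    def test_known_quartic_recovered_exactly(self):
        # no noise, smoothing disabled: plain least squares must
        # interpolate the quartic to numerical precision
        coeffs = (0.3, -0.05, 0.02, 0.001, 3e-5)
        poly = np.polynomial.Polynomial(coeffs)
        positions = range(1, 24)
        midplane, rise = 12, 1.5
        wildtype = {p: "G" for p in positions}
        ddg = {}
        for p in positions:
            z = (p - midplane) * rise
            for aa in AMINO_ACIDS:
                ddg[(p, aa)] = float(poly(z)) if aa == "L" else 0.0
            ddg[(p, "G")] = 0.0
            ddg[(p, "A")] = 0.0
        ls = flat_landscape(ddg, wildtype)
        prof = fit_profiles(ls, midplane=midplane, rise=rise, window=1)
        assert np.allclose(prof.coefficients["L"], coeffs, atol=1e-9)

    def test_ala_fit_is_zero_polynomial(self, sim_bundle):
        prof = sim_bundle["profile"]
        assert np.allclose(prof.coefficients["A"], 0.0, atol=1e-9)

    def test_too_few_points_flagged(self):
        positions = range(1, 5)  # 4 points < 6 required
        wildtype = {p: "G" for p in positions}
        ddg = {(p, aa): 0.1 for p in positions for aa in AMINO_ACIDS}
        for p in positions:
            ddg[(p, "G")] = 0.0
        ls = flat_landscape(ddg, wildtype)
        prof = fit_profiles(ls, midplane=2.5)
        assert prof.unfit == frozenset(AMINO_ACIDS)

    def test_excluded_positions_absent_from_fit(self, sim_bundle):
        ls = sim_bundle["landscape"]
        mid = sim_bundle["midplane"]
        excl = (mid - 1, mid)
        prof = fit_profiles(ls, midplane=mid, excluded_positions=excl)
        zs = {z for z, _ in prof.points["L"]}
        assert not {(p - mid) * 1.5 for p in excl} & zs

    def test_simulation_truth_profile_recovery(self, sim_bundle):
        # full-pipeline: fitted polynomials track the generating truth
        from memscan.simulate import demo_polynomials

        prof = sim_bundle["profile"]
        scale = 0.6
        zs = np.linspace(-15, 15, 61)
        for aa in ("L", "F", "S", "G", "K"):
            truth_poly = np.polynomial.Polynomial(
                [scale * c for c in demo_polynomials()[aa]]
            )
            fit = np.array([prof.evaluate(aa, z) for z in zs])
            assert np.max(np.abs(fit - truth_poly(zs))) <= 0.2


class TestPropensities:
    def test_uniform_energies(self):
        ddg = {(1, aa): 0.7 for aa in AMINO_ACIDS}
        props = propensities(ddg)
        assert all(v == pytest.approx(0.05) for v in props.values())

    def test_dominant_low_energy(self):
        ddg = {(1, aa): 0.0 for aa in AMINO_ACIDS}
        ddg[(1, "L")] = -50.0
        assert propensities(ddg)[(1, "L")] == pytest.approx(1.0, abs=1e-12)

    def test_leucine_example(self):
        # E_Leu = -2, rest 0: p = e^(2/RT) / (e^(2/RT) + 19)
        ddg = {(1, aa): 0.0 for aa in AMINO_ACIDS}
        ddg[(1, "L")] = -2.0
        w = math.exp(2.0 / RT)
        assert propensities(ddg)[(1, "L")] == pytest.approx(
            w / (w + 19), rel=1e-9
        )
        assert propensities(ddg)[(1, "L")] == pytest.approx(0.575, abs=2e-3)

    def test_rows_sum_to_one(self, sim_bundle):
        props = propensities(relative_to_ala(sim_bundle["landscape"]))
        by_pos = {}
        for (pos, _), v in props.items():
            by_pos[pos] = by_pos.get(pos, 0.0) + v
        assert all(abs(t - 1.0) < 1e-12 for t in by_pos.values())

    @given(st.floats(min_value=-10, max_value=10))
    def test_shift_invariance(self, shift):
        base = {(1, aa): 0.3 * i for i, aa in enumerate(AMINO_ACIDS)}
        shifted = {k: v + shift for k, v in base.items()}
        a, b = propensities(base), propensities(shifted)
        assert all(a[k] == pytest.approx(b[k], rel=1e-9) for k in a)


class TestEndToEndOracle:
    def test_noiseless_recovery_is_exact(self, scan27):
        # expected (not sampled) frequencies pushed through the full
        # conversion reproduce the generating truth to float precision
        from memscan.constructs import enumerate_library
        from memscan.simulate import (
            SimConfig,
            expected_selected_frequencies,
            make_demo_truth,
            simulate_reference_counts,
        )

        truth = make_demo_truth(scan27, scale=0.6)
        ref = simulate_reference_counts(
            enumerate_library(scan27),
            SimConfig(depth_reference=500_000, seed=23,
                      clonal_bias_sigma=0.3),
        )
        freqs = expected_selected_frequencies(ref, truth)
        s = {
            key: (freqs[key] / freqs["WT"])
            / (ref.counts[key] / ref.wildtype_count)
            for key in ref.counts
        }
        ls = to_ddg(s, wildtype=ref.wildtype)
        for key, val in ls.ddg.items():
            if key in s:
                assert val == pytest.approx(truth.ddg(*key), abs=1e-9)


class TestLandscapeIO:
    def test_tsv_round_trip(self, sim_bundle, tmp_path):
        ls = sim_bundle["landscape"]
        path = tmp_path / "landscape.tsv"
        write_landscape_tsv(ls, path)
        back = read_landscape_tsv(path)
        assert back.mask == ls.mask
        assert back.censored == ls.censored
        assert back.wildtype == ls.wildtype
        for key, val in ls.ddg.items():
            assert back.ddg[key] == pytest.approx(val, abs=1e-6)
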