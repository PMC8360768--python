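import json

import numpy as np
import pytest

from chromlgn import stimdesign as sd
from chromlgn.photoreceptors import (
    Opsin,
    SpectralCurve,
    default_lens,
    nomogram_sensitivity,
)

# Frozen from scripts/oracles/oracle_stimdesign.py (independent flux matrix +
# brute-force scan of the free modulation DOF, coarse 1e-4 then refined).
ORACLE_ROD45_MEL = 0.4515367715
ORACLE_L75_MINMAX = 0.0118356737
ORACLE_S75_MINMAX = 0.0105572136
ORACLE_STEP_MEL_RATIO = 875.8069681943509
ORACLE_STEP_ROD_RATIO = 188.16539361643711


def recompute_contrast_from_drives(primaries, bright_drives, dim_drives,
                                   opsin_name):
    """Independent spectra -> flux -> Michelson path used as a test oracle."""
    g = primaries[0].spectrum.grid
    lens = default_lens(g)
    sens = nomogram_sensitivity(Opsin(opsin_name), g)
    bright = sum(d * p.spectrum.values for d, p in zip(bright_drives, primaries))
    dim = sum(d * p.spectrum.values for d, p in zip(dim_drives, primaries))
    fb = np.trapezoid(bright * sens.values * lens.transmission, g.wavelengths)
    fd = np.trapezoid(dim * sens.values * lens.transmission, g.wavelengths)
    return (fb - fd) / (fb + fd)


class TestSolver:
    def test_all_zero_targets(self, primaries, daylight_bg):
        spec = sd.ContrastSpec({"L": ("target", 0.0), "S": ("target", 0.0)})
        sol = sd.solve_silent_substitution(primaries, daylight_bg, spec)
        np.testing.assert_allclose(sol.delta_drives, 0.0, atol=1e-12)
        for v in sol.achieved.values():
            assert abs(v) < 1e-12

    def test_rod_isolating_silences_cones(self, battery):
        sol = battery["Rod"]
        assert sol.feasible
        assert sol.achieved["rod"] == pytest.approx(0.45, abs=1e-6)
        # paper bound: < 0.05% contrast for cones
        assert abs(sol.achieved["L"]) < 5e-4
        assert abs(sol.achieved["S"]) < 5e-4

    def test_rod_isolating_mel_contrast_matches_oracle(self, battery):
        assert abs(battery["Rod"].achieved["mel"]) == pytest.approx(
            ORACLE_ROD45_MEL, abs=1e-6)

    @pytest.mark.parametrize("name,oracle", [("L_Only", ORACLE_L75_MINMAX),
                                             ("S_Only", ORACLE_S75_MINMAX)])
    def test_cone_isolating_residual_matches_grid_search_oracle(
            self, battery, name, oracle):
        sol = battery[name]
        assert sol.feasible
        resid = max(abs(sol.achieved["rod"]), abs(sol.achieved["mel"]))
        assert resid == pytest.approx(oracle, abs=5e-5)

    def test_silenced_cone_residual_below_paper_bound(self, battery):
        # paper: < 0.2% Michelson for the silenced cone
        assert abs(battery["L_Only"].achieved["S"]) < 0.002
        assert abs(battery["S_Only"].achieved["L"]) < 0.002

    def test_targets_hit_to_tolerance(self, battery):
        assert battery["L_Only"].achieved["L"] == pytest.approx(0.75, abs=1e-6)
        assert battery["S_Only"].achieved["S"] == pytest.approx(0.75, abs=1e-6)
        assert battery["L-S"].achieved["S"] == pytest.approx(-0.75, abs=1e-6)

    def test_too_many_constraints_rejected(self, primaries, daylight_bg):
        spec = sd.ContrastSpec({o: ("target", 0.1)
                                for o in ("L", "S", "rod", "mel")})
        with pytest.raises(ValueError, match="more constrained"):
            sd.solve_silent_substitution(primaries, daylight_bg, spec)

    def test_singular_system_rejected(self, daylight_bg):
        grid = sd.default_primaries()[0].spectrum.grid
        p = sd.gaussian_primary("a", 500.0, grid=grid)
        prims = [p, sd.gaussian_primary("b", 500.0, grid=grid),
                 sd.gaussian_primary("c", 620.0, grid=grid)]
        bg = sd.Background(np.ones(3), {}, 0)
        spec = sd.ContrastSpec({"L": ("target", 0.3), "S": ("target", 0.0),
                                "rod": ("target", 0.0)})
        with pytest.raises(ValueError, match="singular"):
            sd.solve_silent_substitution(prims, bg, spec)

    def test_infeasible_flagged_with_diagnostics(self, primaries, daylight_bg):
        spec = sd.ContrastSpec({"rod": ("target", 0.95),
                                "L": ("silenced", 0.0),
                                "S": ("silenced", 0.0)})
        sol = sd.solve_silent_substitution(primaries, daylight_bg, spec)
        assert not sol.feasible
        assert "infeasibility" in sol.diagnostics

    def test_solver_linearity(self, primaries, daylight_bg):
        small = sd.solve_silent_substitution(
            primaries, daylight_bg, sd.ContrastSpec.isolate("S", 0.2, ["L"]))
        big = sd.solve_silent_substitution(
            primaries, daylight_bg, sd.ContrastSpec.isolate("S", 0.4, ["L"]))
        np.testing.assert_allclose(big.delta_drives, 2 * small.delta_drives,
                                   rtol=1e-8, atol=1e-12)

    def test_json_serialization(self, battery):
        payload = json.loads(battery["L_Only"].to_json())
        assert payload["feasible"] is True
        assert payload["achieved"]["L"] == pytest.approx(0.75, abs=1e-6)


class TestValidation:
    def test_exact_solution_passes_bounds(self, battery, primaries,
                                          daylight_bg):
        report = sd.validate_solution(battery["L_Only"], primaries,
                                      daylight_bg,
                                      {"S": 0.002, "rod": 0.06, "mel": 0.06})
        assert report["all_pass"]

    def test_corrupted_modulation_fails(self, battery, primaries, daylight_bg):
        import copy
        bad = copy.deepcopy(battery["L_Only"])
        bad.delta_drives = bad.delta_drives.copy()
        # +10% modulation on the short-wavelength primary
        bad.delta_drives[0] += 0.10 * daylight_bg.drives[0]
        report = sd.validate_solution(bad, primaries, daylight_bg,
                                      {"S": 0.002})
        assert not report["all_pass"]

    def test_residual_matches_independent_recomputation(self, battery,
                                                        primaries,
                                                        daylight_bg):
        sol = battery["L_Only"]
        bright = daylight_bg.drives + sol.delta_drives
        dim = daylight_bg.drives - sol.delta_drives
        for opsin in ("rod", "mel", "S", "L"):
            c = recompute_contrast_from_drives(primaries, bright, dim, opsin)
            assert sol.achieved[opsin] == pytest.approx(c, abs=1e-9)


class TestSquareWave:
    def test_zero_contrast_constant(self, primaries, daylight_bg):
        spec = sd.ContrastSpec({"L": ("target", 0.0), "S": ("target", 0.0)})
        sol = sd.solve_silent_substitution(primaries, daylight_bg, spec)
        wf = sd.build_square_wave(sol, primaries, daylight_bg)
        assert np.ptp(wf.drives, axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_duration_and_cycles(self, battery, primaries, daylight_bg):
        wf = sd.build_square_wave(battery["L_Only"], primaries, daylight_bg,
                                  frequency=0.25, n_cycles=6)
        assert wf.duration == pytest.approx(24.0)

    def test_ramp_longer_than_half_period_rejected(self, battery, primaries,
                                                   daylight_bg):
        with pytest.raises(ValueError, match="ramp"):
            sd.build_square_wave(battery["L_Only"], primaries, daylight_bg,
                                 frequency=10.0, ramp_ms=60.0)

    def test_75pct_gives_sevenfold_flux_ratio(self, battery, daylight_bg):
        c = battery["L_Only"].achieved["L"]
        ratio = (1 + c) / (1 - c)
        assert ratio == pytest.approx(7.0, abs=1e-4)

    def test_contrast_trace_consistent_with_drives(self, battery, primaries,
                                                   daylight_bg):
        wf = sd.build_square_wave(battery["L_Only"], primaries, daylight_bg,
                                  n_cycles=1)
        # plateau samples (bright mid-phase, dim mid-phase)
        i_b = len(wf.times) // 4
        i_d = 3 * len(wf.times) // 4
        c = recompute_contrast_from_drives(primaries, wf.drives[i_b],
                                           wf.drives[i_d], "L")
        assert c == pytest.approx(battery["L_Only"].achieved["L"], abs=1e-9)

    def test_nd_scaling_preserves_contrast(self, battery, primaries,
                                           daylight_bg):
        wf2 = sd.build_square_wave(battery["L_Only"], primaries,
                                   daylight_bg.with_nd(2), n_cycles=1)
        i_b, i_d = len(wf2.times) // 4, 3 * len(wf2.times) // 4
        c = recompute_contrast_from_drives(primaries, wf2.drives[i_b],
                                           wf2.drives[i_d], "L")
        assert c == pytest.approx(0.75, abs=1e-9)
        assert wf2.drives.max() == pytest.approx(
            sd.build_square_wave(battery["L_Only"], primaries, daylight_bg,
                                 n_cycles=1).drives.max() / 100)

    def test_csv_export(self, battery, primaries, daylight_bg, tmp_path):
        wf = sd.build_square_wave(battery["L_Only"], primaries, daylight_bg,
                                  n_cycles=1)
        p = tmp_path / "wf.csv"
        wf.to_csv(p)
        header = p.read_text().splitlines()[0]
        assert header.startswith("time_s,drive_0")
        assert "contrast_mel" in header


class TestStepPair:
    def test_cone_fluxes_matched(self, primaries):
        high, low = sd.build_step_pair(primaries)
        c = sd.OPSINS
        for opsin in ("L", "S"):
            k = c.index(opsin)
            on = high.times >= 0
            assert high.contrasts[on, k] == pytest.approx(
                low.contrasts[on, k], abs=1e-9)

    def test_mel_and_rod_ratios_match_oracle(self, primaries):
        high, _ = sd.build_step_pair(primaries)
        assert high.meta["mel_ratio"] == pytest.approx(ORACLE_STEP_MEL_RATIO,
                                                       rel=1e-9)
        assert high.meta["rod_ratio"] == pytest.approx(ORACLE_STEP_ROD_RATIO,
                                                       rel=1e-9)

    def test_mel_ratio_order_of_magnitude(self, primaries):
        high, _ = sd.build_step_pair(primaries)
        assert 1e2 <= high.meta["mel_ratio"] <= 1e3


class TestWhiteNoise:
    def test_seed_reproducible(self, primaries, reduced_s_bg):
        a = sd.build_white_noise(primaries, reduced_s_bg, duration=30, seed=7)
        b = sd.build_white_noise(primaries, reduced_s_bg, duration=30, seed=7)
        np.testing.assert_array_equal(a.drives, b.drives)
        np.testing.assert_array_equal(a.contrasts, b.contrasts)

    def test_sequences_uncorrelated(self, primaries, reduced_s_bg):
        wf = sd.build_white_noise(primaries, reduced_s_bg, duration=600,
                                  seed=3)
        rod = wf.contrast("rod")
        L = wf.contrast("L")
        S = wf.contrast("S")
        n = len(rod)
        for a, b in ((rod, L), (rod, S), (L, S)):
            r = np.corrcoef(a, b)[0, 1]
            assert abs(r) < 3.5 / np.sqrt(n)

    def test_achieved_matches_requested(self, primaries, reduced_s_bg):
        wf = sd.build_white_noise(primaries, reduced_s_bg, duration=30, seed=1)
        req = wf.meta["requested"]       # (n, 3) rod, L, S
        ach = wf.contrasts[:, [sd.OPSINS.index("rod"), sd.OPSINS.index("L"),
                               sd.OPSINS.index("S")]]
        assert np.abs(req - ach).max() < 1e-6

    def test_frame_contrast_matches_integration_oracle(self, primaries,
                                                       reduced_s_bg):
        rc = recompute_contrast_from_drives
        wf = sd.build_white_noise(primaries, reduced_s_bg, duration=5, seed=2)
        bg = reduced_s_bg.drives
        for f in (0, 17, 42):
            for opsin in ("rod", "L", "S"):
                # frame contrast (F - F0)/F0 equals the Michelson contrast of
                # the symmetric excursion: bright = bg + delta, dim = bg - delta
                c = rc(primaries, wf.drives[f], 2 * bg - wf.drives[f], opsin)
                k = sd.OPSINS.index(opsin)
                assert wf.contrasts[f, k] == pytest.approx(c, abs=1e-9)

    def test_infeasible_frame_reported(self, primaries, daylight_bg):
        # the daylight background cannot support +-65% joint modulation
        with pytest.raises(ValueError, match="frame"):
            sd.build_white_noise(primaries, daylight_bg, duration=60, seed=0)

    def test_gamut_feasible_at_65pct(self, primaries, reduced_s_bg):
        wf = sd.build_white_noise(primaries, reduced_s_bg, duration=120,
                                  seed=11)
        assert wf.drives.min() >= 0


class TestBackground:
    def test_unknown_variant_rejected(self, primaries):
        with pytest.raises(ValueError, match="variant"):
            sd.make_background(primaries, "moonlight")

    def test_reduced_s_has_lower_s_flux(self, daylight_bg, reduced_s_bg):
        day = daylight_bg.fluxes["S"] / daylight_bg.fluxes["L"]
        red = reduced_s_bg.fluxes["S"] / reduced_s_bg.fluxes["L"]
        assert red < day

    def test_nd_scale(self, daylight_bg):
        assert daylight_bg.with_nd(3).nd_scale == pytest.approx(1e-3)
        with pytest.raises(ValueError):
            sd.Background(np.ones(3), {}, nd_level=7)
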