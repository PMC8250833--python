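"""Forward-simulator physics: diffusion oracle, conservation, fronts."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfc

from sandflux.errors import ConfigError
from sandflux.kinetics import hill_rate
from sandflux.penetration import penetration_depth, penetration_series
from sandflux.profiles import Analyte, KineticsFit
from sandflux.simulate import (ScenarioConfig, ScenarioKind,
                               make_fixture_suite,
                               percolation_config_from_flow, simulate,
                               total_nitrogen)
from sandflux.profiles import read_profile_table


class TestStability:
    def test_unstable_diffusion_step_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(dt_h=0.5)

    def test_excess_courant_rejected(self):
        with pytest.raises(ConfigError):
            percolation_config_from_flow(1.3, dt_h=0.02)

    def test_output_cadence_must_align(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(dt_h=0.01, output_every_h=0.305)


class TestDiffusionOracle:
    def test_step_matches_complementary_error_function(self):
        """Zero-reaction diffusion of a concentration step matches the
        half-space analytic solution within 1% of the step height."""
        dz = 0.0005
        cfg0 = ScenarioConfig(grid_dz_m=dz, reactions_on=False,
                              duration_h=0.5, output_every_h=0.25,
                              dt_h=0.005)
        z = cfg0.depths
        z0 = 0.02
        c0 = 20.0
        step = np.where(z > z0, c0, np.where(z == z0, c0 / 2, 0.0))
        cfg = ScenarioConfig(grid_dz_m=dz, reactions_on=False,
                             duration_h=0.5, output_every_h=0.25, dt_h=0.005,
                             nox_init_profile=step, noise_sd=0.0)
        res = simulate(cfg)
        d_eff = cfg.core.effective_diffusivity()
        for k, t in enumerate(res.truth.times):
            if t == 0:
                continue
            analytic = c0 / 2 * erfc((z0 - z) / (2 * np.sqrt(d_eff * t)))
            sim = res.truth.fields[Analyte.NOX][k]
            mask = analytic > 0.5
            assert np.max(np.abs(sim[mask] - analytic[mask])) < 0.01 * c0

    def test_refinement_convergence(self):
        """Halving dz and dt changes final snapshots by < 1%."""
        coarse = simulate(ScenarioConfig(duration_h=3.0, noise_sd=0.0))
        fine = simulate(ScenarioConfig(duration_h=3.0, noise_sd=0.0,
                                       grid_dz_m=0.0005, dt_h=0.0025))
        for a in (Analyte.NOX, Analyte.N2O):
            c_coarse = coarse.truth.fields[a][-1]
            c_fine = fine.truth.fields[a][-1][::2]
            scale = max(c_coarse.max(), 1e-9)
            assert np.max(np.abs(c_coarse - c_fine)) < 0.01 * scale


class TestConservation:
    def test_closed_domain_nitrogen_inventory(self):
        """NOx + 2*N2O + cumulative other-sink is constant over 10 h."""
        res = simulate(ScenarioConfig(duration_h=10.0, noise_sd=0.0))
        tn = total_nitrogen(res)
        drift = (tn.max() - tn.min()) / tn[0]
        assert drift < 0.005

    def test_n2o_ceiling_approach(self):
        """With a 9% non-denitrification sink the N2O maximum approaches
        ~91% of the stoichiometric ceiling."""
        res = simulate(ScenarioConfig(duration_h=10.0, noise_sd=0.0))
        n2o = res.truth.fields[Analyte.N2O]
        i = np.argmin(np.abs(res.truth.depths - 0.017))
        assert 2 * n2o[:, i].max() / 20.0 == pytest.approx(0.91, abs=0.02)


class TestPercolation:
    def test_plug_flow_front_displacement(self):
        """Without reactions the advected front sits at the plug-flow depth
        (~2.6 cm after 8 h at 0.11 mL/min)."""
        cfg = percolation_config_from_flow(0.11, nox_top=15.0,
                                           reactions_on=False, noise_sd=0.0)
        res = simulate(cfg)
        last = res.series[Analyte.NOX].profiles[-1]
        front = penetration_depth(last, 7.5, interpolate=True)  # half height
        assert front == pytest.approx(2.6, abs=0.15)

    def test_penetration_series_monotone_and_saturating(self):
        cfg = percolation_config_from_flow(0.11, nox_top=15.0, noise_sd=0.0)
        res = simulate(cfg)
        pen = penetration_series(res.series[Analyte.NOX], 1.0)
        assert np.all(np.diff(pen.depths_cm) >= -1e-9)
        # increments shrink as the front approaches its asymptote
        first_half = pen.depths_cm[4] - pen.depths_cm[0]
        second_half = pen.depths_cm[-1] - pen.depths_cm[-5]
        assert second_half < first_half

    def test_oxygen_shallower_than_nox(self):
        """O2 consumption outpaces denitrification, so the O2 front stays
        shallower than the NOx front, as observed in percolated cores."""
        cfg = percolation_config_from_flow(0.11, nox_top=15.0, noise_sd=0.0)
        res = simulate(cfg)
        last_o2 = res.series[Analyte.O2].profiles[-1]
        last_nox = res.series[Analyte.NOX].profiles[-1]
        o2_pen = penetration_depth(last_o2, 1.0, interpolate=True)
        nox_pen = penetration_depth(last_nox, 1.0, interpolate=True)
        assert o2_pen < nox_pen
        assert nox_pen - o2_pen == pytest.approx(1.1, abs=0.6)

    def test_front_width_matches_advective_theory(self):
        """At quasi-steady state the width of the reaction front is bounded
        below by the pure-advection quadrature v * int dC / R(C) and is
        stationary in time."""
        cfg = percolation_config_from_flow(
            0.11, nox_top=15.0, noise_sd=0.0, o2_top=0.0,
            denit_depth_ramp=(0.0, 0.0), duration_h=12.0)
        res = simulate(cfg)
        kin = KineticsFit(v_max=6.8, k_m=3.1, hill_n=2.4)
        pred_cm = cfg.velocity_m_h * quad(
            lambda c: 1.0 / hill_rate(c, kin), 1.0, 7.8)[0] * 100
        gaps = []
        for t in (10.0, 12.0):
            p = [pp for pp in res.series[Analyte.NOX].profiles
                 if abs(pp.time_h - t) < 1e-9][0]
            gap = (penetration_depth(p, 1.0, interpolate=True)
                   - penetration_depth(p, 7.8, interpolate=True))
            gaps.append(gap)
        assert gaps[0] == pytest.approx(gaps[1], abs=0.05)  # stationary
        assert pred_cm <= gaps[-1] <= 1.6 * pred_cm  # diffusion broadens

    def test_anoxic_oxic_rate_contrast(self):
        """The oxygen-inhibition half-constant yields the observed ~6-7x
        anoxic/oxic contrast at air-saturated porewater."""
        cfg = ScenarioConfig()
        contrast = (cfg.o2_inhibition_k + 250.0) / cfg.o2_inhibition_k
        assert 6.0 <= contrast <= 7.5


class TestFixtureSuite:
    def test_deterministic_and_parseable(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = make_fixture_suite(d1, seed=5)
        m2 = make_fixture_suite(d2, seed=5)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        for name in names:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        assert m1 == m2
        # every listed file parses cleanly with matching analyte
        for entry in m1.values():
            for analyte, fname in entry["files"].items():
                series = read_profile_table(d1 / fname, analyte)
                assert len(series) >= 3

    def test_manifest_covers_all_files(self, tmp_path):
        manifest = make_fixture_suite(tmp_path / "fix", seed=1)
        listed = {f for entry in manifest.values()
                  for f in entry["files"].values()}
        on_disk = {p.name for p in (tmp_path / "fix").iterdir()
                   if p.suffix == ".csv"}
        assert listed == on_disk
        for entry in manifest.values():
            assert "v_max" in entry["ground_truth"]
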