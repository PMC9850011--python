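"""PLD model, RK4 advection, settlement, kernels, transition matrices."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ventconn.dispersal import (
    FATE_DIED,
    FATE_LEFT,
    FATE_SETTLED,
    PLDParams,
    VentRegistry,
    advect,
    build_synthetic_field,
    kernel,
    pld_from_temperature,
    settle,
    temperature_profile,
    transition_matrix,
)


class TestPLD:
    def test_reference_temperature_gives_exp_beta0(self):
        p = PLDParams()
        assert pld_from_temperature(p.T_ref, p) == pytest.approx(math.exp(p.beta0))

    def test_cold_water_slows_development(self):
        assert pld_from_temperature(2.0) > pld_from_temperature(25.0)

    def test_calibration_brackets_study_range(self):
        # ~19 d at tropical surface temperature, ~283 d in ~1.8 C deep water
        assert pld_from_temperature(28.0) == pytest.approx(18.93, abs=0.05)
        assert pld_from_temperature(1.8) == pytest.approx(282.68, rel=0.01)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            pld_from_temperature(0.0)
        with pytest.raises(ValueError):
            pld_from_temperature(-3.0)

    def test_profile_monotone_decreasing(self):
        depths = np.array([0, 100, 500, 1000, 1500, 2000, 2500, 3000])
        temps = temperature_profile(depths)
        assert np.all(np.diff(temps) < 0)


def jet_scenario(u=0.1, v=0.0, x_km=600.0, y_km=300.0, T=10.0, depth=1000.0):
    return build_synthetic_field(
        {"x_km": x_km, "y_km": y_km, "dx_km": 10.0},
        [{"type": "uniform_jet", "u": u, "v": v}],
        dispersal_depth_m=depth,
        temperature=T,
    )


class TestAdvection:
    def test_uniform_flow_closed_form(self):
        # u = 0.1 m/s for exactly one day -> 8.64 km east
        sc = jet_scenario(u=0.1)
        ens = advect(sc, 50.0, 150.0, 10, dt_seconds=3600.0, seed=0, max_steps=24)
        assert np.allclose(ens.end_x - 50.0, 8.64, atol=1e-6)
        assert np.allclose(ens.end_y, 150.0, atol=1e-12)

    def test_zero_field_zero_displacement(self):
        sc = jet_scenario(u=0.0)
        ens = advect(sc, 100.0, 100.0, 5, dt_seconds=3600.0, seed=0, max_steps=48)
        assert np.allclose(ens.end_x, 100.0)
        assert np.allclose(ens.end_y, 100.0)

    def _orbit_error(self, dt_seconds):
        # solid-body rotation: bilinear interpolation is exact for a linear
        # field, so the orbit-closure error is pure RK4 truncation
        omega = 2 * np.pi / (5 * 86400.0)  # 5-day period
        sc = build_synthetic_field(
            {"x_km": 400.0, "y_km": 400.0, "dx_km": 10.0},
            [{"type": "solid_body_gyre", "center": (200.0, 200.0), "omega": omega}],
            temperature=5.0,
        )
        steps = int(round(5 * 86400.0 / dt_seconds))
        ens = advect(
            sc, 250.0, 200.0, 1, dt_seconds=dt_seconds, seed=0, max_steps=steps
        )
        return float(np.hypot(ens.end_x[0] - 250.0, ens.end_y[0] - 200.0))

    def test_orbit_closure_small_at_hourly_step(self):
        # radius 50 km; closure error far below 1e-3 of the radius
        assert self._orbit_error(3600.0) < 0.05

    def test_rk4_fourth_order_convergence(self):
        e1 = self._orbit_error(7200.0)
        e2 = self._orbit_error(3600.0)
        assert 10.0 < e1 / e2 < 25.0  # ~16x per dt halving

    def test_development_fraction_accumulation_constant_t(self):
        sc = jet_scenario(u=0.01, T=10.0)
        pld = pld_from_temperature(10.0)
        ens = advect(sc, 50.0, 150.0, 3, dt_seconds=3600.0, seed=0,
                     max_steps=48, store_every=1)
        k = len(ens.times_days) - 1
        expected = k * (3600.0 / 86400.0) / pld
        assert np.allclose(ens.frac[-1], expected, atol=1e-9)

    def test_cfl_violation_warns(self):
        sc = jet_scenario(u=1.0)  # 1 m/s, 10 km grid
        with pytest.warns(UserWarning, match="CFL"):
            advect(sc, 50.0, 150.0, 2, dt_seconds=7200.0, seed=0, max_steps=2)

    def test_release_inside_mask_rejected(self):
        sc = build_synthetic_field(
            {"x_km": 200.0, "y_km": 200.0, "dx_km": 10.0},
            [
                {"type": "uniform_jet", "u": 0.05},
                {"type": "topographic_block", "x_range": (80, 120), "y_range": (80, 120)},
            ],
            temperature=5.0,
        )
        with pytest.raises(ValueError, match="mask"):
            advect(sc, 100.0, 100.0, 2, dt_seconds=3600.0, seed=0, max_steps=2)

    def test_eddy_field_deterministic(self):
        spec = {"x_km": 300.0, "y_km": 300.0, "dx_km": 10.0}
        comps = [{"type": "eddy_field", "amplitude": 0.05, "n_modes": 4}]
        s1 = build_synthetic_field(spec, comps, seed=3)
        s2 = build_synthetic_field(spec, comps, seed=3)
        s3 = build_synthetic_field(spec, comps, seed=4)
        assert np.array_equal(s1.u, s2.u)
        assert not np.array_equal(s1.u, s3.u)


class TestSettlement:
    def _registry(self, rows):
        return VentRegistry(pd.DataFrame(rows))

    def test_site_at_release_settles_at_t0(self):
        sc = jet_scenario(u=0.05)
        reg = self._registry(
            [{"id": "src", "x_km": 50.0, "y_km": 150.0, "depth_m": 2000.0}]
        )
        ens = advect(sc, 50.0, 150.0, 50, dt_seconds=3600.0, seed=1, max_steps=24)
        ens = settle(ens, reg, sc, radius_km=5.0)
        assert np.all(ens.fate == FATE_SETTLED)
        assert np.all(ens.settled_site == "src")
        assert np.allclose(ens.settle_time_days, 0.0)

    def test_site_shallower_than_dispersal_depth_never_settles(self):
        sc = jet_scenario(u=0.05, depth=1500.0)
        reg = self._registry(
            [{"id": "shallow", "x_km": 50.0, "y_km": 150.0, "depth_m": 1000.0}]
        )
        ens = advect(sc, 50.0, 150.0, 50, dt_seconds=3600.0, seed=1, max_steps=24)
        ens = settle(ens, reg, sc, radius_km=5.0)
        assert not np.any(ens.fate == FATE_SETTLED)

    def test_eligibility_flips_with_depth_only(self):
        # same site, dispersal depth above vs below its depth
        reg = self._registry(
            [{"id": "s", "x_km": 100.0, "y_km": 150.0, "depth_m": 1500.0}]
        )
        for depth, expect in ((1000.0, True), (2000.0, False)):
            sc = jet_scenario(u=0.05, depth=depth)
            ens = advect(sc, 100.0, 150.0, 20, dt_seconds=3600.0, seed=2, max_steps=12)
            ens = settle(ens, reg, sc, radius_km=5.0)
            assert bool(np.any(ens.fate == FATE_SETTLED)) is expect

    def test_jet_line_crossing_matches_analytic_fraction(self):
        """Single eligible downstream site on the jet line: with Gaussian
        release jitter the settlement fraction equals the chance that the
        cross-stream offset is within the radius."""
        jitter, radius = 4.0, 5.0
        sc = jet_scenario(u=0.1, T=3.0)  # slow development: all reach the site
        reg = self._registry(
            [{"id": "down", "x_km": 150.0, "y_km": 150.0, "depth_m": 2000.0}]
        )
        n = 4000
        ens = advect(sc, 50.0, 150.0, n, dt_seconds=3600.0, seed=3,
                     jitter_km=jitter, store_every=1, max_steps=16 * 24)
        ens = settle(ens, reg, sc, radius_km=radius)
        frac = float(np.mean(ens.fate == FATE_SETTLED))
        # |N(0, jitter^2)| < radius; x-jitter only shifts arrival time
        expected = 2 * stats.norm.cdf(radius / jitter) - 1
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 4 * se

    def test_settlement_nonincreasing_with_distance(self):
        sc = jet_scenario(u=0.1, T=8.0)
        fracs = []
        for x_site in (120.0, 220.0, 320.0):
            reg = self._registry(
                [{"id": "s", "x_km": x_site, "y_km": 150.0, "depth_m": 2000.0}]
            )
            ens = advect(sc, 50.0, 150.0, 800, dt_seconds=3600.0, seed=4,
                         jitter_km=6.0, store_every=1)
            ens = settle(ens, reg, sc, radius_km=5.0)
            fracs.append(float(np.mean(ens.fate == FATE_SETTLED)))
        assert fracs[0] >= fracs[1] >= fracs[2]


class TestKernel:
    def test_point_mass_density(self):
        sc = jet_scenario(u=0.0)
        ens = advect(sc, 100.0, 100.0, 50, dt_seconds=3600.0, seed=0, max_steps=4)
        k = kernel(ens, cell_km=10.0)
        assert k.integral() == pytest.approx(1.0, abs=1e-9)
        assert k.density.max() == pytest.approx(1.0 / 100.0)  # all mass in one cell

    def test_conservation_with_loss(self):
        sc = jet_scenario(u=0.2, x_km=300.0, T=2.0)  # many exit east
        ens = advect(sc, 250.0, 150.0, 500, dt_seconds=3600.0, seed=5, jitter_km=5.0)
        k = kernel(ens, cell_km=10.0)
        assert k.integral() + k.lost_fraction == pytest.approx(1.0, abs=1e-9)
        assert k.lost_fraction > 0

    def test_jet_kernel_centered_at_analytic_displacement(self):
        T = 10.0
        sc = jet_scenario(u=0.1, x_km=2000.0, T=T)
        pld_days = pld_from_temperature(T)
        ens = advect(sc, 100.0, 150.0, 400, dt_seconds=3600.0, seed=6)
        assert np.all(ens.fate == FATE_DIED)
        k = kernel(ens, cell_km=10.0)
        xc = 0.5 * (k.x_edges[:-1] + k.x_edges[1:])
        mean_x = float(np.sum(k.density.sum(axis=0) * xc) / np.sum(k.density.sum(axis=0)))
        expected = 100.0 + 0.1 * 86.4 * pld_days  # km
        assert abs(mean_x - expected) < 10.0  # within one cell


class TestTransitionMatrix:
    def _two_site_jet(self, u):
        sc = jet_scenario(u=u, T=6.0)
        reg = VentRegistry(
            pd.DataFrame(
                [
                    {"id": "west", "x_km": 100.0, "y_km": 150.0, "depth_m": 2000.0},
                    {"id": "east", "x_km": 300.0, "y_km": 150.0, "depth_m": 2000.0},
                ]
            )
        )
        ensembles = {}
        for sid in reg.ids:
            s = reg.site(sid)
            ens = advect(sc, float(s.x_km), float(s.y_km), 300,
                         dt_seconds=3600.0, seed=hash(sid) % 1000, jitter_km=3.0,
                         store_every=1)
            ensembles[sid] = settle(ens, reg, sc, radius_km=6.0,
                                    min_competency=0.02)
        return transition_matrix(ensembles, reg), reg

    def test_westward_jet_asymmetric(self):
        tm, _ = self._two_site_jet(u=-0.1)  # westward flow
        P = tm.to_frame()
        assert P.loc["east", "west"] > 0.1
        assert P.loc["east", "west"] > 10 * P.loc["west", "east"]

    def test_no_settlement_zero_matrix(self):
        sc = jet_scenario(u=0.05, T=25.0, depth=3000.0)
        reg = VentRegistry(
            pd.DataFrame([{"id": "s", "x_km": 400.0, "y_km": 280.0, "depth_m": 1000.0}])
        )
        ens = advect(sc, 50.0, 150.0, 50, dt_seconds=3600.0, seed=0, max_steps=48)
        ens = settle(ens, reg, sc)
        tm = transition_matrix({"s": ens}, reg)
        assert np.all(tm.P == 0)

    def test_all_settle_at_source_identity(self):
        sc = jet_scenario(u=0.0)
        reg = VentRegistry(
            pd.DataFrame(
                [
                    {"id": "a", "x_km": 100.0, "y_km": 100.0, "depth_m": 2000.0},
                    {"id": "b", "x_km": 400.0, "y_km": 200.0, "depth_m": 2000.0},
                ]
            )
        )
        ensembles = {}
        for sid in reg.ids:
            s = reg.site(sid)
            ens = advect(sc, float(s.x_km), float(s.y_km), 40,
                         dt_seconds=3600.0, seed=1, max_steps=24)
            ensembles[sid] = settle(ens, reg, sc, radius_km=5.0)
        tm = transition_matrix(ensembles, reg)
        assert np.allclose(tm.P, np.eye(2))

    def test_missing_source_restricts_with_warning(self):
        sc = jet_scenario(u=0.0)
        reg = VentRegistry(
            pd.DataFrame(
                [
                    {"id": "a", "x_km": 100.0, "y_km": 100.0, "depth_m": 2000.0},
                    {"id": "b", "x_km": 400.0, "y_km": 200.0, "depth_m": 2000.0},
                ]
            )
        )
        ens = advect(sc, 100.0, 100.0, 20, dt_seconds=3600.0, seed=1, max_steps=12)
        ens = settle(ens, reg, sc)
        with pytest.warns(UserWarning, match="restricted"):
            tm = transition_matrix({"a": ens}, reg)
        assert tm.sites == ["a"]
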