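"""Langevin integrator, forces, boundaries and chain observables."""

import numpy as np
import pytest
from scipy.optimize import brentq

import traphop as tp
from traphop.geometry import build_hex_array, nearest_post_distance
from traphop.simulation import (ChainState, IntegrationError, SimConfig,
                                bonded_forces, post_forces, post_potential,
                                projected_rg, run, step, total_energy)


def two_bead_state(r, axis=0):
    pos = np.zeros((2, 3))
    pos[1, axis] = r
    return ChainState(pos, np.zeros((2, 3)))


def bond_force_magnitude(r, config):
    f = bonded_forces(two_bead_state(r), config)
    return float(np.linalg.norm(f[0]))


def bond_dudr(r, config):
    """Signed radial derivative of the bonded potential (oracle via forces)."""
    f = bonded_forces(two_bead_state(r), config)
    return -f[0, 0]  # force on bead 0 along +x toward bead 1


class TestBondedForces:
    def test_equilibrium_bond_length_near_097(self):
        # root of dU/dr located independently by bisection
        cfg = SimConfig(n_beads=2)
        r_star = brentq(lambda r: bond_dudr(r, cfg), 0.8, 1.122)
        assert r_star == pytest.approx(0.97, abs=0.02)
        assert bond_force_magnitude(r_star, cfg) < 1e-9

    def test_fene_divergence_near_max_extension(self):
        cfg = SimConfig(n_beads=2)
        assert bond_force_magnitude(1.499, cfg) > 1e3

    def test_newtons_third_law_exact(self, rng):
        cfg = SimConfig(n_beads=5)
        bonds = rng.uniform(-0.5, 0.5, (5, 3))
        bonds *= (0.9 / np.linalg.norm(bonds, axis=1))[:, None]
        pos = np.cumsum(bonds, axis=0)
        f = bonded_forces(ChainState(pos, np.zeros((5, 3))), cfg)
        assert np.allclose(f.sum(axis=0), 0.0,
                           atol=1e-12 * max(1.0, np.abs(f).max()))

    def test_overstretched_bond_names_the_bond(self):
        cfg = SimConfig(n_beads=2)
        with pytest.raises(IntegrationError, match="bond 0-1"):
            bonded_forces(two_bead_state(1.6), cfg)

    def test_printed_fene_form_differs_but_binds(self):
        kg = SimConfig(n_beads=2)
        lit = SimConfig(n_beads=2, printed_fene=True)
        assert bond_dudr(1.2, kg) != pytest.approx(bond_dudr(1.2, lit))
        r_star = brentq(lambda r: bond_dudr(r, lit), 0.7, 1.122)
        assert 0.7 < r_star < 1.122


class TestPostForces:
    def geo_state(self, surface_sep):
        geo = build_hex_array(16.0, 7.0, 3.0)
        pos = np.zeros((1, 3))
        pos[0, 0] = 16.0 + surface_sep
        pos[0, 2] = 1.5
        return geo, ChainState(pos, np.zeros((1, 3)))

    def test_minimum_at_wca_distance_with_depth_epsilon(self):
        geo, state = self.geo_state(2.0 ** (1 / 6))
        cfg = SimConfig(n_beads=1, geometry=geo, epsilon=0.8, r_cutoff=2.5)
        f = post_forces(state, cfg)
        assert np.allclose(f, 0.0, atol=1e-9)
        # unshifted well depth is epsilon*kT: U(min) minus the cutoff shift
        u_min = post_potential(np.array([2.0 ** (1 / 6)]), cfg)[0]
        src6 = (1.0 / 2.5) ** 6
        shift = 4 * 0.8 * (src6**2 - src6)
        assert u_min + 0.8 == pytest.approx(-shift, abs=1e-9)

    def test_zero_beyond_cutoff(self):
        geo, state = self.geo_state(3.0)
        cfg = SimConfig(n_beads=1, geometry=geo, epsilon=1.0, r_cutoff=2.5)
        assert np.allclose(post_forces(state, cfg), 0.0)
        assert post_potential(np.array([3.0]), cfg)[0] == 0.0

    def test_repulsive_mode_energy_nonnegative(self):
        geo = build_hex_array(16.0, 7.0, 3.0)
        cfg = SimConfig(n_beads=1, geometry=geo, epsilon=1.0, r_cutoff=1.12)
        s = np.linspace(0.8, 1.1199, 2000)
        assert post_potential(s, cfg).min() >= -1e-3

    def test_bead_inside_post_is_overlap_error(self):
        geo, state = self.geo_state(-0.5)
        cfg = SimConfig(n_beads=1, geometry=geo)
        with pytest.raises(IntegrationError, match="inside a post"):
            post_forces(state, cfg)


class TestStep:
    def test_free_flight_is_exact(self, rng):
        cfg = SimConfig(n_beads=1, gamma=0.0, random_forces=False, dt=0.01)
        state = ChainState(np.zeros((1, 3)), np.array([[1.0, -2.0, 0.5]]))
        new = step(state, cfg, rng)
        assert np.allclose(new.positions, state.velocities * 0.01, atol=1e-15)
        assert np.allclose(new.velocities, state.velocities)

    def test_wall_reflection_contract(self, rng):
        geo = build_hex_array(16.0, 7.0, 3.0)
        pos = np.array([[9.75, 16.88, 2.95]])  # mid-gap, clear of posts
        vel = np.array([[0.0, 0.0, 50.0]])  # will cross z = H this step
        cfg = SimConfig(n_beads=1, geometry=geo, random_forces=False,
                        gamma=0.0, epsilon=0.0)
        new = step(ChainState(pos, vel), cfg, rng)
        assert 0.0 <= new.positions[0, 2] <= 3.0
        assert new.velocities[0, 2] < 0

    def test_energy_conservation_without_thermostat(self, rng):
        # velocity-Verlet order check: gamma = 0, no random force
        cfg = SimConfig(n_beads=8, gamma=0.0, random_forces=False, dt=0.01)
        pos = np.zeros((8, 3))
        pos[:, 0] = np.arange(8) * 0.97
        vel = rng.standard_normal((8, 3)) * 0.5
        state = ChainState(pos, vel)
        e0 = total_energy(state, cfg)
        for _ in range(10_000):
            state = step(state, cfg, rng)
        e1 = total_energy(state, cfg)
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_single_bead_einstein_relation(self):
        # D = k_B T/(m gamma) = 1 sigma^2/t_D at default parameters; the MSD
        # window starts well past the velocity relaxation time 1/gamma
        cfg = SimConfig(n_beads=1, n_steps_total=10_000_000, sample_every=200,
                        seed=21)
        trace = run(cfg)
        curve = tp.msd(trace.com_track, max_lag=1000)
        fit = tp.fit_diffusivity(curve, (300, 800))
        assert fit.D == pytest.approx(1.0, rel=0.05)


class TestRun:
    def test_single_bead_com_equals_bead_track(self):
        cfg = SimConfig(n_beads=1, n_steps_total=2000, sample_every=100,
                        seed=3, snapshot_every=100)
        trace = run(cfg)
        assert np.allclose(trace.com_samples, trace.snapshots[:, 0, :2])

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_beads=10, n_steps_total=2000, sample_every=200,
                        seed=5)
        a, b = run(cfg), run(cfg)
        assert np.array_equal(a.com_samples, b.com_samples)

    def test_com_diffusivity_scales_as_one_over_n(self):
        # free-chain COM diffuses at D_0/N (internal forces cancel)
        cfg = SimConfig(n_beads=16, n_steps_total=2_000_000, sample_every=100,
                        seed=9)
        trace = run(cfg)
        curve = tp.msd(trace.com_track, max_lag=1500)
        fit = tp.fit_diffusivity(curve, (300, 1200))
        assert fit.D == pytest.approx(1.0 / 16, rel=0.2)

    def test_confined_run_respects_walls_and_bonds(self, small_geometry):
        cfg = SimConfig(geometry=small_geometry, epsilon=0.6, seed=2,
                        n_steps_total=50_000, sample_every=500)
        trace = run(cfg)
        assert trace.zmin_samples.min() >= 0.0
        assert trace.zmax_samples.max() <= small_geometry.slit_height_H
        assert trace.maxbond_samples.max() < cfg.r_o

    def test_attractive_posts_trap_the_chain(self, small_geometry):
        # with eps = 1 the chain should spend most time near post surfaces
        cfg = SimConfig(geometry=small_geometry, epsilon=1.0, seed=4,
                        n_steps_total=400_000, n_steps_equil=50_000,
                        sample_every=100, kick="uniform")
        trace = run(cfg)
        dr = nearest_post_distance(trace.com_samples, small_geometry)
        dr = dr - small_geometry.post_radius_R
        assert np.median(dr) < 0.5 * small_geometry.gap_d


class TestTransportTrends:
    """Gap-size dependence of long-term transport (scaled-down runs at
    eps = 1.0, where the chain adsorbs robustly; see docs/methods.md)."""

    def _trace(self, d, r_cutoff, n_steps):
        geo = build_hex_array(16.0, d, 3.0)
        cfg = SimConfig(geometry=geo, epsilon=1.0, r_cutoff=r_cutoff,
                        seed=31, n_steps_total=n_steps,
                        n_steps_equil=100_000, sample_every=400,
                        kick="uniform")
        return run(cfg)

    def _d_long(self, trace):
        hi = trace.times[-1] / 3
        curve = tp.msd(trace.com_track, max_lag=hi)
        return tp.fit_diffusivity(curve, (hi / 8, hi)).D

    def test_diffusivity_ordering_and_trapping_plateau(self):
        att_18 = self._trace(7.0, 2.5, 8_000_000)
        att_44 = self._trace(17.0, 2.5, 8_000_000)
        rep_18 = self._trace(7.0, 1.12, 2_000_000)
        rep_44 = self._trace(17.0, 1.12, 2_000_000)

        # attractive posts: more crowding -> faster long-term transport
        assert self._d_long(att_18) > 2 * self._d_long(att_44)
        # repulsive posts: the ordering reverses (narrow gaps cage the chain)
        assert self._d_long(rep_44) > 5 * self._d_long(rep_18) + 1e-9

        # trapped large-gap chain: intermediate-time MSD falls well below its
        # short-time linear extrapolation (the trapping plateau); the
        # small-gap chain stays close to linear
        def plateau_ratio(trace):
            curve = tp.msd(trace.com_track, max_lag=110_000)
            short = tp.fit_diffusivity(curve, (2_000, 10_000))
            extrap = 4 * short.D * 100_000 + short.intercept
            at = curve.msd[np.argmin(np.abs(curve.lags - 100_000))]
            return curve, at / extrap

        curve_44, ratio_44 = plateau_ratio(att_44)
        _, ratio_18 = plateau_ratio(att_18)
        assert ratio_44 < 0.55
        assert ratio_18 > 0.70
        # trapping makes the intermediate-time MSD subdiffusive
        alpha = tp.powerlaw_exponent(curve_44, (10_000, 100_000))
        assert 0.4 <= alpha <= 0.8

    def test_repulsive_posts_deplete_perimeter_attractive_enhance(self):
        # COM density in the near-perimeter shell (surface to +2 sigma; the
        # COM of an Rg = 3.9 sigma chain cannot approach closer) vs uniform
        geo = build_hex_array(16.0, 14.0, 3.0)
        fracs = {}
        for label, r_cutoff in (("attractive", 2.5), ("repulsive", 1.12)):
            cfg = SimConfig(geometry=geo, epsilon=1.0, r_cutoff=r_cutoff,
                            seed=7, n_steps_total=800_000,
                            n_steps_equil=100_000, sample_every=50,
                            kick="uniform")
            trace = run(cfg)
            dr = nearest_post_distance(trace.com_samples, geo)
            fracs[label] = float((dr < geo.post_radius_R + 2.0).mean())
        cell = geo.cell_dimensions
        R = geo.post_radius_R
        uniform = 2 * np.pi * ((R + 2.0) ** 2 - R**2) / (cell[0] * cell[1])
        assert fracs["repulsive"] < 0.5 * uniform
        assert fracs["attractive"] > 1.5 * uniform


class TestProjectedRg:
    def test_single_bead_is_zero(self):
        assert projected_rg(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_unwraps_through_periodic_boundary(self):
        box = np.array([10.0, 10.0])
        xy = np.array([[9.5, 0.0, 0.0], [0.5, 0.0, 0.0]])  # 1 sigma apart
        assert projected_rg(xy, box=box) == pytest.approx(0.5)

    def test_ideal_chain_scaling_sqrt_n(self):
        # Rg(160)/Rg(40) ~ 2 for an ideal chain
        rgs = {}
        for n in (40, 160):
            cfg = SimConfig(n_beads=n, n_steps_total=600_000,
                            n_steps_equil=200_000, sample_every=500, seed=13,
                            kick="uniform")
            rgs[n] = run(cfg).rg_samples.mean()
        assert rgs[160] / rgs[40] == pytest.approx(2.0, rel=0.15)
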