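import numpy as np
import pytest

from minwaves import models, stability
from minwaves._bulkgrid import BulkGrid
from minwaves.sphere_sim import SphereSimulator, run_sphere


@pytest.fixture(scope="module")
def wave_params():
    return models.canonical_parameters(ce0=0.0)


class TestBulkColumn:
    def test_uniform_field_unchanged_by_diffusion(self):
        grid = BulkGrid("sphere", 5.0, 32)
        L = grid.laplacian(100.0, mode_l=0)
        np.testing.assert_allclose(L @ np.ones(grid.n), 0.0, atol=1e-9)

    def test_point_release_conserves_mass(self):
        grid = BulkGrid("sphere", 5.0, 40)
        c = np.zeros(grid.n)
        c[5] = 1.0 / grid.volumes[5]
        mass0 = (c * grid.volumes).sum()
        lu, bplus = grid.crank_nicolson_factors(100.0, 0.05, mode_l=0)
        from scipy.linalg import lu_solve
        # Crank-Nicolson only marginally damps the stiffest content of the
        # initial delta; give it time to relax
        for _ in range(2000):
            c = lu_solve(lu, bplus @ c)
        assert (c * grid.volumes).sum() == pytest.approx(mass0, rel=1e-10)
        np.testing.assert_allclose(c, 1.0 / grid.total_volume, atol=1e-4)

    @pytest.mark.parametrize("kind,size", [("sphere", 5.0), ("slab", 8.0)])
    def test_steady_profile_matches_closed_form(self, kind, size):
        """Diffusion + decay with constant boundary influx relaxes onto the
        analytic modified-spherical-Bessel (or cosh) profile."""
        D, lam, flux = 100.0, 1.0, 0.3
        grid = BulkGrid(kind, size, 96, beta=1.0)
        target = grid.stationary_profile(flux, D, lam)
        c = np.zeros(grid.n)
        lu, bplus = grid.crank_nicolson_factors(
            D, 0.01, mode_l=0 if kind == "sphere" else None)
        from scipy.linalg import lu_solve
        dt = 0.01
        for _ in range(4000):
            dc = np.zeros_like(c)
            grid.deposit(dc, flux)
            c = (c + dt * dc - 0.5 * dt * lam * c) / (1 + 0.5 * dt * lam)
            c = lu_solve(lu, bplus @ c)
        # cell-centred FV values vs the pointwise closed form: O(h^2);
        # the membrane cell carries the local flux deposit, skip it
        np.testing.assert_allclose(c[:-1], target[:-1], rtol=2e-2)


class TestConservation:
    def test_totals_conserved(self, wave_params):
        traj = run_sphere(wave_params, 5.0, t_max=2.0, dt=2e-3, lmax=8,
                          n_r=32, sample_every=100)
        drift = np.abs(traj.totals - traj.totals[0]).max()
        assert drift < 1e-6 * traj.t[-1]

    def test_totals_conserved_model_I(self):
        p = models.canonical_parameters(model_variant="I", ce0=0.01)
        traj = run_sphere(p, 5.0, t_max=2.0, dt=2e-3, lmax=8, n_r=32,
                          sample_every=100)
        assert np.abs(traj.totals - traj.totals[0]).max() < 1e-6

    def test_noise_preserves_totals(self, wave_params):
        traj = run_sphere(wave_params, 5.0, t_max=1.0, dt=2e-3, lmax=8,
                          n_r=32, noise_amp=1e-3, seed=7, sample_every=100)
        assert np.abs(traj.totals - traj.totals[0]).max() < 1e-6


class TestDeterminism:
    def test_bit_reproducible_with_seed(self, wave_params):
        kw = dict(t_max=0.5, dt=2e-3, lmax=8, n_r=32, noise_amp=1e-3, seed=42,
                  sample_every=50)
        a = run_sphere(wave_params, 5.0, **kw)
        b = run_sphere(wave_params, 5.0, **kw)
        assert np.array_equal(a.mem_coeffs, b.mem_coeffs)


class TestEquivariance:
    def test_z_rotation_leaves_mode_norms_invariant(self, wave_params):
        """Rotating the initial condition about z rotates the solution;
        rotationally invariant norms are unchanged."""
        def run(phase_shift):
            sim = SphereSimulator(wave_params, 5.0, lmax=8, n_r=32)
            sim.init_from_stationary(rel_amp=1e-3, perturb_m=None)
            m = np.arange(sim.lmax + 1)
            sim.mem *= np.exp(1j * m * phase_shift)[None, None, :]
            sim.bulk *= np.exp(1j * m * phase_shift)[None, None, None, :]
            return sim.run(t_max=1.0, dt=2e-3, sample_every=100)

        a, b = run(0.0), run(1.1)
        na = a.sht().mode_norms(a.mem_coeffs[:, 0])
        nb = b.sht().mode_norms(b.mem_coeffs[:, 0])
        np.testing.assert_allclose(na, nb, rtol=1e-8, atol=1e-12)


class TestLinearRegime:
    def test_growth_rate_matches_stability(self, wave_params, sphere5):
        """Early-time growth of a small l=1 perturbation matches Re sigma from
        the stability module within 5%."""
        traj = run_sphere(wave_params, 5.0, t_max=7.0, dt=2e-3, lmax=8,
                          n_r=64, rel_amp=1e-6, perturb_m=0, sample_every=50)
        norms = traj.mode_norms(0)
        t, n1 = traj.t, norms[:, 1]
        sel = (t > 3.0) & (t < 6.5)  # after subdominant modes have died out
        slope = np.polyfit(t[sel], np.log(n1[sel]), 1)[0]
        sigma = stability.max_growth_rate(wave_params, sphere5, 1)
        assert slope == pytest.approx(sigma.real, rel=0.05)

    def test_decay_above_critical_ce0(self, sphere5):
        """Above the critical spontaneous-binding level the l=1 amplitude
        decays."""
        p = models.canonical_parameters(ce0=0.06)
        traj = run_sphere(p, 5.0, t_max=8.0, dt=2e-3, lmax=8, n_r=48,
                          rel_amp=1e-4, sample_every=100)
        n1 = traj.mode_norms(0)[:, 1]
        assert n1[-1] < 0.1 * n1[0]

    def test_no_mine_relaxes_to_saturated_uniform(self):
        """eps0 = 0 with the saturation term: membrane MinD -> 1, uniform."""
        p = models.canonical_parameters(eps0=0.0, ce0=0.0, D0=1.0,
                                        saturation=True)
        sim = SphereSimulator(p, 5.0, lmax=8, n_r=32)
        sim.mem[0] = sim.sht.uniform(0.3)
        sim.mem[0, 1, 0] = 0.05
        sim.bulk[0, :, 0, 0] = sim.sht.uniform(
            p.D0 - sim.geometry.alpha * 0.3)[0, 0]
        traj = sim.run(t_max=30.0, dt=2e-3, sample_every=500)
        norms = traj.mode_norms(0)
        cd_mean = traj.mem_coeffs[-1, 0, 0, 0].real / np.sqrt(4 * np.pi)
        assert cd_mean == pytest.approx(1.0, abs=1e-3)
        assert norms[-1, 1:].max() < 1e-6


class TestResolutionRobustness:
    def test_lmax_16_vs_24_short_horizon(self, wave_params):
        """Results are unchanged when raising the truncation."""
        kw = dict(t_max=1.0, dt=2e-3, n_r=32, rel_amp=1e-3, perturb_m=0,
                  sample_every=100)
        a = run_sphere(wave_params, 5.0, lmax=16, **kw)
        b = run_sphere(wave_params, 5.0, lmax=24, **kw)
        na = a.mode_norms(0)[-1, :5]
        nb = b.mode_norms(0)[-1, :5]
        np.testing.assert_allclose(na, nb, rtol=1e-6, atol=1e-12)


class TestCrossValidation:
    def test_homogeneous_dynamics_match_ode_oracle(self, sphere5):
        """The spectral simulator restricted to the uniform mode agrees with
        the independently integrated 0D-membrane reduction."""
        from minwaves.plane_sim import run_point_membrane

        p = models.canonical_parameters(ce0=0.02)
        delta = np.array([0.02, 0.0, 0.0])
        ref = run_point_membrane(p, sphere5, 4.0, delta, n_cells=48)

        sim = SphereSimulator(p, 5.0, lmax=4, n_r=48)
        state = sim.init_from_stationary(rel_amp=0.0)
        sim.mem[0] += sim.sht.uniform(delta[0])
        traj = sim.run(t_max=4.0, dt=1e-3, sample_every=25)
        cd = traj.mem_coeffs[:, 0, 0, 0].real / np.sqrt(4 * np.pi)
        cd_ref = np.interp(traj.t, ref.t, ref.membrane[:, 0])
        span = cd_ref.max() - cd_ref.min()
        assert np.max(np.abs(cd - cd_ref)) < 0.02 * span

    def test_blow_up_guard(self, wave_params):
        sim = SphereSimulator(wave_params, 5.0, lmax=4, n_r=16)
        sim.init_from_stationary()
        traj = sim.run(t_max=10.0, dt=1.0, sample_every=1)  # wildly unstable dt
        assert traj.blew_up


class TestTrajectoryIO:
    def test_hdf5_roundtrip(self, wave_params, tmp_path):
        from minwaves.io import load_sphere_trajectory

        traj = run_sphere(wave_params, 5.0, t_max=0.5, dt=2e-3, lmax=6,
                          n_r=24, sample_every=100)
        path = tmp_path / "traj.h5"
        traj.save(path)
        back = load_sphere_trajectory(path)
        np.testing.assert_array_equal(back.mem_coeffs, traj.mem_coeffs)
        assert back.params == traj.params
        assert back.geometry == traj.geometry
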