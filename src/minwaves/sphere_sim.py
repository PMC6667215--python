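"""Pseudo-spectral simulation of Models I/II on a closed spherical membrane.

Membrane fields are expanded in spherical harmonics (truncation ``lmax``,
default 16); every (l, m) mode of every bulk field obeys a radial
diffusion(-decay) PDE discretized by conservative finite volumes.  Time
stepping is Strang-split: half a step of the stiff linear part (Crank-Nicolson
radial diffusion, exact decay and membrane-diffusion factors), a full Heun
step of the nonlinear reactions evaluated pointwise on the collocation grid
(with boundary fluxes deposited into the membrane-adjacent bulk cells), then
another linear half step.  The scheme conserves total MinD and MinE to
round-off by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from minwaves._bulkgrid import BulkGrid
from minwaves._sht import SphericalHarmonics
from minwaves.models import (
    Geometry,
    ModelParameters,
    StationaryState,
    membrane_reaction_rates,
    stationary_state,
)

__all__ = ["SphereSimulator", "SphereTrajectory", "run_sphere"]

_OVERFLOW_GUARD = 1e6


@dataclass
class SphereTrajectory:
    """Sampled history of a spherical simulation.

    ``mem_coeffs[frame, species, l, m]`` are spherical-harmonic coefficients
    of the membrane fields (species order d, de, e; m >= 0 storage);
    ``totals[frame]`` are the conserved (total MinD, total MinE).
    """

    t: np.ndarray
    mem_coeffs: np.ndarray
    totals: np.ndarray
    params: ModelParameters
    geometry: Geometry
    lmax: int
    blew_up: bool = False
    final_bulk: np.ndarray | None = None

    species = ("d", "de", "e")

    def sht(self) -> SphericalHarmonics:
        return SphericalHarmonics(self.lmax)

    def mode_norms(self, species: int = 0) -> np.ndarray:
        """Rotationally invariant per-degree norms, shape (n_frames, lmax+1)."""
        return self.sht().mode_norms(self.mem_coeffs[:, species])

    def save(self, path) -> None:
        from minwaves.io import save_sphere_trajectory

        save_sphere_trajectory(self, path)


class SphereSimulator:
    """IMEX pseudo-spectral integrator on the sphere of radius R."""

    def __init__(self, params: ModelParameters, radius: float,
                 lmax: int = 16, n_r: int = 64, beta: float = 2.0):
        self.params = params
        self.geometry = Geometry("sphere", radius)
        self.lmax = lmax
        self.sht = SphericalHarmonics(lmax)
        self.grid = BulkGrid("sphere", radius, n_r, beta)
        self.n_bulk = params.n_bulk
        self.mem = np.zeros((3, lmax + 1, lmax + 1), dtype=complex)
        self.bulk = np.zeros((self.n_bulk, self.grid.n, lmax + 1, lmax + 1),
                             dtype=complex)
        self.t = 0.0
        self._cn_cache: dict[float, list] = {}

    # -- initialisation ----------------------------------------------------

    def init_from_stationary(self, state: StationaryState | None = None,
                             perturb_l: int = 1, perturb_m: int | None = None,
                             rel_amp: float = 1e-3) -> StationaryState:
        """Homogeneous stationary state plus a small perturbation of membrane
        MinD at degree ``perturb_l``.

        With ``perturb_m=None`` a generic (axisymmetry-breaking) combination
        of m = 0 and m = 1 is used so that rotating patterns can develop;
        pass an explicit m for a single-mode perturbation.
        """
        if state is None:
            state = stationary_state(self.params, self.geometry)
        p = self.params
        for i, v in enumerate(state.membrane):
            self.mem[i] = self.sht.uniform(v)
        if rel_amp and perturb_l > 0:
            amp = rel_amp * max(state.cd, 1e-3)
            if perturb_m is None:
                self.mem[0, perturb_l, 0] += amp
                self.mem[0, perturb_l, 1] += amp * (0.6 + 0.8j)
            else:
                self.mem[0, perturb_l, perturb_m] += amp
        self.bulk[:] = 0.0
        if p.model_variant == "I":
            self.bulk[0, :, 0, 0] = self.sht.uniform(state.bulk_surface[0])[0, 0]
            self.bulk[1, :, 0, 0] = self.sht.uniform(state.bulk_surface[1])[0, 0]
        else:
            u = state.bulk_surface[0] + state.bulk_surface[1]
            prof = self.grid.stationary_profile(p.omega_e * state.cde,
                                                p.D_bulk, p.lam)
            s4 = math.sqrt(4.0 * math.pi)
            self.bulk[0, :, 0, 0] = u * s4
            self.bulk[1, :, 0, 0] = prof * s4
            self.bulk[2, :, 0, 0] = state.bulk_surface[2] * s4
        self.t = 0.0
        return state

    def init_droplet(self, perturb_l: int = 1, amp: float = 1e-3) -> None:
        """Fresh-droplet protocol: all protein uniformly in the bulk, an empty
        membrane, and a tiny symmetry-breaking membrane MinD seed.

        This is the wave-emergence scenario: the membrane loads collectively
        (pulsing) before a spatial mode takes over.
        """
        p = self.params
        s4 = math.sqrt(4.0 * math.pi)
        self.mem[:] = 0.0
        self.bulk[:] = 0.0
        self.bulk[0, :, 0, 0] = p.D0 * s4
        self.bulk[-1, :, 0, 0] = p.eps0 * s4
        if perturb_l > 0 and amp:
            self.mem[0, perturb_l, 0] = amp
            self.mem[0, perturb_l, 1] = amp * (0.6 + 0.8j)
        self.t = 0.0

    # -- dynamics ----------------------------------------------------------

    def _reaction_rhs(self, mem, bulk):
        surf_eigen = self.grid.surface_value(bulk, axis=1)
        surf_phys = self.params.bulk_from_eigen(surf_eigen)
        fields = self.sht.synthesize(np.concatenate([mem, surf_phys]))
        rates, fluxes = membrane_reaction_rates(fields[:3], fields[3:],
                                                self.params)
        coeffs = self.sht.analyze(np.concatenate([rates, fluxes]))
        dmem = coeffs[:3]
        flux_eigen = self.params.bulk_to_eigen(coeffs[3:])
        dbulk = np.zeros_like(bulk)
        self.grid.deposit(dbulk, flux_eigen, axis=1)
        return dmem, dbulk

    def _propagators(self, dt_lin: float):
        """Dense propagators of the linear bulk step, per degree l.

        Crank-Nicolson for the radial diffusion combined with the exact decay
        factor of each eigenfield, precomputed as one matrix multiply.
        """
        key = round(dt_lin, 15)
        if key not in self._cn_cache:
            props = []
            eye = np.eye(self.grid.n)
            for l in range(self.lmax + 1):
                L = self.grid.laplacian(self.params.D_bulk, mode_l=l)
                M = np.linalg.solve(eye - 0.5 * dt_lin * L,
                                    eye + 0.5 * dt_lin * L)
                props.append(M)
            l_arr = np.arange(self.lmax + 1)
            mem_fac = np.exp(-self.params.D_mem * l_arr * (l_arr + 1)
                             / self.geometry.size ** 2 * dt_lin)
            decay = np.exp(-self.params.bulk_decay * dt_lin)
            self._cn_cache[key] = (props, mem_fac, decay)
        return self._cn_cache[key]

    def _linear_step(self, dt_lin: float) -> None:
        props, mem_fac, decay = self._propagators(dt_lin)
        self.mem *= mem_fac[None, :, None]
        self.bulk *= decay[:, None, None, None]
        for l in range(self.lmax + 1):
            block = self.bulk[:, :, l, :l + 1]
            nb, n_r, nm = block.shape
            x = block.transpose(1, 0, 2).reshape(n_r, nb * nm)
            self.bulk[:, :, l, :l + 1] = (props[l] @ x).reshape(
                n_r, nb, nm).transpose(1, 0, 2)

    def _reaction_step(self, dt: float) -> None:
        d1m, d1b = self._reaction_rhs(self.mem, self.bulk)
        m1 = self.mem + dt * d1m
        b1 = self.bulk + dt * d1b
        d2m, d2b = self._reaction_rhs(m1, b1)
        self.mem += 0.5 * dt * (d1m + d2m)
        self.bulk += 0.5 * dt * (d1b + d2b)

    def step(self, dt: float, rng: np.random.Generator | None = None,
             noise_amp: float = 0.0) -> None:
        """One Strang-split step (standalone; ``run`` fuses the half steps of
        consecutive steps for speed)."""
        self._linear_step(0.5 * dt)
        self._reaction_step(dt)
        self._linear_step(0.5 * dt)
        if noise_amp and rng is not None:
            self._add_noise(dt, rng, noise_amp)
        self.t += dt

    def _add_noise(self, dt: float, rng: np.random.Generator,
                   amp: float) -> None:
        """Seeded Gaussian forcing of the inhomogeneous membrane modes
        (l >= 1 only, so conservation is untouched)."""
        scale = amp * math.sqrt(dt)
        shape = self.mem.shape
        re = rng.normal(scale=scale, size=shape)
        im = rng.normal(scale=scale, size=shape)
        noise = re + 1j * im
        mask = np.tril(np.ones((self.lmax + 1, self.lmax + 1)))
        mask[0, :] = 0.0                       # keep l=0 untouched
        noise *= mask
        noise[:, :, 0] = noise[:, :, 0].real   # m=0 coefficients are real
        self.mem += noise

    # -- diagnostics -------------------------------------------------------

    def totals(self) -> tuple[float, float]:
        """Conserved totals (bulk average + alpha * membrane average)."""
        s4 = math.sqrt(4.0 * math.pi)
        alpha = self.geometry.alpha
        mem_mean = self.mem[:, 0, 0].real / s4
        bulk_mean = self.grid.mean(self.bulk[:, :, 0, 0].real, axis=1) / s4
        if self.params.model_variant == "I":
            d_bulk, e_bulk = bulk_mean
        else:
            d_bulk, e_bulk = bulk_mean[0], bulk_mean[2]
        total_d = d_bulk + alpha * (mem_mean[0] + mem_mean[1])
        total_e = e_bulk + alpha * (mem_mean[1] + mem_mean[2])
        return float(total_d), float(total_e)

    def run(self, t_max: float, dt: float = 2e-3, sample_every: int = 50,
            noise_amp: float = 0.0, seed: int | None = None) -> SphereTrajectory:
        rng = np.random.default_rng(seed) if (noise_amp or seed is not None) \
            else None
        n_steps = int(round(t_max / dt))
        frames_t, frames_c, frames_tot = [], [], []

        def record():
            frames_t.append(self.t)
            frames_c.append(self.mem.copy())
            frames_tot.append(self.totals())

        record()
        blew_up = False
        if noise_amp:
            for i in range(n_steps):
                self.step(dt, rng=rng, noise_amp=noise_amp)
                if not np.isfinite(self.mem).all() or \
                        np.abs(self.mem).max() > _OVERFLOW_GUARD:
                    blew_up = True
                    break
                if (i + 1) % sample_every == 0:
                    record()
            if not blew_up and (n_steps % sample_every):
                record()
        else:
            # fuse the trailing/leading linear half steps of adjacent steps
            half = 0.5 * dt
            self._linear_step(half)
            for i in range(n_steps):
                self._reaction_step(dt)
                self.t += dt
                last = i == n_steps - 1
                boundary = last or ((i + 1) % sample_every == 0)
                self._linear_step(half if boundary else dt)
                if not np.isfinite(self.mem).all() or \
                        np.abs(self.mem).max() > _OVERFLOW_GUARD:
                    blew_up = True
                    break
                if boundary:
                    record()
                    if not last:
                        self._linear_step(half)
        return SphereTrajectory(
            np.array(frames_t), np.array(frames_c), np.array(frames_tot),
            self.params, self.geometry, self.lmax, blew_up=blew_up,
            final_bulk=self.bulk.copy())


def run_sphere(params: ModelParameters, radius: float, t_max: float,
               dt: float = 2e-3, lmax: int = 16, n_r: int = 64,
               init: str | dict = "stationary+perturbation",
               perturb_l: int = 1, perturb_m: int | None = None,
               rel_amp: float = 1e-3,
               sample_every: int = 50, noise_amp: float = 0.0,
               seed: int | None = None) -> SphereTrajectory:
    """Simulate Model I/II on a closed sphere and return the trajectory.

    ``init`` is the default stationary-plus-perturbation protocol, the
    ``"droplet"`` wave-emergence protocol (all protein in the bulk), or a
    dict with explicit coefficient arrays ``{"mem": ..., "bulk": ...}``.
    """
    sim = SphereSimulator(params, radius, lmax=lmax, n_r=n_r)
    if isinstance(init, dict):
        sim.mem[:] = init["mem"]
        sim.bulk[:] = init["bulk"]
    elif init == "stationary+perturbation":
        sim.init_from_stationary(perturb_l=perturb_l, perturb_m=perturb_m,
                                 rel_amp=rel_amp)
    elif init == "droplet":
        sim.init_droplet(perturb_l=perturb_l, amp=rel_amp)
    else:
        raise ValueError(f"unknown init {init!r}")
    return sim.run(t_max, dt=dt, sample_every=sample_every,
                   noise_amp=noise_amp, seed=seed)
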