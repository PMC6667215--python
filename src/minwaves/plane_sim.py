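"""Planar-membrane simulators: 2D membrane / 3D bulk, 1D membrane / 2D bulk,
and the 0D-membrane / 1D-bulk reduction used for excitability analysis.

The in-plane directions are periodic and handled in Fourier space; the height
direction is resolved with the same conservative finite-volume column as the
sphere's radial direction (clustered towards the membrane at z = 0).  The
full simulators use the Strang-split IMEX scheme of :mod:`sphere_sim`; the
point-membrane reduction integrates the unsplit stiff ODE system with
``scipy.integrate.solve_ivp`` for smooth phase-space trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

from minwaves._bulkgrid import BulkGrid
from minwaves.models import (
    Geometry,
    ModelParameters,
    StationaryState,
    membrane_reaction_rates,
    stationary_state,
)

__all__ = [
    "PlanarSimulator",
    "PlanarTrajectory",
    "run_plane",
    "run_point_membrane",
    "PointTrajectory",
    "excitability_threshold",
    "NotExcitable",
]

_OVERFLOW_GUARD = 1e6


# ---------------------------------------------------------------------------
# 0D membrane / 1D bulk reduction

@dataclass
class PointTrajectory:
    """Membrane concentrations of the spatially homogeneous reduction."""

    t: np.ndarray
    membrane: np.ndarray          # (n_frames, 3) -> (c_d, c_de, c_e)
    params: ModelParameters
    geometry: Geometry
    state: StationaryState

    @property
    def excursion(self) -> float:
        """Maximum phase-space distance from the stationary point."""
        return float(np.linalg.norm(
            self.membrane - self.state.membrane, axis=1).max())


def run_point_membrane(params: ModelParameters, geometry: Geometry,
                       t_max: float, delta: np.ndarray | None = None,
                       n_cells: int = 64, rtol: float = 1e-8,
                       atol: float = 1e-10,
                       n_frames: int = 400) -> PointTrajectory:
    """Integrate the homogeneous-membrane reduction (bulk resolved in 1D).

    The membrane starts at the stationary state shifted by ``delta`` (a length
    3 array added to ``(c_d, c_de, c_e)``); the bulk starts on its stationary
    profile.
    """
    p = params
    state = stationary_state(p, geometry)
    grid = BulkGrid(geometry.kind, geometry.size, n_cells)
    n_b = p.n_bulk
    L = grid.laplacian(p.D_bulk, mode_l=0 if geometry.kind == "sphere" else None)
    lam = p.bulk_decay

    bulk0 = np.zeros((n_b, grid.n))
    if p.model_variant == "I":
        bulk0[0] = state.bulk_surface[0]
        bulk0[1] = state.bulk_surface[1]
    else:
        bulk0[0] = state.bulk_surface[0] + state.bulk_surface[1]
        bulk0[1] = grid.stationary_profile(p.omega_e * state.cde, p.D_bulk,
                                           p.lam)
        bulk0[2] = state.bulk_surface[2]

    y0 = np.concatenate([state.membrane + (delta if delta is not None else 0.0),
                         bulk0.ravel()])

    def rhs(t, y):
        mem = y[:3]
        bulk = y[3:].reshape(n_b, grid.n)
        surf = p.bulk_from_eigen(grid.surface_value(bulk))
        rates, fluxes = membrane_reaction_rates(mem, surf, p)
        dbulk = bulk @ L.T - lam[:, None] * bulk
        grid.deposit(dbulk, p.bulk_to_eigen(fluxes))
        return np.concatenate([rates, dbulk.ravel()])

    t_eval = np.linspace(0.0, t_max, n_frames)
    sol = solve_ivp(rhs, (0.0, t_max), y0, method="LSODA", rtol=rtol,
                    atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"point-membrane integration failed: {sol.message}")
    return PointTrajectory(sol.t, sol.y[:3].T.copy(), p, geometry, state)


class NotExcitable(RuntimeError):
    """Raised when no excitability threshold exists within the search bounds."""


def excitability_threshold(params: ModelParameters, geometry: Geometry,
                           axis: int = 0, bounds=(1e-3, 0.5),
                           factor: float = 10.0, t_max: float = 50.0,
                           tol: float = 1e-3, n_cells: int = 64) -> float:
    """Smallest perturbation of one membrane species triggering a large
    excursion.

    The response is classified as excited when the maximum phase-space
    distance from the fixed point exceeds ``factor`` times the initial
    perturbation.  The threshold is refined by bisection to ``tol``; if the
    response is never excited within ``bounds`` a :class:`NotExcitable` error
    is raised.
    """

    def excited(delta_val: float) -> bool:
        delta = np.zeros(3)
        delta[axis] = delta_val
        traj = run_point_membrane(params, geometry, t_max, delta,
                                  n_cells=n_cells)
        return traj.excursion > factor * abs(delta_val)

    lo, hi = bounds
    if excited(lo):
        raise NotExcitable(
            f"already excited at the lower bound {lo}; no threshold in bounds")
    # geometric scan for a bracket
    val = lo
    bracket_hi = None
    while val < hi:
        val = min(val * 1.3, hi)
        if excited(val):
            bracket_hi = val
            break
        lo = val
        if val >= hi:
            break
    if bracket_hi is None:
        raise NotExcitable(
            f"no excursion above {factor}x response for perturbations up to "
            f"{hi}; system is not excitable")
    while bracket_hi - lo > tol:
        mid = 0.5 * (lo + bracket_hi)
        if excited(mid):
            bracket_hi = mid
        else:
            lo = mid
    return 0.5 * (lo + bracket_hi)


# ---------------------------------------------------------------------------
# full planar simulators (1D or 2D membrane)

@dataclass
class PlanarTrajectory:
    """Sampled history of a planar simulation.

    ``mem[frame, species, x(, y)]`` are real-space membrane fields;
    ``mem_k`` gives the rfft coefficients of the last frame.
    """

    t: np.ndarray
    mem: np.ndarray
    totals: np.ndarray
    params: ModelParameters
    height: float
    lengths: tuple[float, ...]
    blew_up: bool = False

    species = ("d", "de", "e")

    def amplitudes(self, species: int = 0) -> np.ndarray:
        """|c_{d,k}| per frame and wave number (1D membranes only)."""
        if self.mem.ndim != 3:
            raise ValueError("per-k amplitudes are defined for 1D membranes")
        n = self.mem.shape[-1]
        return np.abs(np.fft.rfft(self.mem[:, species], axis=-1)) / n

    def save(self, path) -> None:
        from minwaves.io import save_planar_trajectory

        save_planar_trajectory(self, path)


class PlanarSimulator:
    """Strang-split IMEX integrator for a periodic planar membrane under a
    z-resolved bulk (membrane dimensionality 1 or 2)."""

    def __init__(self, params: ModelParameters, height: float,
                 lengths, n_grid, n_z: int = 48, beta: float = 2.0):
        self.params = params
        self.height = float(height)
        self.lengths = tuple(float(v) for v in np.atleast_1d(lengths))
        self.shape = tuple(int(v) for v in np.atleast_1d(n_grid))
        self.dim = len(self.shape)
        if self.dim not in (1, 2):
            raise ValueError("membrane must be 1D or 2D")
        if len(self.lengths) != self.dim:
            raise ValueError("lengths and n_grid mismatch")
        self.grid = BulkGrid("slab", height, n_z, beta)
        self.n_bulk = params.n_bulk
        # spectral shapes (rfft over the last axis)
        kshape = self.shape[:-1] + (self.shape[-1] // 2 + 1,)
        self.kshape = kshape
        ks = []
        for ax, (n, Lbox) in enumerate(zip(self.shape, self.lengths)):
            freq = (np.fft.rfftfreq(n, d=Lbox / n) if ax == self.dim - 1
                    else np.fft.fftfreq(n, d=Lbox / n))
            ks.append(2.0 * np.pi * freq)
        mesh = np.meshgrid(*ks, indexing="ij")
        self.k2 = sum(k ** 2 for k in mesh)
        self.mem = np.zeros((3,) + kshape, dtype=complex)
        self.bulk = np.zeros((self.n_bulk, self.grid.n) + kshape,
                             dtype=complex)
        self.t = 0.0
        self._cn_cache: dict[float, tuple] = {}
        self._npoints = int(np.prod(self.shape))

    # -- spectral helpers --------------------------------------------------

    def _to_grid(self, coeffs: np.ndarray) -> np.ndarray:
        return np.fft.irfftn(coeffs, s=self.shape,
                             axes=tuple(range(-self.dim, 0))) * self._npoints

    def _to_spectral(self, fields: np.ndarray) -> np.ndarray:
        return np.fft.rfftn(fields, axes=tuple(range(-self.dim, 0))) \
            / self._npoints

    # -- initialisation ----------------------------------------------------

    def init_from_stationary(self, state: StationaryState | None = None):
        p = self.params
        if state is None:
            state = stationary_state(p, Geometry("slab", self.height))
        zero = (0,) * self.dim
        for i, v in enumerate(state.membrane):
            self.mem[i][zero] = v
        self.bulk[:] = 0.0
        if p.model_variant == "I":
            self.bulk[0, :, *zero] = state.bulk_surface[0]
            self.bulk[1, :, *zero] = state.bulk_surface[1]
        else:
            self.bulk[0, :, *zero] = state.bulk_surface[0] + state.bulk_surface[1]
            self.bulk[1, :, *zero] = self.grid.stationary_profile(
                p.omega_e * state.cde, p.D_bulk, p.lam)
            self.bulk[2, :, *zero] = state.bulk_surface[2]
        self.t = 0.0
        return state

    def add_membrane_band(self, species: int = 0, amplitude: float = 0.3,
                          center: float | None = None, width: float = 2.0,
                          axis: int = 0) -> None:
        """Add a localized Gaussian band of a membrane species (real space).

        A band launches two counter-propagating excitation pulses; on a
        periodic domain they annihilate when they meet, so analyses should
        use the pre-collision window.
        """
        fields = self._to_grid(self.mem)
        coords = [np.linspace(0, Lbox, n, endpoint=False)
                  for Lbox, n in zip(self.lengths, self.shape)]
        x = coords[axis]
        c0 = self.lengths[axis] / 2 if center is None else center
        bump = amplitude * np.exp(-0.5 * ((x - c0) / width) ** 2)
        shape = [1] * self.dim
        shape[axis] = -1
        fields[species] += bump.reshape(shape)
        self.mem = self._to_spectral(fields)

    def cut_half_plane(self, axis: int = 0, position: float | None = None) -> None:
        """Zero all membrane fields on one half of the domain (spiral-wave
        protocol: cut a propagating band)."""
        fields = self._to_grid(self.mem)
        coords = np.linspace(0, self.lengths[axis], self.shape[axis],
                             endpoint=False)
        pos = self.lengths[axis] / 2 if position is None else position
        mask = coords < pos
        shape = [1] * self.dim
        shape[axis] = -1
        fields *= mask.reshape(shape)
        self.mem = self._to_spectral(fields)

    # -- dynamics ----------------------------------------------------------

    def _reaction_rhs(self, mem, bulk):
        mem_fields = self._to_grid(mem)
        surf = self.params.bulk_from_eigen(self.grid.surface_value(bulk, axis=1))
        surf_fields = self._to_grid(surf)
        rates, fluxes = membrane_reaction_rates(mem_fields, surf_fields,
                                                self.params)
        dmem = self._to_spectral(rates)
        flux_eigen = self.params.bulk_to_eigen(self._to_spectral(fluxes))
        dbulk = np.zeros_like(bulk)
        self.grid.deposit(dbulk, flux_eigen, axis=1)
        return dmem, dbulk

    def _cn_factors(self, dt_half: float):
        key = round(dt_half, 15)
        if key not in self._cn_cache:
            self._cn_cache[key] = self.grid.crank_nicolson_factors(
                self.params.D_bulk, dt_half)
        return self._cn_cache[key]

    def _linear_half_step(self, dt_half: float) -> None:
        p = self.params
        self.mem *= np.exp(-p.D_mem * self.k2 * dt_half)[None]
        decay = np.exp(-(p.bulk_decay[:, None] + p.D_bulk * self.k2.reshape(
            1, -1)) * dt_half).reshape((self.n_bulk, 1) + self.kshape)
        self.bulk *= decay
        lu, bplus = self._cn_factors(dt_half)
        flat = self.bulk.reshape(self.n_bulk, self.grid.n, -1)
        x = np.moveaxis(flat, 1, 0).reshape(self.grid.n, -1)
        x = linalg.lu_solve(lu, bplus @ x)
        self.bulk = np.moveaxis(
            x.reshape(self.grid.n, self.n_bulk, -1), 0, 1).reshape(
            self.bulk.shape)

    def step(self, dt: float) -> None:
        self._linear_half_step(0.5 * dt)
        d1m, d1b = self._reaction_rhs(self.mem, self.bulk)
        m1 = self.mem + dt * d1m
        b1 = self.bulk + dt * d1b
        d2m, d2b = self._reaction_rhs(m1, b1)
        self.mem += 0.5 * dt * (d1m + d2m)
        self.bulk += 0.5 * dt * (d1b + d2b)
        self._linear_half_step(0.5 * dt)
        self.t += dt

    def totals(self) -> tuple[float, float]:
        zero = (0,) * self.dim
        alpha = 1.0 / self.height
        mem_mean = np.array([self.mem[i][zero].real for i in range(3)])
        bulk_mean = self.grid.mean(
            np.stack([self.bulk[i][(slice(None),) + zero].real
                      for i in range(self.n_bulk)]), axis=1)
        if self.params.model_variant == "I":
            d_bulk, e_bulk = bulk_mean
        else:
            d_bulk, e_bulk = bulk_mean[0], bulk_mean[2]
        total_d = d_bulk + alpha * (mem_mean[0] + mem_mean[1])
        total_e = e_bulk + alpha * (mem_mean[1] + mem_mean[2])
        return float(total_d), float(total_e)

    def run(self, t_max: float, dt: float = 2e-3, sample_every: int = 50,
            cut_at: float | None = None, cut_axis: int = 0) -> PlanarTrajectory:
        n_steps = int(round(t_max / dt))
        frames_t, frames_f, frames_tot = [], [], []

        def record():
            frames_t.append(self.t)
            frames_f.append(self._to_grid(self.mem))
            frames_tot.append(self.totals())

        record()
        blew_up = False
        did_cut = cut_at is None
        for i in range(n_steps):
            self.step(dt)
            if not did_cut and self.t >= cut_at:
                self.cut_half_plane(axis=cut_axis)
                did_cut = True
            if not np.isfinite(self.mem).all() or \
                    np.abs(self.mem).max() > _OVERFLOW_GUARD:
                blew_up = True
                break
            if (i + 1) % sample_every == 0:
                record()
        if not blew_up and (n_steps % sample_every):
            record()
        return PlanarTrajectory(
            np.array(frames_t), np.array(frames_f), np.array(frames_tot),
            self.params, self.height, self.lengths, blew_up=blew_up)


def run_plane(params: ModelParameters, height: float, lengths, n_grid,
              t_max: float, dt: float = 2e-3, n_z: int = 48,
              init: str = "stationary", band_amplitude: float = 0.3,
              band_width: float = 2.0, sample_every: int = 50,
              cut_at: float | None = None) -> PlanarTrajectory:
    """Simulate a 1D or 2D planar membrane under a z-resolved bulk.

    ``init`` is "stationary" (homogeneous stationary state) or "band"
    (stationary state plus a localized band of membrane MinD, the solitary
    pulse protocol).  ``cut_at`` optionally zeros half the membrane at the
    given time to seed a spiral wave.
    """
    sim = PlanarSimulator(params, height, lengths, n_grid, n_z=n_z)
    sim.init_from_stationary()
    if init == "band":
        sim.add_membrane_band(amplitude=band_amplitude, width=band_width)
    elif init != "stationary":
        raise ValueError(f"unknown init {init!r}")
    return sim.run(t_max, dt=dt, sample_every=sample_every, cut_at=cut_at)
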