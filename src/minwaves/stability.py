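"""Linear stability of the homogeneous stationary state.

Two independent routes are provided:

* :func:`full_eigenvalues` discretizes the bulk diffusion problem with
  Chebyshev collocation and solves the resulting generalized linear
  eigenproblem (membrane concentrations are dynamic; the boundary rows are
  algebraic constraints).
* :func:`dispersion_bulk_eliminated` eliminates the bulk analytically: per
  mode the bulk perturbation of a field with linear rate lambda_i is
  ``a * i_l(r/xi_i)`` on the sphere (modified spherical Bessel function) or
  ``a * cosh((H-z)/xi_i)`` on the slab, with ``xi_i = sqrt(D/(sigma +
  lambda_i))`` (slab: ``1/xi_i^2 = k^2 + (sigma + lambda_i)/D``).  Boundary
  conditions then reduce the problem to a 3x3 root search
  ``det(C(sigma)) = 0`` in the complex plane.

The two routes agree to ~1e-8 on the dominant eigenvalue and serve as mutual
oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.special import spherical_in

from minwaves.models import (
    Geometry,
    ModelParameters,
    StationaryState,
    stationary_state,
)

__all__ = [
    "LinearizedSystem",
    "DispersionResult",
    "linearize",
    "mode_shift_eigenvalues",
    "full_eigenvalues",
    "dispersion_bulk_eliminated",
    "max_growth_rate",
    "critical_ce0",
    "phase_diagram",
    "dispersion_to_frame",
]


@dataclass(frozen=True)
class LinearizedSystem:
    """Blocks of the linearized bulk-surface problem at a fixed point.

    All bulk quantities refer to the decoupled (eigen) bulk fields with linear
    rates ``lam`` (Model I: ``(c_D, c_E)``; Model II:
    ``(c_DT + c_DD, c_DD, c_E)``).

    Attributes
    ----------
    A0 : membrane reaction Jacobian at mode zero, bulk held fixed (3x3).
    Gamma : coupling of membrane rates to bulk surface values (3 x n_bulk).
    F : coupling of boundary fluxes (into bulk) to membrane species.
    G : coupling of boundary fluxes to bulk surface values.
    lam : linear rates of the eigen bulk fields.
    """

    A0: np.ndarray
    Gamma: np.ndarray
    F: np.ndarray
    G: np.ndarray
    lam: np.ndarray
    params: ModelParameters
    geometry: Geometry
    state: StationaryState


@dataclass(frozen=True)
class DispersionResult:
    """Eigenvalues of one spatial mode."""

    mode: float                 # l (sphere) or k (slab)
    sigma: np.ndarray           # eigenvalues sorted by decreasing real part
    geometry: Geometry

    @property
    def max_re(self) -> float:
        return float(self.sigma[0].real)

    @property
    def max_re_nontrivial(self) -> float:
        """Largest Re sigma excluding the exact zeros that mass conservation
        pins at the homogeneous mode (l=0 / k=0)."""
        keep = np.abs(self.sigma) > 1e-7
        if self.mode == 0 and keep.any():
            return float(np.max(self.sigma[keep].real))
        return self.max_re

    @property
    def im_at_max(self) -> float:
        return float(self.sigma[0].imag)

    @property
    def unstable(self) -> bool:
        return self.max_re > 0

    @property
    def oscillatory(self) -> bool:
        return self.unstable and abs(self.im_at_max) > 1e-10


def linearize(params: ModelParameters, geometry: Geometry,
              state: StationaryState | None = None) -> LinearizedSystem:
    """Build the linearized blocks around the homogeneous stationary state."""
    if state is None:
        state = stationary_state(params, geometry)
    p = params
    cd, cde, ce = state.cd, state.cde, state.ce
    if p.model_variant == "I":
        cA, cE = state.bulk_surface
    else:
        cDT, cDD, cE = state.bulk_surface
        cA = cDT
    g = p.omega_D + p.omega_dD * cd
    if p.saturation:
        s = 1.0 - cd - cde
        ds_cd = ds_cde = -1.0
    else:
        s, ds_cd, ds_cde = 1.0, 0.0, 0.0

    dJatt_cd = (p.omega_dD * s + g * ds_cd) * cA
    dJatt_cde = g * ds_cde * cA
    A0 = np.array([
        [dJatt_cd - p.omega_E * cE - p.omega_ed * ce,
         dJatt_cde, -p.omega_ed * cd],
        [p.omega_E * cE + p.omega_ed * ce, -p.omega_e, p.omega_ed * cd],
        [-p.omega_ed * ce, p.omega_e, -p.omega_e - p.omega_ed * cd],
    ])
    gs = g * s
    if p.model_variant == "I":
        Gamma = np.array([[gs, -p.omega_E * cd],
                          [0.0, p.omega_E * cd],
                          [0.0, 0.0]])
        F = np.array([[-dJatt_cd, p.omega_e - dJatt_cde, 0.0],
                      [-p.omega_E * cE, 0.0, p.omega_e]])
        G = np.array([[-gs, 0.0],
                      [0.0, -p.omega_E * cd]])
    else:
        Gamma = np.array([[gs, -gs, -p.omega_E * cd],
                          [0.0, 0.0, p.omega_E * cd],
                          [0.0, 0.0, 0.0]])
        F = np.array([[-dJatt_cd, p.omega_e - dJatt_cde, 0.0],
                      [0.0, p.omega_e, 0.0],
                      [-p.omega_E * cE, 0.0, p.omega_e]])
        G = np.array([[-gs, gs, 0.0],
                      [0.0, 0.0, 0.0],
                      [0.0, 0.0, -p.omega_E * cd]])
    return LinearizedSystem(A0, Gamma, F, G, p.bulk_decay.copy(),
                            p, geometry, state)


def _mode_shift(geometry: Geometry, mode: float, D_mem: float) -> float:
    """Membrane-diffusion eigenvalue: l(l+1)/R^2 on the sphere, k^2 on the slab."""
    if geometry.kind == "sphere":
        l = int(mode)
        return D_mem * l * (l + 1) / geometry.size ** 2
    return D_mem * mode ** 2


def mode_shift_eigenvalues(params: ModelParameters, geometry: Geometry,
                           mode: float,
                           system: LinearizedSystem | None = None) -> np.ndarray:
    """Eigenvalues of the membrane-only Jacobian shifted by membrane diffusion,
    i.e. of ``Lambda_{l=0}(0) - l(l+1)/R^2 * I`` (bulk dynamics neglected)."""
    sys_ = system if system is not None else linearize(params, geometry)
    shift = _mode_shift(geometry, mode, params.D_mem)
    ev = np.linalg.eigvals(sys_.A0) - shift
    return ev[np.argsort(-ev.real)]


# ---------------------------------------------------------------------------
# analytic bulk factors

def _spherical_i_ratio(l: int, z: np.ndarray) -> np.ndarray:
    """i_l(z)/i_l'(z) for complex z, elementwise."""
    z = np.atleast_1d(np.asarray(z, dtype=complex))
    out = np.empty_like(z)
    for idx, zz in np.ndenumerate(z):
        if abs(zz) < 1e-6:
            # i_l ~ z^l/(2l+1)!!: ratio -> z/l for l>=1; 3/z + z/5 for l=0
            out[idx] = (3.0 / zz + zz / 5.0) if l == 0 else zz / l
        else:
            out[idx] = spherical_in(l, zz) / spherical_in(l, zz, derivative=True)
    return out


def bulk_response(system: LinearizedSystem, mode: float,
                  sigma: complex) -> np.ndarray:
    """Diagonal K(sigma): bulk surface perturbation per unit boundary flux."""
    D = system.params.D_bulk
    size = system.geometry.size
    denom = sigma + system.lam + 0j
    denom = np.where(np.abs(denom) < 1e-14, 1e-14, denom)
    if system.geometry.kind == "sphere":
        xi = np.sqrt(D / denom)
        l = int(mode)
        return (xi / D) * _spherical_i_ratio(l, size / xi)
    inv_xi2 = mode ** 2 + denom / D
    xi = 1.0 / np.sqrt(inv_xi2)
    return (xi / D) / np.tanh(size / xi)


def characteristic_matrix(system: LinearizedSystem, mode: float,
                          sigma: complex) -> np.ndarray:
    """C(sigma) whose singularity condition det C = 0 gives the eigenvalues."""
    K = np.diag(bulk_response(system, mode, sigma))
    n = system.lam.size
    bs = np.linalg.solve(np.eye(n) - K @ system.G, K @ system.F)
    shift = _mode_shift(system.geometry, mode, system.params.D_mem)
    return (system.A0 - shift * np.eye(3) + system.Gamma @ bs
            - sigma * np.eye(3))


def _det_normalized(system: LinearizedSystem, mode: float,
                    sigma: complex) -> complex:
    C = characteristic_matrix(system, mode, sigma)
    scale = max(np.linalg.norm(C, ord=np.inf), 1.0)
    return np.linalg.det(C / scale)


def dispersion_bulk_eliminated(
    params: ModelParameters,
    geometry: Geometry,
    mode: float,
    state: StationaryState | None = None,
    re_range: tuple[float, float] = (-3.0, 3.0),
    im_range: tuple[float, float] = (0.0, 4.0),
    n_starts: tuple[int, int] = (13, 9),
    extra_starts=(),
    residual_tol: float = 1e-10,
) -> DispersionResult:
    """Roots sigma of det(Lambda_l(0) + Gamma.M(sigma) - sigma I) = 0.

    Newton iterations are seeded on a rectangular grid in the complex plane
    (only Im >= 0 is scanned; conjugates are added).  Roots are deduplicated
    and filtered by the normalized determinant residual.
    """
    system = linearize(params, geometry, state)

    def fun(v):
        d = _det_normalized(system, mode, v[0] + 1j * v[1])
        return [d.real, d.imag]

    starts = [complex(re, im)
              for re in np.linspace(*re_range, n_starts[0])
              for im in np.linspace(*im_range, n_starts[1])]
    starts += list(extra_starts)
    roots: list[complex] = []
    for s0 in starts:
        sol = optimize.root(fun, [s0.real, s0.imag], method="hybr",
                            options={"xtol": 1e-13})
        if not sol.success:
            continue
        s = complex(sol.x[0], abs(sol.x[1]))
        if abs(_det_normalized(system, mode, s)) > residual_tol:
            continue
        if not any(abs(s - r) < 1e-8 * max(1.0, abs(r)) for r in roots):
            roots.append(s)
    sigma = []
    for r in roots:
        sigma.append(r)
        if abs(r.imag) > 1e-10:
            sigma.append(r.conjugate())
    sigma = np.array(sorted(sigma, key=lambda z: (-z.real, -z.imag)),
                     dtype=complex)
    return DispersionResult(mode, sigma, geometry)


# ---------------------------------------------------------------------------
# full eigenproblem via Chebyshev collocation of the bulk

def _cheb(N: int):
    """Chebyshev differentiation matrix and Gauss-Lobatto nodes on [-1, 1]."""
    if N == 0:
        return np.zeros((1, 1)), np.array([1.0])
    x = np.cos(np.pi * np.arange(N + 1) / N)
    c = np.ones(N + 1)
    c[0] = c[-1] = 2.0
    c *= (-1.0) ** np.arange(N + 1)
    X = np.tile(x, (N + 1, 1)).T
    dX = X - X.T
    Dm = np.outer(c, 1.0 / c) / (dX + np.eye(N + 1))
    Dm -= np.diag(Dm.sum(axis=1))
    return Dm, x


def full_eigenvalues(
    params: ModelParameters,
    geometry: Geometry,
    mode: float,
    state: StationaryState | None = None,
    n_cheb: int = 48,
) -> DispersionResult:
    """All eigenvalues of the linearized bulk-surface problem at one mode.

    The bulk is resolved with ``n_cheb + 1`` Chebyshev nodes; on the sphere
    the substitution ``w(r) = r c(r)`` removes the coordinate singularity at
    the origin (regularity becomes the Dirichlet condition ``w(0) = 0``).
    Rows expressing boundary conditions are algebraic, which makes the pencil
    singular; infinite eigenvalues are filtered out.
    """
    system = linearize(params, geometry, state)
    p = params
    D = p.D_bulk
    n_b = system.lam.size
    N = n_cheb
    Dm, x = _cheb(N)
    size = geometry.size
    # node 0 -> boundary opposite the membrane, node N -> membrane
    if geometry.kind == "sphere":
        r = size * (1.0 - x) / 2.0     # r[0]=0 (center), r[N]=size (membrane)
        Dr = -(2.0 / size) * Dm
    else:
        z = size * (1.0 + x) / 2.0     # z[0]=size (top), z[N]=0 (membrane)
        Dr = (2.0 / size) * Dm         # d/dz
    D2 = (Dr @ Dr)

    ntot = 3 + n_b * (N + 1)
    M = np.zeros((ntot, ntot))
    B = np.zeros(ntot)
    B[:3] = 1.0
    shift = _mode_shift(geometry, mode, p.D_mem)
    M[:3, :3] = system.A0 - shift * np.eye(3)

    def blk(i):
        return 3 + i * (N + 1)

    surf_cols = [blk(i) + N for i in range(n_b)]
    if geometry.kind == "sphere":
        l = int(mode)
        with np.errstate(divide="ignore"):
            inv_r2 = np.where(r > 0, 1.0 / np.maximum(r, 1e-300) ** 2, 0.0)
        for i in range(n_b):
            j0 = blk(i)
            # interior rows: sigma w = D (w'' - l(l+1) w / r^2) - lam_i w
            rows = slice(j0 + 1, j0 + N)
            M[rows, j0:j0 + N + 1] = D * D2[1:N, :]
            idx = np.arange(j0 + 1, j0 + N)
            M[idx, idx] -= D * l * (l + 1) * inv_r2[1:N] + system.lam[i]
            B[j0 + 1:j0 + N] = 1.0
            # regularity at the center: w(0) = 0
            M[j0, j0] = 1.0
            # membrane flux: D (w'(R)/R - w(R)/R^2) = J_i ; c_s = w(R)/R
            row = j0 + N
            M[row, j0:j0 + N + 1] = (D / size) * Dr[N, :]
            M[row, row] -= D / size ** 2
            M[row, :3] -= system.F[i, :]
            for i2 in range(n_b):
                M[row, surf_cols[i2]] -= system.G[i, i2] / size
        # membrane coupling uses c_s = w(R)/R
        for i in range(n_b):
            M[:3, surf_cols[i]] += system.Gamma[:, i] / size
    else:
        k = float(mode)
        for i in range(n_b):
            j0 = blk(i)
            rows = slice(j0 + 1, j0 + N)
            M[rows, j0:j0 + N + 1] = D * D2[1:N, :]
            idx = np.arange(j0 + 1, j0 + N)
            M[idx, idx] -= D * k ** 2 + system.lam[i]
            B[j0 + 1:j0 + N] = 1.0
            # zero flux at the top, z = H
            M[j0, j0:j0 + N + 1] = Dr[0, :]
            # membrane flux at z = 0: -D c'(0) = J_i - D k^2 * 0 (flux into bulk)
            row = j0 + N
            M[row, j0:j0 + N + 1] = -D * Dr[N, :]
            M[row, :3] -= system.F[i, :]
            for i2 in range(n_b):
                M[row, surf_cols[i2]] -= system.G[i, i2]
        for i in range(n_b):
            M[:3, surf_cols[i]] += system.Gamma[:, i]

    ev = linalg.eig(M, np.diag(B), right=False)
    ev = ev[np.isfinite(ev)]
    ev = ev[np.lexsort((-ev.imag, -ev.real))]
    return DispersionResult(mode, ev, geometry)


def max_growth_rate(params: ModelParameters, geometry: Geometry, mode: float,
                    state: StationaryState | None = None,
                    n_cheb: int = 48) -> complex:
    """Dominant eigenvalue (largest real part) of one spatial mode."""
    res = full_eigenvalues(params, geometry, mode, state, n_cheb=n_cheb)
    return complex(res.sigma[0])


# ---------------------------------------------------------------------------
# scans

def _max_re_over_modes(params: ModelParameters, geometry: Geometry,
                       modes, n_cheb: int = 40) -> float:
    try:
        state = stationary_state(params, geometry)
    except RuntimeError:
        return math.nan
    return max(full_eigenvalues(params, geometry, m, state,
                                n_cheb=n_cheb).max_re for m in modes)


def critical_ce0(params: ModelParameters, geometry: Geometry,
                 modes=None, bracket=(0.0, 0.2), tol: float = 1e-4,
                 n_cheb: int = 40) -> float:
    """ce0 at which the most unstable wave mode becomes neutrally stable.

    On the sphere the wave mode is l=1; on the slab the growth rate is
    maximized over a wave-number grid.
    """
    if modes is None:
        modes = [1] if geometry.kind == "sphere" else list(
            np.linspace(0.1, 2.0, 20))

    def f(ce0: float) -> float:
        return _max_re_over_modes(params.replace(ce0=ce0), geometry, modes,
                                  n_cheb=n_cheb)

    a, b = bracket
    fa, fb = f(a), f(b)
    if not (fa > 0 > fb):
        raise RuntimeError(
            f"no sign change in bracket {bracket}: f(a)={fa}, f(b)={fb}")
    return float(optimize.brentq(f, a, b, xtol=tol))


def phase_diagram(params: ModelParameters, geometry: Geometry,
                  D0_values, eps0_values, modes=(0, 1),
                  n_cheb: int = 32):
    """Stability classification over a (D0, eps0) grid.

    Returns a DataFrame with one row per grid point and the max Re sigma and
    instability flag per mode.
    """
    import pandas as pd

    records = []
    for D0 in D0_values:
        for eps0 in eps0_values:
            p = params.replace(D0=D0, eps0=eps0)
            rec = {"D0": D0, "eps0": eps0}
            try:
                state = stationary_state(p, geometry)
            except RuntimeError:
                for m in modes:
                    rec[f"max_re_l{m}"] = math.nan
                    rec[f"unstable_l{m}"] = False
                records.append(rec)
                continue
            for m in modes:
                res = full_eigenvalues(p, geometry, m, state, n_cheb=n_cheb)
                mre = res.max_re_nontrivial if m == 0 else res.max_re
                rec[f"max_re_l{m}"] = mre
                rec[f"unstable_l{m}"] = mre > 0
            records.append(rec)
    return pd.DataFrame.from_records(records)


def boundary_bisect(params: ModelParameters, geometry: Geometry, mode,
                    scan: str, bracket: tuple[float, float],
                    fixed: dict | None = None, tol: float = 1e-3,
                    n_cheb: int = 32) -> float:
    """Bisect one parameter (``scan`` in {'D0','eps0','ce0'}) to the stability
    boundary of the given mode."""
    fixed = fixed or {}

    def f(v: float) -> float:
        p = params.replace(**{scan: v}, **fixed)
        state = stationary_state(p, geometry)
        res = full_eigenvalues(p, geometry, mode, state, n_cheb=n_cheb)
        return res.max_re_nontrivial if mode == 0 else res.max_re

    a, b = bracket
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise RuntimeError(f"no sign change for {scan} in {bracket}")
    return float(optimize.brentq(f, a, b, xtol=tol))


def dispersion_to_frame(results) -> "pd.DataFrame":  # noqa: F821
    """Flatten DispersionResults to a tidy table (CSV-ready)."""
    import pandas as pd

    rows = []
    for res in results:
        for s in res.sigma:
            rows.append({"mode": res.mode, "re_sigma": s.real,
                         "im_sigma": s.imag,
                         "geometry": res.geometry.kind,
                         "size": res.geometry.size,
                         "unstable": res.unstable})
    return pd.DataFrame.from_records(rows)
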