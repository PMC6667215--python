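"""Reaction kinetics, conservation laws and stationary states of Models I and II.

Both models track three membrane species -- MinD (``c_d``), the MinD-MinE
complex (``c_de``) and MinE (``c_e``) -- coupled to diffusing cytosolic pools
through boundary fluxes.  Model I has two bulk fields (MinD, MinE); Model II
splits cytosolic MinD into an ATP-bound, membrane-competent form and an
ADP-bound form that recovers at the nucleotide-exchange rate ``lam``.

Nondimensional unit system: time in units of the MinE detachment rate
(``omega_e`` = 1), length in units of sqrt(D_mem/omega_e) with the membrane
diffusion constant ``D_mem`` = 1.

Membrane kinetics (nondimensional)::

    dc_d/dt  = (omega_D + omega_dD c_d) * s * cA   - omega_E cE c_d - omega_ed c_e c_d
    dc_de/dt = omega_E cE c_d + omega_ed c_e c_d   - omega_e c_de
    dc_e/dt  = omega_e c_de + omega_e ce0 - omega_e c_e - omega_ed c_e c_d

where ``cA`` is the attachable cytosolic MinD at the membrane (Model I: the
single MinD pool; Model II: the ATP-bound pool), ``cE`` the cytosolic MinE at
the membrane, and ``s`` an optional saturation factor ``1 - c_d - c_de``.
MinE released by complex breakup stays on the membrane (persistent binding);
``ce0`` is a spontaneous MinE membrane-binding source chosen such that the
membrane MinE level relaxes to exactly ``ce0`` in the absence of MinD.
Every membrane gain is mirrored by a bulk boundary flux so mass is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize
from scipy.special import spherical_in

__all__ = [
    "ModelParameters",
    "Geometry",
    "StationaryState",
    "membrane_reaction_rates",
    "stationary_state",
    "find_stationary_states",
    "dimensionalize",
    "nondimensionalize",
    "cm_theory",
    "canonical_parameters",
    "load_parameters",
    "save_parameters",
    "stationary_states_to_csv",
]

MEMBRANE_SPECIES = ("d", "de", "e")


class ConfigurationError(ValueError):
    """Raised for inconsistent model configuration."""


@dataclass(frozen=True)
class ModelParameters:
    """Nondimensional parameter set for Model I or Model II.

    Attributes
    ----------
    omega_D : MinD membrane attachment rate (dimensional: length/time).
    omega_dD : cooperative MinD recruitment rate (dimensional: volume/time).
    omega_E : MinE recruitment rate onto membrane MinD (volume/time).
    omega_ed : persistent membrane-MinE + membrane-MinD binding rate (area/time).
    omega_e : MinE detachment rate; the unit of time (1 nondimensionally).
    D_bulk : cytosolic diffusion constant.
    D_mem : membrane diffusion constant (1 nondimensionally).
    ce0 : spontaneous MinE membrane-binding level (membrane MinE without MinD).
    lam : nucleotide-exchange rate ADP-MinD -> ATP-MinD (Model II only).
    D0 : total MinD concentration (bulk average + alpha * membrane).
    eps0 : total MinE concentration.
    model_variant : "I" or "II".
    saturation : if True, attachment carries the factor (1 - c_d - c_de).
    """

    omega_D: float = 0.1
    omega_dD: float = 5.0
    omega_E: float = 0.1
    omega_ed: float = 100.0
    omega_e: float = 1.0
    D_bulk: float = 100.0
    D_mem: float = 1.0
    ce0: float = 0.0
    lam: float = 1.0
    D0: float = 0.5
    eps0: float = 0.8
    model_variant: str = "II"
    saturation: bool = False

    def __post_init__(self) -> None:
        if self.model_variant not in ("I", "II"):
            raise ConfigurationError(
                f"unknown model_variant {self.model_variant!r}; expected 'I' or 'II'"
            )
        for name in ("omega_D", "omega_dD", "omega_E", "omega_ed", "omega_e",
                     "D_bulk", "D_mem", "ce0", "lam", "D0", "eps0"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def n_bulk(self) -> int:
        """Number of bulk fields (2 for Model I, 3 for Model II)."""
        return 2 if self.model_variant == "I" else 3

    @property
    def bulk_species(self) -> tuple[str, ...]:
        """Physical bulk species names."""
        return ("D", "E") if self.model_variant == "I" else ("DT", "DD", "E")

    @property
    def bulk_decay(self) -> np.ndarray:
        """Linear rates lambda_i of the decoupled (eigen) bulk fields.

        Model I: (c_D, c_E) -> (0, 0).
        Model II: the exchange couples c_DT and c_DD; the decoupled fields are
        (c_DT + c_DD, c_DD, c_E) with rates (0, lam, 0).
        """
        if self.model_variant == "I":
            return np.array([0.0, 0.0])
        return np.array([0.0, self.lam, 0.0])

    def bulk_to_eigen(self, fields: np.ndarray) -> np.ndarray:
        """Map physical bulk fields (first axis) to decoupled eigenfields."""
        if self.model_variant == "I":
            return np.asarray(fields).copy()
        out = np.array(fields, copy=True)
        out[0] = fields[0] + fields[1]
        return out

    def bulk_from_eigen(self, fields: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`bulk_to_eigen`."""
        if self.model_variant == "I":
            return np.asarray(fields).copy()
        out = np.array(fields, copy=True)
        out[0] = fields[0] - fields[1]
        return out

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Geometry:
    """Confining geometry: a closed sphere of radius R or a slab of height H.

    ``alpha`` converts a membrane areal concentration into an equivalent bulk
    concentration in the conservation law ``total = bulk_avg + alpha * mem``:
    surface area over volume, i.e. 3/R for the sphere and 1/H for the slab.
    """

    kind: str
    size: float

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "slab"):
            raise ConfigurationError(f"unknown geometry kind {self.kind!r}")
        if self.size <= 0:
            raise ConfigurationError("geometry size must be > 0")

    @property
    def alpha(self) -> float:
        return 3.0 / self.size if self.kind == "sphere" else 1.0 / self.size

    def bulk_factor_l0(self, xi: float) -> float:
        """Steady-profile boundary factor i_0(size/xi)/i_0'(size/xi) or coth."""
        x = self.size / xi
        if self.kind == "sphere":
            return float(spherical_in(0, x) / spherical_in(0, x, derivative=True))
        return 1.0 / math.tanh(x)


def membrane_reaction_rates(
    membrane: Sequence[np.ndarray] | np.ndarray,
    bulk_surface: Sequence[np.ndarray] | np.ndarray,
    params: ModelParameters,
    *,
    check: bool = False,
    negative_tol: float = 1e-9,
):
    """Local membrane reaction rates and matching bulk boundary fluxes.

    Parameters
    ----------
    membrane
        Membrane concentrations ``(c_d, c_de, c_e)``; scalars or arrays.
    bulk_surface
        Physical bulk concentrations adjacent to the membrane, ordered as
        ``params.bulk_species`` (Model I: ``(c_D, c_E)``; Model II:
        ``(c_DT, c_DD, c_E)``).
    check
        If True, raise on concentrations below ``-negative_tol``.

    Returns
    -------
    rates : ndarray, shape (3, ...)
        Time derivatives of ``(c_d, c_de, c_e)``.
    fluxes : ndarray, shape (n_bulk, ...)
        Boundary fluxes *into the bulk* per physical species; what leaves the
        bulk enters the membrane exactly.
    """
    cd, cde, ce = (np.asarray(x, dtype=float) for x in membrane)
    bulk_surface = [np.asarray(x, dtype=float) for x in bulk_surface]
    if len(bulk_surface) != params.n_bulk:
        raise ConfigurationError(
            f"Model {params.model_variant} expects {params.n_bulk} bulk fields, "
            f"got {len(bulk_surface)}"
        )
    if check:
        for arr in (cd, cde, ce, *bulk_surface):
            if np.any(arr < -negative_tol):
                raise ValueError("negative concentration beyond tolerance")

    if params.model_variant == "I":
        cA, cE = bulk_surface
    else:
        cA, cDD, cE = bulk_surface

    p = params
    s = (1.0 - cd - cde) if p.saturation else 1.0
    attach = (p.omega_D + p.omega_dD * cd) * s * cA
    recruit = p.omega_E * cE * cd
    rebind = p.omega_ed * ce * cd
    breakup = p.omega_e * cde
    detach = p.omega_e * ce
    spont = p.omega_e * p.ce0

    f_d = attach - recruit - rebind
    f_de = recruit + rebind - breakup
    f_e = breakup + spont - detach - rebind

    # MinE released by complex breakup stays on the membrane; the bulk only
    # exchanges MinE through detachment, recruitment and the spontaneous term.
    flux_E = detach - recruit - spont
    if p.model_variant == "I":
        fluxes = np.stack([np.broadcast_to(breakup - attach, f_d.shape).astype(float),
                           np.broadcast_to(flux_E, f_d.shape).astype(float)])
    else:
        fluxes = np.stack([np.broadcast_to(-attach, f_d.shape).astype(float),
                           np.broadcast_to(breakup, f_d.shape).astype(float),
                           np.broadcast_to(flux_E, f_d.shape).astype(float)])
    return np.stack([f_d, f_de, f_e]), fluxes


@dataclass(frozen=True)
class StationaryState:
    """Homogeneous stationary state on a given geometry.

    ``bulk_surface`` holds physical bulk values at the membrane;
    ``bulk_mean`` holds the volume-averaged values (they differ for the
    decaying ADP-MinD profile of Model II).
    """

    cd: float
    cde: float
    ce: float
    bulk_surface: tuple[float, ...]
    bulk_mean: tuple[float, ...]
    residual: float
    geometry: Geometry
    multiple: bool = False

    @property
    def membrane(self) -> np.ndarray:
        return np.array([self.cd, self.cde, self.ce])

    def cm_measured(self, which: str = "E") -> float:
        """Cytosol/membrane partition index at the fixed point.

        For MinE: bulk-average MinE divided by total membrane MinE
        (``c_de + c_e``); for MinD: bulk MinD over ``c_d + c_de``.
        """
        if which == "E":
            mem = self.cde + self.ce
            bulk = self.bulk_mean[-1]
        elif which == "D":
            mem = self.cd + self.cde
            bulk = sum(self.bulk_mean[:-1])
        else:
            raise ValueError("which must be 'D' or 'E'")
        if mem == 0:
            return math.inf
        return bulk / mem


def _stationary_residual(x: np.ndarray, params: ModelParameters,
                         geometry: Geometry) -> np.ndarray:
    cd, cde, ce = x
    surf = _stationary_bulk_surface(cd, cde, ce, params, geometry)
    rates, _ = membrane_reaction_rates((cd, cde, ce), surf, params)
    return rates


def _stationary_bulk_surface(cd, cde, ce, params: ModelParameters,
                             geometry: Geometry) -> list[float]:
    """Closed-form bulk surface values for a homogeneous stationary membrane.

    At stationarity the net boundary flux of every conserved pool vanishes, so
    the non-decaying eigenfields are spatially uniform and fixed by mass
    conservation; the ADP-MinD field of Model II has the steady decaying
    profile with boundary factor i_0/i_0' (sphere) or coth (slab).
    """
    p, alpha = params, geometry.alpha
    cE = p.eps0 - alpha * (cde + ce)
    if p.model_variant == "I":
        cD = p.D0 - alpha * (cd + cde)
        return [cD, cE]
    u = p.D0 - alpha * (cd + cde)  # c_DT + c_DD, uniform
    if p.lam == 0:
        raise ConfigurationError("Model II requires lam > 0 for a stationary state")
    xi = math.sqrt(p.D_bulk / p.lam)
    cDD_s = p.omega_e * cde * (xi / p.D_bulk) * geometry.bulk_factor_l0(xi)
    return [u - cDD_s, cDD_s, cE]


_DEFAULT_STARTS = (
    (0.01, 0.05, 0.05),
    (0.3, 0.3, 0.1),
    (1.0, 0.0, 0.0),
    (0.0, 0.0, 0.0),
)


def find_stationary_states(
    params: ModelParameters,
    geometry: Geometry,
    starts: Sequence[Sequence[float]] | None = None,
    tol: float = 1e-12,
) -> list[StationaryState]:
    """Locate all nonnegative homogeneous fixed points reachable from ``starts``."""
    alpha = geometry.alpha
    if starts is None:
        scale_d = params.D0 / alpha
        scale_e = params.eps0 / alpha
        starts = list(_DEFAULT_STARTS) + [
            (params.ce0 * 0.1, min(scale_e, 0.2), max(params.ce0, 1e-3)),
            (min(scale_d, 1.0), 0.0, max(params.ce0, 0.0)),
        ]
    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = optimize.root(_stationary_residual, np.asarray(x0, dtype=float),
                            args=(params, geometry), method="hybr",
                            options={"xtol": 1e-14})
        x = sol.x
        res = np.max(np.abs(_stationary_residual(x, params, geometry)))
        if res > 1e-10 or np.any(x < -1e-9):
            continue
        surf = _stationary_bulk_surface(*x, params, geometry)
        if any(v < -1e-9 for v in surf):
            continue
        if not any(np.allclose(x, r, atol=1e-8) for r in roots):
            roots.append(np.clip(x, 0.0, None))
    states = []
    for x in roots:
        surf = _stationary_bulk_surface(*x, params, geometry)
        mean = _stationary_bulk_mean(x, params, geometry)
        res = float(np.max(np.abs(_stationary_residual(x, params, geometry))))
        states.append(StationaryState(*map(float, x), tuple(surf), tuple(mean),
                                      res, geometry, multiple=len(roots) > 1))
    states.sort(key=lambda s: -s.cd)
    return states


def _stationary_bulk_mean(x, params: ModelParameters, geometry: Geometry):
    cd, cde, ce = x
    alpha = geometry.alpha
    cE = params.eps0 - alpha * (cde + ce)
    if params.model_variant == "I":
        return [params.D0 - alpha * (cd + cde), cE]
    u = params.D0 - alpha * (cd + cde)
    # stationary balance: lam * <c_DD> * V = breakup flux * A
    cDD_mean = alpha * params.omega_e * cde / params.lam
    return [u - cDD_mean, cDD_mean, cE]


def stationary_state(params: ModelParameters, geometry: Geometry,
                     **kwargs) -> StationaryState:
    """The physically relevant homogeneous fixed point.

    Raises ``RuntimeError`` when no nonnegative root is found.  If several
    roots exist the one with the largest membrane MinD is returned with its
    ``multiple`` flag set.
    """
    states = find_stationary_states(params, geometry, **kwargs)
    if not states:
        raise RuntimeError(
            "no nonnegative stationary state found for "
            f"model {params.model_variant} on {geometry.kind} "
            f"(D0={params.D0}, eps0={params.eps0}, ce0={params.ce0})"
        )
    if len(states) == 1:
        return states[0]
    # prefer an interior fixed point over the trivial MinE-free branch
    interior = [s for s in states if s.ce > 1e-12 or params.eps0 == 0]
    return interior[0] if interior else states[0]


# ---------------------------------------------------------------------------
# unit conversion

_RATE_FIELDS = ("omega_D", "omega_dD", "omega_E", "omega_ed", "omega_e",
                "D_bulk", "D_mem", "ce0", "lam", "D0", "eps0")


def dimensionalize(params: ModelParameters, omega_e_dim: float, Dd_dim: float,
                   conc_bulk_unit: float, conc_mem_unit: float) -> dict:
    """Convert the nondimensional parameter set to dimensional rates.

    ``omega_e_dim`` [1/s] and ``Dd_dim`` [area/s] fix the time and length
    units; ``conc_bulk_unit`` [1/volume] and ``conc_mem_unit`` [1/area] fix
    the concentration scales in the cytosol and on the membrane.
    """
    for name, v in (("omega_e_dim", omega_e_dim), ("Dd_dim", Dd_dim),
                    ("conc_bulk_unit", conc_bulk_unit),
                    ("conc_mem_unit", conc_mem_unit)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    cb, cs = conc_bulk_unit, conc_mem_unit
    we = omega_e_dim
    return {
        "omega_D": params.omega_D * we * cs / cb,     # length/time
        "omega_dD": params.omega_dD * we / cb,        # volume/time
        "omega_E": params.omega_E * we / cb,          # volume/time
        "omega_ed": params.omega_ed * we / cs,        # area/time
        "omega_e": params.omega_e * we,               # 1/time
        "D_bulk": params.D_bulk * Dd_dim,             # area/time
        "D_mem": params.D_mem * Dd_dim,               # area/time
        "ce0": params.ce0 * cs,                       # 1/area
        "lam": params.lam * we,                       # 1/time
        "D0": params.D0 * cb,                         # 1/volume
        "eps0": params.eps0 * cb,                     # 1/volume
        "length_unit": math.sqrt(Dd_dim / we),        # length
    }


def nondimensionalize(dim: dict, omega_e_dim: float, Dd_dim: float,
                      conc_bulk_unit: float, conc_mem_unit: float,
                      model_variant: str = "II",
                      saturation: bool = False) -> ModelParameters:
    """Inverse of :func:`dimensionalize` (round-trips to machine precision)."""
    cb, cs, we = conc_bulk_unit, conc_mem_unit, omega_e_dim
    return ModelParameters(
        omega_D=dim["omega_D"] * cb / (we * cs),
        omega_dD=dim["omega_dD"] * cb / we,
        omega_E=dim["omega_E"] * cb / we,
        omega_ed=dim["omega_ed"] * cs / we,
        omega_e=dim["omega_e"] / we,
        D_bulk=dim["D_bulk"] / Dd_dim,
        D_mem=dim["D_mem"] / Dd_dim,
        ce0=dim["ce0"] / cs,
        lam=dim["lam"] / we,
        D0=dim["D0"] / cb,
        eps0=dim["eps0"] / cb,
        model_variant=model_variant,
        saturation=saturation,
    )


def cm_theory(total: float, alpha: float, ce0: float) -> float:
    """Cytosol/membrane localization index ``(total - alpha*ce0) / ce0``.

    ``total`` is the caller-supplied total concentration: with the total MinE
    this is the physically motivated MinE partition ratio; passing total MinD
    reproduces the published formula literally.  Returns ``inf`` for
    ``ce0 == 0`` (nothing on the membrane).
    """
    if ce0 < 0:
        raise ValueError("ce0 must be >= 0")
    if ce0 == 0:
        return math.inf
    return (total - alpha * ce0) / ce0


# ---------------------------------------------------------------------------
# parameter-file round trip

def save_parameters(params: ModelParameters, path) -> None:
    data = {name: getattr(params, name) for name in _RATE_FIELDS}
    data["model_variant"] = params.model_variant
    data["saturation"] = params.saturation
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_parameters(path) -> ModelParameters:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ModelParameters(**data)


def canonical_parameters(**overrides) -> ModelParameters:
    """The bundled canonical rate set (omega_D=0.1, omega_dD=5, omega_E=0.1,
    D=100, omega_ed=100, omega_e=1)."""
    ref = resources.files("minwaves").joinpath("data/canonical.yaml")
    with resources.as_file(ref) as path:
        params = load_parameters(path)
    return params.replace(**overrides) if overrides else params


def stationary_states_to_csv(rows, path) -> None:
    """Export (params, state) pairs as CSV rows."""
    import pandas as pd

    records = []
    for params, state in rows:
        rec = {name: getattr(params, name) for name in _RATE_FIELDS}
        rec.update(model_variant=params.model_variant,
                   saturation=params.saturation,
                   geometry=state.geometry.kind, size=state.geometry.size,
                   cd=state.cd, cde=state.cde, ce=state.ce,
                   residual=state.residual)
        for name, v in zip(params.bulk_species, state.bulk_surface):
            rec[f"c{name}_surface"] = v
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)
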