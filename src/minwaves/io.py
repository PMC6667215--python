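"""HDF5 trajectory containers.

Layout (sphere): ``/time``, ``/totals``, ``/membrane/{d,de,e}/coeffs[t,l,m]``
(complex spherical-harmonic coefficients, m >= 0).  Planar runs store real
membrane grids under ``/membrane/{species}/grid[t,x(,y)]``.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from minwaves.models import Geometry, ModelParameters

__all__ = [
    "save_sphere_trajectory",
    "load_sphere_trajectory",
    "save_planar_trajectory",
    "load_planar_trajectory",
]

_SPECIES = ("d", "de", "e")


def _params_json(params: ModelParameters) -> str:
    from dataclasses import asdict

    return json.dumps(asdict(params))


def _params_from_json(s: str) -> ModelParameters:
    return ModelParameters(**json.loads(s))


def save_sphere_trajectory(traj, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=traj.t)
        fh.create_dataset("totals", data=traj.totals)
        grp = fh.create_group("membrane")
        for i, name in enumerate(_SPECIES):
            grp.create_dataset(f"{name}/coeffs", data=traj.mem_coeffs[:, i])
        fh.attrs["params"] = _params_json(traj.params)
        fh.attrs["geometry_kind"] = traj.geometry.kind
        fh.attrs["geometry_size"] = traj.geometry.size
        fh.attrs["lmax"] = traj.lmax
        fh.attrs["blew_up"] = traj.blew_up


def load_sphere_trajectory(path):
    from minwaves.sphere_sim import SphereTrajectory

    with h5py.File(path, "r") as fh:
        t = fh["time"][:]
        totals = fh["totals"][:]
        coeffs = np.stack([fh[f"membrane/{n}/coeffs"][:] for n in _SPECIES],
                          axis=1)
        return SphereTrajectory(
            t, coeffs, totals, _params_from_json(fh.attrs["params"]),
            Geometry(fh.attrs["geometry_kind"], float(fh.attrs["geometry_size"])),
            int(fh.attrs["lmax"]), blew_up=bool(fh.attrs["blew_up"]))


def save_planar_trajectory(traj, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=traj.t)
        fh.create_dataset("totals", data=traj.totals)
        grp = fh.create_group("membrane")
        for i, name in enumerate(_SPECIES):
            grp.create_dataset(f"{name}/grid", data=traj.mem[:, i])
        fh.attrs["params"] = _params_json(traj.params)
        fh.attrs["height"] = traj.height
        fh.attrs["lengths"] = list(traj.lengths)
        fh.attrs["blew_up"] = traj.blew_up


def load_planar_trajectory(path):
    from minwaves.plane_sim import PlanarTrajectory

    with h5py.File(path, "r") as fh:
        t = fh["time"][:]
        totals = fh["totals"][:]
        mem = np.stack([fh[f"membrane/{n}/grid"][:] for n in _SPECIES], axis=1)
        return PlanarTrajectory(
            t, mem, totals, _params_from_json(fh.attrs["params"]),
            float(fh.attrs["height"]), tuple(fh.attrs["lengths"]),
            blew_up=bool(fh.attrs["blew_up"]))
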