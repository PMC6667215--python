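"""Conservative finite-volume discretization of the bulk along r (sphere) or z (slab).

Cells are clustered towards the membrane (r = R, respectively z = 0) because
decaying bulk profiles form boundary layers there.  The discrete diffusion
operator conserves mass exactly under zero-flux boundaries; the membrane
exchange flux is deposited into the membrane-adjacent cell.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg

__all__ = ["BulkGrid"]


def _clustered_faces(size: float, n: int, beta: float) -> np.ndarray:
    """Faces on [0, size], clustered near ``size`` (sinh stretching)."""
    s = np.linspace(0.0, 1.0, n + 1)
    if beta == 0:
        return size * s
    return size * (1.0 - np.sinh(beta * (1.0 - s)) / math.sinh(beta))


class BulkGrid:
    """1D bulk grid for a sphere interior (coordinate r) or slab (coordinate z).

    For the slab the stored coordinate is the distance from the membrane, so
    in both cases the membrane sits at coordinate ``size`` and the grid is
    clustered there; the membrane-adjacent cell is the last one.
    """

    def __init__(self, kind: str, size: float, n_cells: int = 64,
                 beta: float = 2.0):
        if kind not in ("sphere", "slab"):
            raise ValueError(f"unknown bulk kind {kind!r}")
        self.kind = kind
        self.size = float(size)
        self.n = int(n_cells)
        self.faces = _clustered_faces(self.size, self.n, beta)
        self.centers = 0.5 * (self.faces[1:] + self.faces[:-1])
        if kind == "sphere":
            self.face_area = self.faces ** 2              # per steradian
            self.volumes = np.diff(self.faces ** 3) / 3.0
        else:
            self.face_area = np.ones(self.n + 1)
            self.volumes = np.diff(self.faces)
        self.total_volume = float(self.volumes.sum())
        self.membrane_area = float(self.face_area[-1])
        # linear extrapolation of the two membrane-adjacent cell centers to
        # the membrane face
        x1, x2 = self.centers[-1], self.centers[-2]
        t = (self.size - x1) / (x1 - x2)
        self._extrap = (1.0 + t, -t)

    # -- operators ---------------------------------------------------------

    def laplacian(self, D: float, mode_l: int | None = None) -> np.ndarray:
        """Dense matrix of the FV diffusion operator (zero-flux boundaries).

        For the sphere a degree-l angular term ``-D l(l+1)/r^2`` is included;
        the slab handles in-plane wave numbers analytically outside.
        """
        n = self.n
        L = np.zeros((n, n))
        h = np.diff(self.centers)
        for j in range(n - 1):
            w = D * self.face_area[j + 1] / h[j]
            L[j, j] -= w / self.volumes[j]
            L[j, j + 1] += w / self.volumes[j]
            L[j + 1, j + 1] -= w / self.volumes[j + 1]
            L[j + 1, j] += w / self.volumes[j + 1]
        if self.kind == "sphere" and mode_l:
            L[np.diag_indices(n)] -= D * mode_l * (mode_l + 1) / self.centers ** 2
        return L

    def crank_nicolson_factors(self, D: float, dt: float,
                               mode_l: int | None = None):
        """LU factors of (I - dt/2 L) and the matrix (I + dt/2 L)."""
        L = self.laplacian(D, mode_l)
        eye = np.eye(self.n)
        lu = linalg.lu_factor(eye - 0.5 * dt * L)
        return lu, eye + 0.5 * dt * L

    # -- field helpers -----------------------------------------------------

    def surface_value(self, field: np.ndarray, axis: int = -1) -> np.ndarray:
        """Extrapolated value at the membrane face.

        ``axis`` selects the cell axis of ``field``.
        """
        a, b = self._extrap
        f = np.moveaxis(field, axis, -1)
        return a * f[..., -1] + b * f[..., -2]

    def deposit(self, field_deriv: np.ndarray, flux: np.ndarray,
                axis: int = -1) -> None:
        """Add a membrane boundary flux (per unit area, into the bulk) to the
        time derivative of the membrane-adjacent cell, in place."""
        f = np.moveaxis(field_deriv, axis, -1)
        f[..., -1] += flux * (self.membrane_area / self.volumes[-1])

    def mean(self, field: np.ndarray, axis: int = -1) -> np.ndarray:
        """Volume average over the bulk."""
        f = np.moveaxis(field, axis, -1)
        return (f * self.volumes).sum(axis=-1) / self.total_volume

    @property
    def alpha(self) -> float:
        """Membrane area per bulk volume."""
        return self.membrane_area / self.total_volume

    def stationary_profile(self, boundary_flux: float, D: float,
                           lam: float) -> np.ndarray:
        """Steady profile of a decaying field fed by a constant membrane flux.

        Solves ``D lap c = lam c`` with the given influx at the membrane,
        evaluated at cell centers (sphere: a i_0(r/xi); slab: a cosh(z'/xi)).
        """
        if lam <= 0:
            raise ValueError("stationary decaying profile needs lam > 0")
        from scipy.special import spherical_in

        xi = math.sqrt(D / lam)
        if self.kind == "sphere":
            a = boundary_flux * xi / (D * spherical_in(0, self.size / xi,
                                                       derivative=True))
            return a * spherical_in(0, self.centers / xi)
        a = boundary_flux * xi / (D * math.sinh(self.size / xi))
        return a * np.cosh(self.centers / xi)
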