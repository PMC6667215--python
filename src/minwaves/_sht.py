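"""Scalar spherical-harmonic transforms on a Gauss-Legendre x equiangular grid.

Orthonormal complex basis Y_lm with Condon-Shortley phase; real fields are
stored through their m >= 0 coefficients (c_{l,-m} = (-1)^m conj(c_{lm})).
Grid sizes default to 3*lmax/2-type dealiasing for quadratic nonlinearities.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SphericalHarmonics"]


def _legendre_tables(lmax: int, mu: np.ndarray) -> list[np.ndarray]:
    """Fully normalized associated Legendre functions Pbar_lm(mu).

    Returns a list over m of arrays with shape (n_nodes, lmax + 1 - m) holding
    Pbar_lm for l = m..lmax, computed with the standard stable recurrences.
    Normalization: int_{-1}^{1} Pbar_lm Pbar_l'm dmu = 1/(2 pi) delta_{ll'},
    so that Y_lm = Pbar_lm(mu) e^{i m phi} is orthonormal on the sphere.
    """
    n = mu.size
    sint = np.sqrt(np.clip(1.0 - mu ** 2, 0.0, None))
    tables = []
    pmm = np.full(n, math.sqrt(1.0 / (4.0 * math.pi)))
    for m in range(lmax + 1):
        cols = np.empty((n, lmax + 1 - m))
        cols[:, 0] = pmm
        if m + 1 <= lmax:
            cols[:, 1] = mu * math.sqrt(2 * m + 3) * pmm
        for l in range(m + 2, lmax + 1):
            a = math.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b = math.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
            cols[:, l - m] = a * (mu * cols[:, l - m - 1] - b * cols[:, l - m - 2])
        tables.append(cols)
        # seed for next m: Pbar_{m+1,m+1}
        pmm = -math.sqrt((2.0 * m + 3.0) / (2.0 * m + 2.0)) * sint * pmm
    return tables


class SphericalHarmonics:
    """Forward/backward transforms between grid fields and (l, m) coefficients.

    Coefficients are stored in a dense (lmax+1, lmax+1) complex array ``c``
    with ``c[l, m]`` for m <= l and zeros above the diagonal.
    """

    def __init__(self, lmax: int, n_theta: int | None = None,
                 n_phi: int | None = None):
        if lmax < 0:
            raise ValueError("lmax must be >= 0")
        self.lmax = lmax
        self.n_theta = n_theta or (3 * lmax) // 2 + 2
        self.n_phi = n_phi or max(8, 2 ** math.ceil(math.log2(3 * lmax + 1)))
        if self.n_theta < lmax + 1:
            raise ValueError("n_theta must be at least lmax + 1")
        if self.n_phi < 2 * lmax + 1:
            raise ValueError("n_phi must be at least 2*lmax + 1")
        mu, w = np.polynomial.legendre.leggauss(self.n_theta)
        order = np.argsort(-mu)              # theta increasing from the pole
        self.mu, self.weights = mu[order], w[order]
        self.theta = np.arccos(self.mu)
        self.phi = 2.0 * np.pi * np.arange(self.n_phi) / self.n_phi
        self._P = _legendre_tables(lmax, self.mu)
        # quadrature-weighted tables for analysis
        self._Pw = [2.0 * np.pi * p * self.weights[:, None] for p in self._P]

    # -- transforms --------------------------------------------------------

    def zeros(self) -> np.ndarray:
        return np.zeros((self.lmax + 1, self.lmax + 1), dtype=complex)

    def analyze(self, field: np.ndarray) -> np.ndarray:
        """Grid (..., n_theta, n_phi) real field -> coefficients (..., l, m)."""
        field = np.asarray(field)
        fm = np.fft.rfft(field, axis=-1) / self.n_phi
        out = np.zeros(field.shape[:-2] + (self.lmax + 1, self.lmax + 1),
                       dtype=complex)
        for m in range(self.lmax + 1):
            # c_lm = sum_j 2 pi w_j Pbar_lm(mu_j) <f e^{-im phi}>_phi
            out[..., m:, m] = np.einsum("...j,jl->...l", fm[..., m],
                                        self._Pw[m])
        return out

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """Coefficients (..., l, m) -> real grid field (..., n_theta, n_phi)."""
        coeffs = np.asarray(coeffs)
        shape = coeffs.shape[:-2] + (self.n_theta, self.n_phi // 2 + 1)
        fm = np.zeros(shape, dtype=complex)
        nm = min(self.lmax, self.n_phi // 2)
        for m in range(nm + 1):
            fm[..., m] = np.einsum("...l,jl->...j", coeffs[..., m:, m],
                                   self._P[m])
        return np.fft.irfft(fm * self.n_phi, n=self.n_phi, axis=-1)

    # -- helpers -----------------------------------------------------------

    def uniform(self, value: float) -> np.ndarray:
        """Coefficients of a spatially uniform field."""
        c = self.zeros()
        c[0, 0] = value * math.sqrt(4.0 * math.pi)
        return c

    def mean(self, coeffs: np.ndarray) -> float:
        """Spherical average of the field."""
        return float(np.real(coeffs[..., 0, 0]) / math.sqrt(4.0 * math.pi))

    def mode_norms(self, coeffs: np.ndarray) -> np.ndarray:
        """Rotationally invariant norm per degree l: sqrt(sum_m |c_lm|^2)."""
        c2 = np.abs(coeffs) ** 2
        # m>0 entries count twice (conjugate partners)
        mult = np.ones(self.lmax + 1)
        total = c2[..., 0] + 2.0 * (c2[..., 1:] @ mult[1:])
        return np.sqrt(total)

    def sample_circle(self, coeffs: np.ndarray, n_points: int = 128,
                      colatitude: float = np.pi / 2) -> np.ndarray:
        """Field values along a circle of constant colatitude (default equator)."""
        mu = np.array([math.cos(colatitude)])
        tables = _legendre_tables(self.lmax, mu)
        phi = 2.0 * np.pi * np.arange(n_points) / n_points
        vals = np.zeros(coeffs.shape[:-2] + (n_points,), dtype=float)
        for m in range(self.lmax + 1):
            amp = np.einsum("...l,jl->...j", coeffs[..., m:, m],
                            tables[m])[..., 0]
            wave = np.exp(1j * m * phi)
            contrib = amp[..., None] * wave
            vals += np.real(contrib) if m == 0 else 2.0 * np.real(contrib)
        return vals
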