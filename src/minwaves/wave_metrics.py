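"""Quantification and classification of simulated membrane patterns.

Works on spherical trajectories (per-degree rotationally invariant mode
norms) and planar trajectories (per-wave-number amplitudes).  The pattern
classifier follows declared conventions, since the underlying phenomenology
(pulsing, pole-to-pole, traveling wave) is visual in origin:

* ``pulsing`` -- the uniform mode (l = 0) oscillates while inhomogeneous
  norms stay below 10% of that oscillation amplitude;
* ``pole-to-pole`` -- the l = 1 norm oscillates deeply (standing pattern, the
  norm dips towards zero each half period);
* ``traveling`` -- the l = 1 norm is roughly constant while the pattern
  phase advances monotonically (rotating wave);
* ``stationary`` -- nothing changes;
* ``homogeneous-oscillation`` -- the pulsing signature persists to the end of
  the trajectory.

All thresholds are configurable keyword arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from minwaves._sht import SphericalHarmonics

__all__ = [
    "ModeAmplitudeSeries",
    "Kymograph",
    "mode_amplitude_series",
    "wave_amplitude",
    "classify_windows",
    "classify_pattern",
    "make_kymograph",
]


@dataclass
class ModeAmplitudeSeries:
    """Time series of rotationally invariant mode norms (one column per l)."""

    t: np.ndarray
    norms: np.ndarray           # (n_frames, lmax+1)
    phase: np.ndarray           # phase of the l=1 pattern (rad)
    direction: np.ndarray | None = None   # (n_frames, 3) l=1 vector

    def norm(self, l: int) -> np.ndarray:
        return self.norms[:, l]

    def planarity(self, sel=slice(None)) -> float:
        """Rank-2-ness of the l=1 direction trajectory, in [0, 1].

        A standing pattern keeps a fixed axis (linear polarization, ~0); a
        rotating pattern sweeps a plane (circular polarization, ~1).
        Computed as the ratio of the two largest eigenvalues of the
        second-moment matrix of the direction vector.
        """
        if self.direction is None:
            return 0.0
        a = self.direction[sel]
        if len(a) < 4 or np.abs(a).max() < 1e-300:
            return 0.0
        m = a.T @ a / len(a)
        ev = np.sort(np.linalg.eigvalsh(m))
        return float(ev[1] / ev[2]) if ev[2] > 0 else 0.0


def mode_amplitude_series(traj, species: int = 0) -> ModeAmplitudeSeries:
    """Extract mode norms, l=1 pattern phase and direction vector from a
    sphere trajectory."""
    sht = traj.sht()
    coeffs = traj.mem_coeffs[:, species]
    norms = sht.mode_norms(coeffs)
    c11 = coeffs[:, 1, 1]
    c10 = coeffs[:, 1, 0].real
    # pattern phase: azimuthal angle of the l=1 direction vector; for a
    # z-axis-aligned pattern (c11 ~ 0) fall back to the sign of c10
    phase = np.where(np.abs(c11) > 1e-12, np.angle(c11),
                     np.where(c10 >= 0, 0.0, math.pi))
    # real 3-vector representation of the l=1 pattern direction
    direction = np.stack([-math.sqrt(2.0) * c11.real,
                          math.sqrt(2.0) * c11.imag,
                          c10], axis=1)
    return ModeAmplitudeSeries(traj.t.copy(), norms, phase, direction)


def wave_amplitude(traj, reference=None, species: int = 0,
                   window: float = 0.25) -> float:
    """Late-window steady wave amplitude, optionally normalized.

    Sphere trajectories: time-averaged l = 1 mode norm over the final
    ``window`` fraction of the run.  Planar trajectories: the maximum
    amplitude over finite wave numbers.  When ``reference`` (a trajectory run
    without spontaneous MinE binding) is given, the amplitude is divided by
    the reference amplitude.
    """
    amp = _late_amplitude(traj, species, window)
    if reference is None:
        return amp
    ref = _late_amplitude(reference, species, window)
    if ref <= 1e-12:
        raise ZeroDivisionError(
            "reference trajectory has (near-)zero wave amplitude; "
            "normalization undefined")
    return amp / ref


def _late_amplitude(traj, species: int, window: float) -> float:
    n = len(traj.t)
    sel = slice(int(n * (1.0 - window)), n)
    if hasattr(traj, "mem_coeffs"):            # sphere
        series = mode_amplitude_series(traj, species)
        return float(series.norm(1)[sel].mean())
    amps = traj.amplitudes(species)            # planar, (frames, k)
    return float(amps[sel, 1:].max(axis=1).mean())


# ---------------------------------------------------------------------------
# classification

def classify_windows(series: ModeAmplitudeSeries, n_windows: int = 6,
                     pulse_ratio: float = 0.1, standing_ratio: float = 0.35,
                     travel_osc: float = 0.5, quiet_tol: float = 1e-4,
                     min_frames_per_period: int = 16) -> list[str]:
    """Label each time window of a mode-amplitude series."""
    labels = []
    n = len(series.t)
    edges = np.linspace(0, n, n_windows + 1).astype(int)
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 4:
            labels.append("indeterminate")
            continue
        labels.append(_label_window(series, a, b, pulse_ratio, standing_ratio,
                                    travel_osc, quiet_tol))
    return labels


def _label_window(series, a, b, pulse_ratio, standing_ratio, travel_osc,
                  quiet_tol) -> str:
    n0 = series.norms[a:b, 0]
    n1 = series.norms[a:b, 1]
    osc0 = n0.max() - n0.min()
    n1_mean = n1.mean()
    if osc0 < quiet_tol and (n1.max() - n1.min()) < quiet_tol \
            and n1_mean < quiet_tol:
        return "stationary"
    if n1_mean < pulse_ratio * max(osc0, quiet_tol):
        return "pulsing" if osc0 >= quiet_tol else "stationary"
    planarity = series.planarity(slice(a, b))
    if planarity >= 0.5:
        # the pattern direction sweeps a plane: rotating wave
        return "traveling"
    ratio = n1.min() / max(n1.max(), 1e-300)
    if ratio < standing_ratio:
        return "pole-to-pole"
    rel_osc = (n1.max() - n1.min()) / max(n1_mean, 1e-300)
    phase = np.unwrap(series.phase[a:b])
    advance = abs(phase[-1] - phase[0])
    if rel_osc < travel_osc and advance > 0.1:
        return "traveling"
    if rel_osc < travel_osc:
        # constant-norm, non-advancing inhomogeneous pattern
        return "traveling" if advance > 0.01 else "stationary"
    return "indeterminate"


@dataclass
class PatternClassification:
    label: str
    window_labels: list[str]
    transitions: list[str] = field(default_factory=list)


def classify_pattern(traj, species: int = 0, n_windows: int = 8,
                     **kwargs) -> PatternClassification:
    """Classify a sphere trajectory and report its transition sequence.

    The overall label is the final window's; a pulsing signature that
    persists into the final window is reported as homogeneous-oscillation.
    """
    series = mode_amplitude_series(traj, species)
    labels = classify_windows(series, n_windows=n_windows, **kwargs)
    transitions = [labels[0]]
    for lab in labels[1:]:
        if lab != transitions[-1]:
            transitions.append(lab)
    final = labels[-1]
    if final == "pulsing" and labels.count("pulsing") > len(labels) // 2:
        final = "homogeneous-oscillation"
    return PatternClassification(final, labels, transitions)


# ---------------------------------------------------------------------------
# kymographs

@dataclass
class Kymograph:
    """Intensity(time, arclength) along a periodic membrane circumference."""

    t: np.ndarray
    arclength: np.ndarray
    intensity: np.ndarray       # (n_frames, n_points)
    species: str = "d"

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.intensity, index=self.t, columns=self.arclength)
        df.index.name = "time"
        df.to_csv(path)

    def to_png(self, path, cmap: str = "viridis") -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.imshow(self.intensity.T, aspect="auto", origin="lower",
                  extent=(self.t[0], self.t[-1], self.arclength[0],
                          self.arclength[-1]), cmap=cmap)
        ax.set_xlabel("time")
        ax.set_ylabel("arclength")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def make_kymograph(traj, species: int = 0, n_points: int = 128,
                   colatitude: float = math.pi / 2) -> Kymograph:
    """Sample a trajectory along a membrane circumference.

    Sphere trajectories are sampled on a circle of constant colatitude
    (default the equator); 1D planar trajectories use the membrane line
    directly.
    """
    name = ("d", "de", "e")[species]
    if hasattr(traj, "mem_coeffs"):
        sht = traj.sht()
        intensity = sht.sample_circle(traj.mem_coeffs[:, species],
                                      n_points=n_points,
                                      colatitude=colatitude)
        radius = traj.geometry.size * math.sin(colatitude)
        s = radius * 2.0 * np.pi * np.arange(n_points) / n_points
        return Kymograph(traj.t.copy(), s, intensity, name)
    if traj.mem.ndim != 3:
        raise ValueError("kymographs need a sphere or 1D planar trajectory")
    s = traj.lengths[0] * np.arange(traj.mem.shape[-1]) / traj.mem.shape[-1]
    return Kymograph(traj.t.copy(), s, traj.mem[:, species].copy(), name)
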