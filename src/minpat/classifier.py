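"""Classification of membrane-density windows into oscillation pattern labels.

A window is a membrane MinD density sampled over at least two oscillation
cycles on the cell boundary. The classifier extracts the oscillation axis
from the spatial dipole of the temporal Fourier component at the dominant
frequency, counts alternating membrane domains along that axis, estimates
the period, and maps the result onto the pattern vocabulary of shaped-cell
Min oscillations: longitudinal pole-to-pole, longitudinal striped,
transverse pole-to-pole, homogeneous, or other.

Angle convention: angles are reported against the horizontal with the
cell's long axis drawn vertically, folded to [0, 90]. An oscillation along
the long axis is 90 deg, along the short axis 0 deg; the
longitudinal/transverse decision boundary sits at 45 deg.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "PatternLabel",
    "MembraneWindow",
    "window_from_trajectory",
    "oscillation_axis",
    "count_nodes",
    "classify_window",
    "period_estimate",
    "label_timeline",
    "fold_angle",
]

HOMOGENEOUS_CV = 0.1  # spatial coefficient-of-variation threshold
PEAK_OVER_MEDIAN = 3.0  # spectral dominance required to call an oscillation


def fold_angle(angle_deg: float) -> float:
    """Fold an angle to [0, 90] using the rectangle's multifold symmetry."""
    a = angle_deg % 180.0
    return 180.0 - a if a > 90.0 else a


@dataclass(frozen=True)
class PatternLabel:
    """Pattern mode of a window, with axis angle, node count and period."""

    mode: str  # longitudinal_pole_to_pole | longitudinal_striped |
    #            transverse_pole_to_pole | homogeneous | other
    axis_angle_deg: float | None = None  # folded, [0, 90]
    node_count: int | None = None
    period_s: float | None = None
    confidence: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass
class MembraneWindow:
    """Membrane density over a time window on an ordered boundary curve."""

    times: np.ndarray  # (nt,)
    density: np.ndarray  # (nt, m)
    points: np.ndarray  # (m, 2) boundary node positions
    weights: np.ndarray  # (m,) arc-length weights

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def centroid(self) -> np.ndarray:
        return (self.weights[:, None] * self.points).sum(0) / self.weights.sum()


def window_from_trajectory(traj, t_start: float, t_end: float) -> MembraneWindow:
    """Extract the membrane MinD window [t_start, t_end] from a trajectory."""
    t = traj.times()
    sel = (t >= t_start - 1e-9) & (t <= t_end + 1e-9)
    return MembraneWindow(
        times=t[sel],
        density=traj.membrane_mind()[sel],
        points=traj.mesh.boundary_points,
        weights=traj.mesh.boundary_weights(),
    )


def _dominant_component(win: MembraneWindow):
    """(frequency index, complex node amplitudes, dominance ratio) or None."""
    dens = win.density - win.density.mean(axis=0, keepdims=True)
    F = np.fft.rfft(dens, axis=0)
    power = (np.abs(F) ** 2) @ win.weights
    if len(power) < 3:
        return None
    power[0] = 0.0
    k = int(np.argmax(power[1:])) + 1
    med = float(np.median(power[1:]))
    if med <= 0 or power[k] < PEAK_OVER_MEDIAN * med:
        return None
    return k, F[k], float(power[k] / med)


def oscillation_axis(win: MembraneWindow, geometry=None) -> float | None:
    """Oscillation axis angle (folded to [0, 90], display convention).

    The axis is the direction of the spatial dipole of the temporal
    Fourier component at the dominant frequency. Returns None when no
    dominant frequency stands out (homogeneous/other path).
    """
    dom = _dominant_component(win)
    if dom is None:
        return None
    _, amp, _ = dom
    r = win.points - win.centroid()
    # whiten by the boundary's second-moment tensor so that estimates are
    # unbiased on anisotropic outlines
    C = (win.weights[:, None, None] * r[:, :, None] * r[:, None, :]).sum(0)
    P = (win.weights[:, None] * amp[:, None] * r).sum(0)  # complex dipole
    Pw = np.linalg.solve(C, P)
    scale = (win.weights * np.abs(amp)).sum()
    strength = np.linalg.norm(np.abs(Pw)) * np.sqrt(np.trace(C)) / max(scale, 1e-300)
    if strength > 0.1:
        z = Pw[0] ** 2 + Pw[1] ** 2
        phi = 0.5 * np.angle(z)
        v = np.real(Pw * np.exp(-1j * phi))
        if np.linalg.norm(v) < 1e-12 * max(np.abs(Pw).max(), 1e-300):
            v = np.imag(Pw * np.exp(-1j * phi))
    else:
        # multi-node (striped) patterns have a vanishing dipole: use the
        # amplitude-weighted second moment instead (generalized eigvec)
        S = (win.weights[:, None, None] * np.abs(amp)[:, None, None]
             * r[:, :, None] * r[:, None, :]).sum(0)
        from scipy.linalg import eigh

        vals, vecs = eigh(S, C)
        v = vecs[:, int(np.argmax(vals))]
    ang_from_long = math.degrees(math.atan2(v[1], v[0]))
    return fold_angle(90.0 - fold_angle(ang_from_long))


def _axis_direction_internal(axis_angle_deg: float) -> np.ndarray:
    """Unit vector (internal coords, long axis = x) for a display angle."""
    a = math.radians(90.0 - axis_angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def count_nodes(win: MembraneWindow, axis_angle_deg: float, n_bins: int = 24) -> int:
    """Alternating membrane MinD domains along the oscillation axis.

    The density profile along the axis is evaluated at the two opposite
    phases of the dominant oscillation; connected above-half-max domains
    are counted at each and summed (pole-to-pole 1+1=2, striped 2+1>=3).
    """
    dom = _dominant_component(win)
    if dom is None:
        return 0
    u = _axis_direction_internal(axis_angle_deg)
    proj = (win.points - win.centroid()) @ u
    dens0 = win.density - win.density.mean(axis=0, keepdims=True)
    # opposite phases of the dominant oscillation: project the field onto
    # the dominant spatial pattern (works for both dipolar pole-to-pole and
    # mirror-symmetric striped patterns, where the dipole vanishes)
    _, amp, _ = dom
    q = np.real(dens0 @ (win.weights * np.conj(amp)))
    i_a, i_b = int(np.argmax(q)), int(np.argmin(q))

    edges = np.linspace(proj.min() - 1e-9, proj.max() + 1e-9, n_bins + 1)
    which = np.digitize(proj, edges) - 1
    wsum = np.bincount(which, weights=win.weights, minlength=n_bins)

    def profile(i):
        # deviation from the time-mean profile, so the oscillating domains
        # stand out above the standing membrane baseline
        num = np.bincount(which, weights=win.weights * dens0[i], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            prof = num / wsum
        ok = wsum > 0
        return np.interp(np.arange(n_bins), np.flatnonzero(ok), prof[ok])

    def domains(prof):
        above = prof > 0.5 * prof.max()
        return int(np.sum(above[1:] & ~above[:-1]) + above[0])

    return domains(profile(i_a)) + domains(profile(i_b))


def period_estimate(series: np.ndarray, dt: float) -> float | None:
    """Oscillation period of a scalar time series (s), or None if aperiodic.

    Dominant-frequency reciprocal from the FFT, refined by the nearest
    autocorrelation peak with parabolic interpolation.
    """
    x = np.asarray(series, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 8:
        return None
    x = x.copy()
    if not ok.all():
        idx = np.arange(len(x))
        x = np.interp(idx, idx[ok], x[ok])
    x = x - x.mean()
    t = np.arange(len(x))
    x = x - np.polyval(np.polyfit(t, x, 1), t)  # detrend
    if np.std(x) < 1e-12 * max(abs(x).max(), 1e-300) or np.std(x) == 0:
        return None
    power = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    if len(power) < 4:
        return None
    power[0] = 0.0
    k = int(np.argmax(power[1:])) + 1
    med = float(np.median(power[1:]))
    if med <= 0 or power[k] < PEAK_OVER_MEDIAN * med:
        return None
    period0 = len(x) * dt / k

    # refine on the autocorrelation around the FFT estimate
    acf = np.correlate(x, x, mode="full")[len(x) - 1:]
    acf /= np.maximum(np.arange(len(x), 0, -1), 1)  # unbiased
    lag0 = period0 / dt
    lo = max(2, int(0.6 * lag0))
    hi = min(len(acf) - 2, int(1.5 * lag0) + 1)
    if hi <= lo:
        return float(period0)
    seg = acf[lo:hi + 1]
    j = int(np.argmax(seg)) + lo
    if 1 <= j < len(acf) - 1:
        y0, y1, y2 = acf[j - 1], acf[j], acf[j + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -1, 1))
        return float((j + shift) * dt)
    return float(period0)


def _spatial_cv(win: MembraneWindow) -> np.ndarray:
    w = win.weights / win.weights.sum()
    mean = win.density @ w
    var = ((win.density - mean[:, None]) ** 2) @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(var) / np.maximum(mean, 1e-300)


def classify_window(win: MembraneWindow, geometry=None) -> PatternLabel:
    """Classify one membrane-density window into a :class:`PatternLabel`.

    Homogeneous if the spatial coefficient of variation stays below 0.1
    throughout; otherwise transverse iff the folded axis angle is below
    45 deg, then pole-to-pole vs striped by node count. Anything that does
    not fit lands in "other" (never dropped).
    """
    if win.density.size == 0 or len(win.times) < 8:
        return PatternLabel(mode="other", confidence=0.0)
    cv = _spatial_cv(win)
    if np.all(cv < HOMOGENEOUS_CV):
        return PatternLabel(mode="homogeneous", confidence=1.0)
    dom = _dominant_component(win)
    axis = oscillation_axis(win)
    if dom is None or axis is None:
        return PatternLabel(mode="other", confidence=0.2)
    _, _, ratio = dom
    conf = float(np.clip((ratio - PEAK_OVER_MEDIAN) / 27.0, 0.0, 1.0))
    nodes = count_nodes(win, axis)
    # the dipole projection along the axis carries the fundamental cleanly
    u = _axis_direction_internal(axis)
    proj = (win.points - win.centroid()) @ u
    series = (win.density - win.density.mean(0)) @ (win.weights * proj)
    period = period_estimate(series, win.dt)
    if period is None:
        dens_mean = win.density.mean(axis=0)
        polar = win.weights * (dens_mean > np.quantile(dens_mean, 0.75))
        period = period_estimate(win.density @ polar, win.dt)
    if axis < 45.0:
        if nodes <= 2:
            return PatternLabel("transverse_pole_to_pole", axis, 2, period, conf)
        return PatternLabel("other", axis, nodes, period, 0.5 * conf)
    if nodes >= 3:
        return PatternLabel("longitudinal_striped", axis, nodes, period, conf)
    return PatternLabel("longitudinal_pole_to_pole", axis, 2, period, conf)


def label_timeline(traj, window_s: float = 120.0, stride_s: float | None = None) -> list:
    """Windowed labelling of a full trajectory.

    Returns a list of ``(t_start, t_end, PatternLabel)``; serialize with
    :func:`timeline_to_csv`.
    """
    t = traj.times()
    if len(t) == 0:
        return []
    stride = stride_s if stride_s is not None else window_s / 2.0
    out = []
    t0 = float(t[0])
    while t0 + window_s <= t[-1] + 1e-9:
        win = window_from_trajectory(traj, t0, t0 + window_s)
        out.append((t0, t0 + window_s, classify_window(win, traj.geometry)))
        t0 += stride
    if not out:  # short run: single window over everything
        win = window_from_trajectory(traj, t[0], t[-1])
        out.append((float(t[0]), float(t[-1]), classify_window(win, traj.geometry)))
    return out


def timeline_to_csv(timeline, path) -> None:
    import pandas as pd

    rows = [
        {"t_start": a, "t_end": b, "mode": lab.mode, "angle_deg": lab.axis_angle_deg,
         "node_count": lab.node_count, "period_s": lab.period_s,
         "confidence": lab.confidence}
        for a, b, lab in timeline
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
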