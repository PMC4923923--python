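"""Quantification of two-channel cell movies: shape, oscillation angle, transitions.

The pipeline mirrors how shaped-cell Min experiments are scored: the
cytosolic channel yields a binary cell mask per frame; 360-degree Feret
diameters parameterize the cell shape (minimum Feret tracks the short
symmetry axis, maximum the long axis or diagonal); the MinD channel yields
a polar-cluster angle (cluster centroid relative to the cell centroid,
folded to [0, 90] by the rectangle's symmetry) and the Feret diameter
along that angle; mode transitions are detected as sigmoidal excursions
of the folded angle across 45 degrees between the 15/75-degree plateau
bands, with the duration read off the 10%-90% rise of the fitted
logistic. The cluster tracker targets two-node oscillations; striped
movies belong to the window classifier instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import filters, measure

from .classifier import fold_angle, period_estimate

__all__ = [
    "CellMovie",
    "ShapeMetrics",
    "OscillationTrack",
    "TransitionEvent",
    "segment_cell",
    "feret_diameters",
    "mind_cluster_angle",
    "halves_intensity_difference",
    "track_movie",
    "detect_transitions",
    "transition_rate",
    "read_movie",
    "write_movie",
]

MIN_MASK_AREA_PX = 100
CLUSTER_PERCENTILE = 75.0
PLATEAU_LOW = 15.0
PLATEAU_HIGH = 75.0
CROSSING = 45.0
R2_MIN = 0.8


@dataclass
class CellMovie:
    """Two-channel image stack: cytosolic marker + MinD channel."""

    cyto_stack: np.ndarray  # (frames, H, W)
    mind_stack: np.ndarray  # same shape
    pixel_size_um: float
    frame_interval_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cyto_stack.shape != self.mind_stack.shape:
            raise ValueError("cytosolic and MinD stacks must have the same shape")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.cyto_stack.shape[0]


@dataclass
class ShapeMetrics:
    """360-degree Feret geometry of one frame's mask (angles vs horizontal)."""

    feret_by_angle: np.ndarray  # (360,) um, 1-degree steps; period 180
    feret_max: float
    feret_max_angle: float  # measurement direction, [0, 180)
    feret_min: float
    feret_min_angle: float
    centroid: tuple  # (x, y) um, image convention (x right, y up)


@dataclass
class OscillationTrack:
    """Per-frame MinD-cluster metrics for one movie plus summary values."""

    times: np.ndarray  # (frames,) s
    angle_deg: np.ndarray  # folded cluster angle, NaN when absent
    feret_along_angle: np.ndarray  # um, NaN when absent
    halves_diff: np.ndarray  # top-minus-bottom normalized intensity
    feret_max: np.ndarray
    feret_min: np.ndarray
    feret_max_angle: np.ndarray
    feret_min_angle: np.ndarray
    usable: np.ndarray  # bool per frame
    period_s: float | None = None

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TransitionEvent:
    """One mode transition: logistic fit of the folded angle vs time."""

    t_mid: float  # s, 45-degree crossing (sigmoid midpoint)
    duration_s: float  # 10% -> 90% rise of the fitted sigmoid
    from_mode: str
    to_mode: str
    fit_quality: float  # R^2


# ---------------------------------------------------------------------------
# per-frame operations
# ---------------------------------------------------------------------------


def segment_cell(cyto_frame: np.ndarray, min_area: int = MIN_MASK_AREA_PX) -> np.ndarray | None:
    """Binary cell mask from the cytosolic channel, or None if unusable.

    Lightly smoothed, Otsu-thresholded, hole-filled; the largest connected
    component is kept and must exceed the area floor.
    """
    img = ndimage.gaussian_filter(np.asarray(cyto_frame, dtype=float), 1.0)
    if img.max() <= img.min():
        return None
    thr = filters.threshold_otsu(img)
    fg = img > thr
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] <= min_area:
        return None
    return labels == best


def _mask_points(mask: np.ndarray) -> np.ndarray:
    """Pixel centers of the mask in (x, y) image coordinates (y up)."""
    rows, cols = np.nonzero(mask)
    return np.stack([cols.astype(float), (mask.shape[0] - 1 - rows).astype(float)], axis=1)


def feret_diameters(mask: np.ndarray, pixel_size: float = 1.0) -> ShapeMetrics:
    """Feret (caliper) diameters of a mask at 1-degree steps.

    ``feret_by_angle[k]`` is the extent of the shape measured along the
    direction k degrees from the horizontal: the distance between the two
    parallel tangents perpendicular to that direction. Computed on the
    convex hull (the Feret diameters of a set and of its hull coincide).
    """
    if mask is None or not np.any(mask):
        raise ValueError("empty mask")
    pts = _mask_points(mask)
    if len(pts) > 3:
        from scipy.spatial import ConvexHull

        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass  # degenerate (collinear) masks: project all points
    ang = np.deg2rad(np.arange(360.0))
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    proj = pts @ dirs.T  # (npts, 360)
    extent = (proj.max(axis=0) - proj.min(axis=0) + 1.0) * pixel_size  # +1 px width
    half = extent[:180]
    kmax = int(np.argmax(half))
    kmin = int(np.argmin(half))
    rows, cols = np.nonzero(mask)
    cx = cols.mean()
    cy = (mask.shape[0] - 1 - rows).mean()
    return ShapeMetrics(
        feret_by_angle=extent,
        feret_max=float(half[kmax]),
        feret_max_angle=float(kmax),
        feret_min=float(half[kmin]),
        feret_min_angle=float(kmin),
        centroid=(cx * pixel_size, cy * pixel_size),
    )


def mind_cluster_angle(mind_frame: np.ndarray, mask: np.ndarray,
                       shape: ShapeMetrics | None = None,
                       pixel_size: float = 1.0) -> tuple[float, float] | None:
    """Folded MinD-cluster angle and the Feret diameter along it.

    The cluster is the largest connected region above the 75th intensity
    percentile inside the mask; its intensity-weighted centroid is joined
    to the cell centroid and the angle of that vector against the
    horizontal is folded to [0, 90]. Returns None when no above-threshold
    cluster exists (homogeneous frame).
    """
    vals = np.asarray(mind_frame, dtype=float)[mask]
    if vals.size == 0:
        return None
    thr = np.percentile(vals, CLUSTER_PERCENTILE)
    hot = (mind_frame > thr) & mask
    if not np.any(hot):
        return None
    labels, n = ndimage.label(hot)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    blob = labels == best
    # a real polar cluster stands out against the cell: in a (near-)
    # homogeneous frame the top-quartile region is only noise-bright
    blob_mean = float(np.asarray(mind_frame, dtype=float)[blob].mean())
    cell_mean = float(vals.mean())
    if cell_mean <= 0 or blob_mean < 1.2 * cell_mean:
        return None
    rows, cols = np.nonzero(blob)
    w = np.asarray(mind_frame, dtype=float)[rows, cols]
    w = np.clip(w, 0, None) + 1e-12
    bx = float(np.average(cols, weights=w))
    by = float(np.average(mask.shape[0] - 1 - rows, weights=w))
    mrows, mcols = np.nonzero(mask)
    cx, cy = mcols.mean(), (mask.shape[0] - 1 - mrows).mean()
    dx, dy = bx - cx, by - cy
    if dx == 0 and dy == 0:
        return None
    angle = fold_angle(math.degrees(math.atan2(dy, dx)))
    if shape is None:
        shape = feret_diameters(mask, pixel_size)
    feret_here = float(shape.feret_by_angle[int(round(angle)) % 360])
    return angle, feret_here


def halves_intensity_difference(mind_frame: np.ndarray, mask: np.ndarray,
                                split_axis: str = "horizontal") -> float:
    """Normalized top-minus-bottom (or right-minus-left) MinD intensity.

    The mask is split through its centroid by a horizontal line
    (``split_axis="horizontal"``, measuring vertical asymmetry) or a
    vertical line; the difference of the two halves' summed MinD intensity
    is normalized by the total masked intensity, giving a value in [-1, 1].
    """
    img = np.asarray(mind_frame, dtype=float)
    rows, cols = np.nonzero(mask)
    total = img[rows, cols].sum()
    if total <= 0:
        return 0.0
    if split_axis == "horizontal":
        c = rows.mean()
        top = img[rows[rows < c], cols[rows < c]].sum()
        bot = img[rows[rows > c], cols[rows > c]].sum()
        return float((top - bot) / total)
    c = cols.mean()
    right = img[rows[cols > c], cols[cols > c]].sum()
    left = img[rows[cols < c], cols[cols < c]].sum()
    return float((right - left) / total)


# ---------------------------------------------------------------------------
# movie-level operations
# ---------------------------------------------------------------------------


def track_movie(movie: CellMovie) -> OscillationTrack:
    """Per-frame shape and MinD-cluster metrics for a whole movie.

    Frames with no usable mask are flagged and carry NaN metrics; the
    movie is rejected if more than half its frames are unusable. The
    period is estimated from the half-cell intensity difference along the
    dominant oscillation axis.
    """
    n = movie.n_frames
    times = np.arange(n) * movie.frame_interval_s
    angle = np.full(n, np.nan)
    feret_a = np.full(n, np.nan)
    halves = np.full(n, np.nan)
    fmax = np.full(n, np.nan)
    fmin = np.full(n, np.nan)
    fmax_a = np.full(n, np.nan)
    fmin_a = np.full(n, np.nan)
    usable = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = segment_cell(movie.cyto_stack[i])
        if mask is None:
            continue
        usable[i] = True
        shape = feret_diameters(mask, movie.pixel_size_um)
        fmax[i], fmin[i] = shape.feret_max, shape.feret_min
        fmax_a[i], fmin_a[i] = shape.feret_max_angle, shape.feret_min_angle
        res = mind_cluster_angle(movie.mind_stack[i], mask, shape, movie.pixel_size_um)
        if res is not None:
            angle[i], feret_a[i] = res
        # split along the dominant oscillation direction: vertical asymmetry
        halves[i] = halves_intensity_difference(movie.mind_stack[i], mask, "horizontal")
    if usable.sum() < 0.5 * n:
        raise ValueError(f"movie unusable: only {usable.sum()}/{n} frames segmented")
    # the polar signal: halves difference along whichever split oscillates more
    halves_v = halves
    halves_h = np.array([
        halves_intensity_difference(movie.mind_stack[i], segment_cell(movie.cyto_stack[i]), "vertical")
        if usable[i] else np.nan
        for i in range(n)
    ])
    sig = halves_v if np.nanstd(halves_v) >= np.nanstd(halves_h) else halves_h
    period = period_estimate(sig[usable], movie.frame_interval_s)
    track = OscillationTrack(times=times, angle_deg=angle, feret_along_angle=feret_a,
                             halves_diff=halves, feret_max=fmax, feret_min=fmin,
                             feret_max_angle=fmax_a, feret_min_angle=fmin_a,
                             usable=usable, period_s=period)
    return track


def _logistic(t, lo, hi, t_mid, tau):
    return lo + (hi - lo) / (1.0 + np.exp(-(t - t_mid) / tau))


def detect_transitions(track: OscillationTrack, min_plateau_frames: int = 3) -> list:
    """Sigmoid-fitted mode transitions of the folded oscillation angle.

    A candidate is a monotone excursion crossing 45 degrees with flanking
    plateaus beyond the 15/75-degree bands for at least
    ``min_plateau_frames`` frames; a logistic fit of angle vs time with
    R^2 >= 0.8 is accepted, its duration being the 10%-90% rise time
    (= ln(81) tau).
    """
    if len(track) < 30:
        raise ValueError("need >= 30 usable frames for transition detection")
    t = track.times
    a = track.angle_deg
    ok = np.isfinite(a)
    if ok.sum() < 30:
        raise ValueError("need >= 30 usable frames for transition detection")
    ti, ai = t[ok], a[ok]
    # plateau state per frame: +1 (longitudinal band), -1 (transverse band), 0
    state = np.zeros(len(ai), dtype=int)
    state[ai > PLATEAU_HIGH] = 1
    state[ai < PLATEAU_LOW] = -1
    events = []
    # find runs of +-1 with length >= min_plateau_frames
    runs = []
    i = 0
    while i < len(state):
        if state[i] != 0:
            j = i
            while j + 1 < len(state) and state[j + 1] == state[i]:
                j += 1
            if j - i + 1 >= min_plateau_frames:
                runs.append((i, j, state[i]))
            i = j + 1
        else:
            i += 1
    for (i0, j0, s0), (i1, j1, s1) in zip(runs[:-1], runs[1:]):
        if s0 == s1:
            continue  # no crossing between same-side plateaus
        lo_i, hi_i = i0, j1 + 1  # include both plateau runs for the asymptotes
        seg_t = ti[lo_i:hi_i]
        seg_a = ai[lo_i:hi_i]
        t_guess = 0.5 * (ti[j0] + ti[i1])
        tau_guess = max((ti[i1] - ti[j0]) / 4.0, (seg_t[1] - seg_t[0]) / 2.0)
        try:
            popt, _ = optimize.curve_fit(
                _logistic, seg_t, seg_a,
                p0=(seg_a[0], seg_a[-1], t_guess, tau_guess if s1 > s0 else -tau_guess),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        pred = _logistic(seg_t, *popt)
        ss_res = float(np.sum((seg_a - pred) ** 2))
        ss_tot = float(np.sum((seg_a - seg_a.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if r2 < R2_MIN:
            continue
        tau = abs(popt[3])
        events.append(TransitionEvent(
            t_mid=float(popt[2]),
            duration_s=float(math.log(81.0) * tau),
            from_mode="longitudinal" if s0 > 0 else "transverse",
            to_mode="longitudinal" if s1 > 0 else "transverse",
            fit_quality=r2,
        ))
    return events


def transition_rate(events, observation_span_h: float, n_cells: int = 1) -> float:
    """Transitions per cell per hour."""
    if observation_span_h <= 0:
        raise ValueError("observation span must be positive")
    n_events = len(events) if hasattr(events, "__len__") else int(events)
    return n_events / (n_cells * observation_span_h)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + YAML sidecar
# ---------------------------------------------------------------------------


def write_movie(movie: CellMovie, tiff_path, sidecar_path=None) -> None:
    """Write a movie as a (frames, 2, H, W) TIFF with a YAML sidecar."""
    import tifffile
    import yaml

    stack = np.stack([movie.cyto_stack, movie.mind_stack], axis=1).astype(np.float32)
    tifffile.imwrite(tiff_path, stack)
    sidecar_path = sidecar_path or str(tiff_path) + ".yaml"
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump({
            "pixel_size_um": float(movie.pixel_size_um),
            "frame_interval_s": float(movie.frame_interval_s),
            "channels": ["cytosol", "mind"],
            "metadata": movie.metadata,
        }, fh)


def read_movie(tiff_path, sidecar_path=None) -> CellMovie:
    import tifffile
    import yaml

    sidecar_path = sidecar_path or str(tiff_path) + ".yaml"
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    stack = tifffile.imread(tiff_path)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError("expected a (frames, 2, H, W) two-channel stack")
    return CellMovie(
        cyto_stack=np.asarray(stack[:, 0], dtype=float),
        mind_stack=np.asarray(stack[:, 1], dtype=float),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        metadata=meta.get("metadata") or {},
    )
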