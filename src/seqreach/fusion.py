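"""Movement-fusion metrics: fusion index, spatial reorganization, FI-RD fit.

The fusion index of one transition compares the minimum speed at the
transition with the mean of the two adjacent peak speeds,

    FI = 1 - (m - vmin) / m = vmin / m,    m = (vmax1 + vmax2) / 2,

clamped to [0, 1]: 0 is a full stop between submovements, 1 a fully
coarticulated transition whose minimum equals the mean peak.  A trial has
7 transitions, so the trial score (the sum) ranges from 0 to 7.

Fusion also shows spatially: as two submovements merge, the location of
the velocity peak drifts toward the via point.  Over a sliding window of
10 trials, the scatter of per-trial peak locations on each reach (first
and last excluded) is summarized by its centroid and a 95% confidence
ellipse; the centroid's radial distance d to the via point is normalized
as RD% = 100 * (1 - d / L), with L the reach's straight-line length.
100% means the peak sits on the via; isolated bell-shaped reaches peak
near their midpoint, giving 45-55%.

The curvilinear FI-RD relation is summarized by a continuous two-segment
piecewise linear fit with three knots (outer two at the data range, one
free interior breakpoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import FitError, ParameterError
from .geometry import TaskGeometry
from .kinematics import TrialMetrics

__all__ = [
    "FusionMetrics",
    "RadialDistanceSeries",
    "PiecewiseFit",
    "fusion_index",
    "trial_fusion",
    "radial_percent",
    "radial_distance",
    "piecewise_fit",
]


@dataclass
class FusionMetrics:
    """Per-transition fusion indices and their per-trial sum."""

    fi_per_transition: np.ndarray  # 7 values in [0, 1]
    trial: int | None = None

    @property
    def fi_trial(self) -> float:
        return float(np.sum(self.fi_per_transition))


@dataclass
class RadialDistanceSeries:
    """One sliding window's spatial-reorganization summary."""

    window_start_trial: int
    segment_indices: np.ndarray          # 1-based reach indices included
    centroids: np.ndarray                # (k, 2)
    ellipse_axes: np.ndarray             # (k, 2) semi-axis lengths at 95% coverage
    ellipse_angles_deg: np.ndarray       # (k,) orientation of the major axis
    rd_percent: np.ndarray               # (k,) in [0, 100]
    @property
    def rd_mean(self) -> float:
        return float(np.mean(self.rd_percent))


@dataclass
class PiecewiseFit:
    """Continuous two-segment linear fit with one free interior knot."""

    knots: tuple[float, float, float]    # (min x, interior, max x)
    slopes: tuple[float, float]
    intercepts: tuple[float, float]
    sse: float

    @property
    def interior_knot(self) -> float:
        return self.knots[1]

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        k = self.knots[1]
        y1 = self.intercepts[0] + self.slopes[0] * x
        y2 = self.intercepts[1] + self.slopes[1] * x
        return np.where(x <= k, y1, y2)


def fusion_index(vmax1: float, vmax2: float, vmin: float) -> float:
    """Fusion index of one transition, clamped to [0, 1].

    Equals ``vmin / m`` with ``m`` the mean of the adjacent peaks; under
    measurement noise vmin can exceed m, in which case the value is
    clamped with a warning.  Scale-invariant: multiplying all three speeds
    by c > 0 leaves it unchanged.
    """
    if vmax1 <= 0 or vmax2 <= 0:
        raise ParameterError("peak velocities must be positive")
    if vmin < 0:
        raise ParameterError("minimum velocity must be nonnegative")
    m = 0.5 * (vmax1 + vmax2)
    fi = 1.0 - (m - vmin) / m
    if fi > 1.0:
        warnings.warn(f"fusion index {fi:.3f} > 1 clamped (vmin exceeds mean peak)", RuntimeWarning)
    return float(np.clip(fi, 0.0, 1.0))


def trial_fusion(metrics: TrialMetrics, trial: int | None = None) -> FusionMetrics:
    """Per-transition fusion indices of one trial (max sum = 7)."""
    vmax = np.asarray(metrics.vmax_per_segment, dtype=float)
    vmin = np.asarray(metrics.vmin_per_transition, dtype=float)
    if len(vmax) != len(vmin) + 1:
        raise ParameterError("need n segments and n-1 transition minima")
    fi = np.array([fusion_index(vmax[k], vmax[k + 1], vmin[k]) for k in range(len(vmin))])
    return FusionMetrics(fi, trial=trial)


def radial_percent(centroid, waypoint, previous_waypoint) -> float:
    """Normalized radial distance of a peak-location centroid, percent.

    100 * (1 - d / L) clamped to [0, 100]: d the centroid-to-waypoint
    distance, L the straight-line reach length.  100% = centroid on the
    waypoint; a mid-reach centroid gives 50%.
    """
    centroid = np.asarray(centroid, dtype=float)
    waypoint = np.asarray(waypoint, dtype=float)
    L = float(np.linalg.norm(waypoint - np.asarray(previous_waypoint, dtype=float)))
    if L <= 0:
        raise ParameterError("degenerate reach: zero straight-line length")
    d = float(np.linalg.norm(centroid - waypoint))
    return float(np.clip(100.0 * (1.0 - d / L), 0.0, 100.0))


def _confidence_ellipse(points: np.ndarray, coverage: float):
    """Principal-axes ellipse covering ``coverage`` of a bivariate normal.

    Semi-axes are the principal-component standard deviations scaled by
    the square root of the chi-square(2) quantile; a degenerate scatter
    (identical points) yields zero axes and a valid centroid.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / max(len(points) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 0.0)
    scale = np.sqrt(chi2.ppf(coverage, df=2))
    axes = scale * np.sqrt(evals)[::-1]  # major first
    major = evecs[:, -1]
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    return centroid, axes, angle


def radial_distance(
    trials: list,
    geometry: TaskGeometry,
    window: int = 10,
    coverage: float = 0.95,
) -> list[RadialDistanceSeries]:
    """Sliding-window spatial-reorganization series.

    ``trials`` is an ordered sequence of objects exposing ``trajectory``,
    ``profile`` and ``segmented`` attributes (or (trajectory, profile,
    segmented) tuples).  For every stride-1 window of ``window`` trials
    and every reach except the first and last, the (x, y) locations of
    the per-trial peak speed are pooled, summarized by centroid and 95%
    ellipse, and normalized against the via point: every included reach
    has the via target at one end, and fusion drags the peak toward it.
    """
    if window < 2:
        raise ParameterError("window must cover at least 2 trials")
    if len(trials) < window:
        raise ParameterError(f"need at least {window} trials, got {len(trials)}")

    def unpack(t):
        if hasattr(t, "trajectory"):
            return t.trajectory, t.profile, t.segmented
        return t  # assume tuple

    seq_pts = geometry.sequence_points
    n_seg = geometry.n_movements
    include = list(range(2, n_seg))  # 1-based reaches 2..7: skip first and last

    # peak locations per trial and included segment; the peak search skips
    # samples still inside the start waypoint's proximity region (the
    # incoming tail and dwell of the previous transition), so the location
    # reflects the reach proper
    peaks = np.empty((len(trials), len(include), 2))
    for i, t in enumerate(trials):
        trajectory, profile, segmented = unpack(t)
        for j, k in enumerate(include):
            a, b = segmented.segments[k - 1]
            pos = trajectory.positions[a : b + 1]
            spd = profile.speed[a : b + 1].copy()
            outside = np.linalg.norm(pos - seq_pts[k - 1], axis=1) >= geometry.proximity_radius
            if np.any(outside):
                spd[~outside] = -np.inf
            rel = int(np.argmax(spd))
            peaks[i, j] = pos[rel]

    out = []
    for w0 in range(len(trials) - window + 1):
        cents = np.empty((len(include), 2))
        axes = np.empty((len(include), 2))
        angles = np.empty(len(include))
        rd = np.empty(len(include))
        for j, k in enumerate(include):
            pts = peaks[w0 : w0 + window, j]
            c, ax, ang = _confidence_ellipse(pts, coverage)
            cents[j], axes[j], angles[j] = c, ax, ang
            # reference = the via end of reach k; normalize by the reach length
            if geometry.reach_sequence[k] == "via":
                via_pt, outer_pt = seq_pts[k], seq_pts[k - 1]
            else:
                via_pt, outer_pt = seq_pts[k - 1], seq_pts[k]
            rd[j] = radial_percent(c, via_pt, outer_pt)
        out.append(
            RadialDistanceSeries(
                window_start_trial=w0,
                segment_indices=np.array(include),
                centroids=cents,
                ellipse_axes=axes,
                ellipse_angles_deg=angles,
                rd_percent=rd,
            )
        )
    return out


def piecewise_fit(x, y, n_knots: int = 3) -> PiecewiseFit:
    """Least-squares continuous two-segment linear fit.

    The outer knots sit at the data range; the interior knot is found by
    a grid search over data quantiles refined by bounded local
    optimization.  For a fixed knot the fit is linear least squares on
    the basis {1, x, max(x - knot, 0)}, so the two-segment SSE can never
    exceed the single-line SSE.
    """
    if n_knots != 3:
        raise ParameterError("only the three-knot (one interior breakpoint) form is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 6:
        raise FitError("need at least 6 (x, y) points")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise FitError("x values span zero range")

    def sse_at(knot: float) -> tuple[float, np.ndarray]:
        A = np.column_stack([np.ones_like(x), x, np.maximum(x - knot, 0.0)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        return float(resid @ resid), beta

    qs = np.quantile(x, np.linspace(0.05, 0.95, 37))
    qs = np.unique(qs)
    qs = qs[(qs > lo) & (qs < hi)]
    if len(qs) == 0:
        raise FitError("degenerate x distribution: no interior knot candidates")
    sses = np.array([sse_at(q)[0] for q in qs])
    best = int(np.argmin(sses))
    lo_b = qs[best - 1] if best > 0 else lo + 1e-9 * (hi - lo)
    hi_b = qs[best + 1] if best < len(qs) - 1 else hi - 1e-9 * (hi - lo)
    res = minimize_scalar(lambda k: sse_at(k)[0], bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": 1e-6 * (hi - lo)})
    knot = float(res.x) if res.fun <= sses[best] else float(qs[best])

    sse, beta = sse_at(knot)
    b0, b1, b2 = beta
    slopes = (float(b1), float(b1 + b2))
    intercepts = (float(b0), float(b0 - b2 * knot))
    return PiecewiseFit(knots=(lo, knot, hi), slopes=slopes, intercepts=intercepts, sse=sse)
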