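"""Minimum-jerk trajectories through via points.

The smoothness-optimal reference for a reaching sequence is the trajectory
minimizing half the time integral of squared jerk,

    J = 1/2 * int ( |d3x/dt3|^2 + |d3y/dt3|^2 ) dt,

subject to passing exactly through each via point, starting and ending at
rest (zero velocity and acceleration).  For *fixed* via passage times the
optimum is a piecewise quintic polynomial per axis with position, velocity,
acceleration, jerk and snap continuous at every via; that inner problem is
a square linear system and is solved exactly.  The passage times themselves
are free parameters: the outer problem minimizes the jerk cost over them by
a bounded simplex search initialized from chord-length-proportional times.

The jerk cost obeys exact scaling laws used throughout the package:
J ~ L^2 for a spatial dilation by L and J ~ T^-5 for a time dilation by T,
so the optimal *relative* passage times are independent of total duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import OptimizationError, ParameterError

__all__ = ["MinJerkProblem", "MinJerkResult", "min_jerk_via", "point_to_point"]


@dataclass
class MinJerkProblem:
    """A via-point minimum-jerk problem (2-D, rest-to-rest)."""

    start: np.ndarray
    end: np.ndarray
    via_points: np.ndarray  # shape (m, 2); m may be 0
    total_duration: float
    passage_times: np.ndarray | None = None  # optional initial guess, strictly inside (0, T)

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.via_points = np.asarray(self.via_points, dtype=float).reshape(-1, 2)
        if self.total_duration <= 0:
            raise ParameterError("total_duration must be positive")
        if self.passage_times is not None:
            pt = np.asarray(self.passage_times, dtype=float)
            if pt.shape != (len(self.via_points),):
                raise ParameterError("passage_times must give one time per via point")
            if np.any(pt <= 0) or np.any(pt >= self.total_duration) or np.any(np.diff(pt) <= 0):
                raise ParameterError("passage_times must be strictly increasing inside (0, total_duration)")
            self.passage_times = pt

    @property
    def waypoints(self) -> np.ndarray:
        """start, vias, end stacked as shape (m+2, 2)."""
        return np.vstack([self.start, self.via_points, self.end])


@dataclass
class MinJerkResult:
    """Solved trajectory: piecewise quintic coefficients plus the jerk cost."""

    waypoints: np.ndarray            # (m+2, 2)
    knot_times: np.ndarray           # (m+2,) absolute times incl. 0 and T
    coeffs: np.ndarray               # (m+1, 6, 2) quintic coeffs per segment, local time
    jerk_cost: float

    @property
    def passage_times(self) -> np.ndarray:
        return self.knot_times[1:-1]

    @property
    def total_duration(self) -> float:
        return float(self.knot_times[-1])

    def _segment_of(self, t: np.ndarray) -> np.ndarray:
        seg = np.searchsorted(self.knot_times, t, side="right") - 1
        return np.clip(seg, 0, len(self.coeffs) - 1)

    def _eval(self, t, order: int) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        seg = self._segment_of(t)
        tau = t - self.knot_times[seg]
        out = np.zeros((len(t), 2))
        powers = np.arange(6)
        for k in range(order, 6):
            fac = np.prod(powers[k - order + 1 : k + 1]) if order else 1.0
            out += fac * self.coeffs[seg, k, :] * (tau ** (k - order))[:, None]
        return out

    def position(self, t) -> np.ndarray:
        return self._eval(t, 0)

    def velocity(self, t) -> np.ndarray:
        return self._eval(t, 1)

    def acceleration(self, t) -> np.ndarray:
        return self._eval(t, 2)

    def speed(self, t) -> np.ndarray:
        return np.linalg.norm(self.velocity(t), axis=1)

    def time_rescaled(self, new_duration: float) -> "MinJerkResult":
        """Exact time dilation: same path, duration scaled to ``new_duration``.

        Quintic coefficient k scales by beta^-k for knot times scaled by
        beta; the jerk cost scales by beta^-5.
        """
        beta = new_duration / self.total_duration
        scale = beta ** -np.arange(6)
        return MinJerkResult(
            waypoints=self.waypoints.copy(),
            knot_times=self.knot_times * beta,
            coeffs=self.coeffs * scale[None, :, None],
            jerk_cost=self.jerk_cost * beta**-5,
        )


def _derivative_row(tau: float, order: int) -> np.ndarray:
    """Row of d^order/dt^order [1, t, ..., t^5] evaluated at tau."""
    row = np.zeros(6)
    for k in range(order, 6):
        fac = 1.0
        for j in range(k - order + 1, k + 1):
            fac *= j
        row[k] = fac * tau ** (k - order)
    return row


def _solve_fixed_times(points: np.ndarray, durations: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact inner solution for fixed segment durations.

    Returns (coeffs with shape (n_seg, 6, 2), jerk_cost).  Constraints per
    axis: rest boundary conditions at both ends, via positions on both
    sides of each knot, and continuity of derivatives 1..4 at each knot
    (the first-order optimality conditions of the fixed-time problem).
    """
    n_seg = len(durations)
    n = 6 * n_seg
    A = np.zeros((n, n))
    B = np.zeros((n, 2))
    row = 0

    def blk(seg):
        return slice(6 * seg, 6 * seg + 6)

    # start at rest
    for order in range(3):
        A[row, blk(0)] = _derivative_row(0.0, order)
        B[row] = points[0] if order == 0 else 0.0
        row += 1
    # interior knots
    for i in range(n_seg - 1):
        d = durations[i]
        A[row, blk(i)] = _derivative_row(d, 0)
        B[row] = points[i + 1]
        row += 1
        A[row, blk(i + 1)] = _derivative_row(0.0, 0)
        B[row] = points[i + 1]
        row += 1
        for order in range(1, 5):
            A[row, blk(i)] = _derivative_row(d, order)
            A[row, blk(i + 1)] = -_derivative_row(0.0, order)
            row += 1
    # end at rest
    for order in range(3):
        A[row, blk(n_seg - 1)] = _derivative_row(durations[-1], order)
        B[row] = points[-1] if order == 0 else 0.0
        row += 1

    coef = np.linalg.solve(A, B)  # (n, 2)
    coeffs = coef.reshape(n_seg, 6, 2)
    return coeffs, _jerk_cost(coeffs, durations)


def _jerk_cost(coeffs: np.ndarray, durations: np.ndarray) -> float:
    """1/2 * int |x'''|^2 + |y'''|^2 over all segments, closed form."""
    j0 = 6.0 * coeffs[:, 3, :]
    j1 = 24.0 * coeffs[:, 4, :]
    j2 = 60.0 * coeffs[:, 5, :]
    d = durations[:, None]
    integral = (
        j0**2 * d
        + j0 * j1 * d**2
        + (j1**2 / 3.0 + 2.0 * j0 * j2 / 3.0) * d**3
        + 0.5 * j1 * j2 * d**4
        + 0.2 * j2**2 * d**5
    )
    return 0.5 * float(np.sum(integral))


def min_jerk_via(problem: MinJerkProblem, optimize_times: bool = True) -> MinJerkResult:
    """Solve a via-point minimum-jerk problem with free passage times.

    Parameters
    ----------
    problem
        Geometry, duration and optional passage-time initial guess.
    optimize_times
        If False (or there are no via points) the passage times are left
        at their initial values (chord-length proportional by default) and
        only the exact inner problem is solved.
    """
    pts = problem.waypoints
    T = problem.total_duration
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chords < 1e-9):
        raise ParameterError("coincident consecutive waypoints make the problem degenerate")

    m = len(problem.via_points)
    if problem.passage_times is not None:
        knots = np.concatenate([[0.0], problem.passage_times, [T]])
        durations0 = np.diff(knots)
    else:
        durations0 = T * chords / chords.sum()

    if m == 0:
        coeffs, cost = _solve_fixed_times(pts, durations0)
        return MinJerkResult(pts, np.concatenate([[0.0], np.cumsum(durations0)]), coeffs, cost)

    # Outer problem: durations = T * softmax([0, z]); z in R^m+... we fix the
    # first component to remove the softmax shift degeneracy.
    z0 = np.log(durations0 / durations0[0])[1:]

    def durations_of(z):
        w = np.exp(np.concatenate([[0.0], z]))
        return T * w / w.sum()

    def cost_of(z):
        _, c = _solve_fixed_times(pts, durations_of(z))
        return c

    if optimize_times:
        c0 = cost_of(z0)
        res = minimize(
            cost_of,
            z0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8 * c0, "maxiter": 6000, "maxfev": 6000},
        )
        if not np.isfinite(res.fun):
            raise OptimizationError(
                "passage-time optimization diverged",
                best=durations_of(z0),
                diagnostics={"message": res.message},
            )
        if not res.success:
            warnings.warn(f"passage-time search stopped early: {res.message}", RuntimeWarning)
        z = res.x if res.fun <= cost_of(z0) else z0
    else:
        z = z0

    durations = durations_of(z)
    coeffs, cost = _solve_fixed_times(pts, durations)
    return MinJerkResult(pts, np.concatenate([[0.0], np.cumsum(durations)]), coeffs, cost)


def point_to_point(start, end, duration: float) -> MinJerkResult:
    """Rest-to-rest minimum-jerk reach with no via points.

    The per-axis solution is the classic quintic x(tau) = L(10 tau^3 -
    15 tau^4 + 6 tau^5) with peak speed 1.875 L/T and jerk cost
    360 L^2 / T^5 (with the 1/2 factor in the cost).
    """
    return min_jerk_via(MinJerkProblem(start, end, np.empty((0, 2)), duration))
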