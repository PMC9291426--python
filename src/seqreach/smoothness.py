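"""Smoothness scoring: minimum-jerk model comparison and spectral arc length.

A trial's observed speed profile is compared with the speed profile of
the minimum-jerk via-point trajectory for the same waypoints and total
movement time (see :mod:`seqreach.minjerk`).  Both profiles are mapped to
normalized time [0, 1], normalized to unit peak amplitude and linearly
interpolated to N = 500 points before taking the mean squared error, so
the score reflects profile *shape*, not speed or duration.

Spectral arc length (SPARC) is an alternative smoothness measure: the
negative arc length of the normalized magnitude spectrum of the speed
profile over normalized frequency, with a 20-Hz cutoff adaptively
tightened to the last frequency whose normalized amplitude exceeds 0.05.
Values are negative; closer to zero means smoother movement.  SPARC is
insensitive to the sampling rate for a fixed movement.

Both analyses run on noncorrected trials only; :func:`exclude_corrected`
applies that filter and reports the exclusion fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .kinematics import VelocityProfile

__all__ = ["SmoothnessResult", "mse_to_model", "spectral_arc_length", "exclude_corrected"]


@dataclass
class SmoothnessResult:
    """Per-trial smoothness summary."""

    mse: float
    sparc: float
    jerk_cost: float
    passage_times: np.ndarray | None = None
    excluded: bool = False


def _as_time_speed(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, VelocityProfile):
        return profile.sample_times, profile.speed
    if isinstance(profile, tuple) and len(profile) == 2:
        return np.asarray(profile[0], float), np.asarray(profile[1], float)
    arr = np.asarray(profile, dtype=float)
    return np.arange(len(arr), dtype=float), arr


def _normalize(profile, n_interp: int) -> np.ndarray:
    t, v = _as_time_speed(profile)
    if len(v) == 0:
        raise DataError("empty velocity profile")
    peak = float(np.max(np.abs(v)))
    if peak <= 0:
        raise DataError("all-zero velocity profile cannot be normalized")
    span = t[-1] - t[0]
    if span <= 0:
        raise DataError("profile spans zero time")
    tn = (t - t[0]) / span
    grid = np.linspace(0.0, 1.0, n_interp)
    return np.interp(grid, tn, v / peak)


def mse_to_model(observed, predicted, n_interp: int = 500) -> float:
    """Mean squared error between normalized speed profiles.

    Both profiles (observed trial and minimum-jerk prediction) are
    time-normalized to [0, 1], amplitude-normalized to unit peak and
    interpolated to ``n_interp`` points; identical shapes give 0.
    """
    if n_interp < 2:
        raise ParameterError("n_interp must be at least 2")
    a = _normalize(observed, n_interp)
    b = _normalize(predicted, n_interp)
    return float(np.mean((a - b) ** 2))


def spectral_arc_length(
    profile,
    sampling_rate_hz: float | None = None,
    cutoff_hz: float = 20.0,
    amp_threshold: float = 0.05,
    pad_pow2: int = 4,
) -> float:
    """Spectral arc length of a speed profile (negative; 0 is smoothest).

    The magnitude spectrum is normalized by its maximum (the DC value of
    a nonnegative speed profile), restricted to ``cutoff_hz`` and then to
    the adaptive band where the normalized amplitude stays above
    ``amp_threshold``; the arc length is accumulated over frequency
    normalized by the selected band.
    """
    t, v = _as_time_speed(profile)
    if len(v) < 8:
        raise DataError("need at least 8 samples for a spectral estimate")
    if sampling_rate_hz is None:
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))

    n_fft = int(2 ** np.ceil(np.log2(len(v)) + pad_pow2))
    freqs = np.arange(n_fft) * (sampling_rate_hz / n_fft)
    mag = np.abs(np.fft.fft(v, n_fft))
    if mag.max() <= 0:
        raise DataError("zero-power profile")
    mag = mag / mag.max()

    sel = freqs <= cutoff_hz
    f_sel, m_sel = freqs[sel], mag[sel]
    above = np.nonzero(m_sel >= amp_threshold)[0]
    if len(above) == 0:
        raise DataError("no spectral content above the amplitude threshold")
    band = slice(above[0], above[-1] + 1)
    f_sel, m_sel = f_sel[band], m_sel[band]
    if len(f_sel) < 2 or f_sel[-1] <= f_sel[0]:
        raise DataError("degenerate spectral band")

    df = np.diff(f_sel) / (f_sel[-1] - f_sel[0])
    dm = np.diff(m_sel)
    return float(-np.sum(np.sqrt(df**2 + dm**2)))


def exclude_corrected(records, corrected_flags=None):
    """Drop corrected trials from smoothness analyses.

    ``records`` is any sequence; ``corrected_flags`` gives one boolean per
    record (default: read ``r.metrics.corrected`` or ``r.corrected``).
    Returns ``(kept_records, report)`` with the count and percentage
    excluded; an all-corrected input yields an empty set with a warning,
    not an error.
    """
    records = list(records)
    if corrected_flags is None:
        def flag(r):
            if hasattr(r, "metrics"):
                return bool(r.metrics.corrected)
            return bool(getattr(r, "corrected", False))
        corrected_flags = [flag(r) for r in records]
    corrected_flags = list(corrected_flags)
    if len(corrected_flags) != len(records):
        raise ParameterError("one corrected flag per record required")

    kept = [r for r, c in zip(records, corrected_flags) if not c]
    n_excl = len(records) - len(kept)
    report = {
        "n_total": len(records),
        "n_excluded": n_excl,
        "pct_excluded": 100.0 * n_excl / len(records) if records else 0.0,
    }
    if records and not kept:
        warnings.warn("all trials are corrected; smoothness set is empty", RuntimeWarning)
    return kept, report
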