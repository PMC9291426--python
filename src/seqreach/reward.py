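"""Closed-loop rank-based monetary feedback and the random-feedback draw.

After each trial, the current movement time is ranked against the 20
preceding trials (the first trial of a block ranks against the last 20
trials of the previous block).  The rank percentile — the fraction of
reference trials strictly slower than the current one — maps onto a
payout in pence:

    >= 90%: 5p   [80, 90): 4p   [60, 80): 3p   [40, 60): 2p
    [20, 40): 1p   < 20%: 0p

The mapping is deterministic and monotone: a faster trial never earns
less.  The random-feedback condition draws payouts uniformly from a pool
of previously awarded values, decoupling feedback from performance while
preserving its marginal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["RewardSchedule", "FeedbackEvent", "closed_loop_feedback", "random_feedback", "session_feedback"]

#: (lower percentile bound, payout in pence), highest first.
DEFAULT_THRESHOLDS: tuple[tuple[float, int], ...] = (
    (90.0, 5),
    (80.0, 4),
    (60.0, 3),
    (40.0, 2),
    (20.0, 1),
    (0.0, 0),
)


@dataclass(frozen=True)
class RewardSchedule:
    window: int = 20
    thresholds: tuple[tuple[float, int], ...] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        if self.window < 1:
            raise ParameterError("reference window must hold at least 1 trial")
        bounds = [b for b, _ in self.thresholds]
        payouts = [p for _, p in self.thresholds]
        if bounds != sorted(bounds, reverse=True) or bounds[-1] != 0.0:
            raise ParameterError("thresholds must descend and end at 0% (a full partition)")
        if payouts != sorted(payouts, reverse=True):
            raise ParameterError("payouts must be nonincreasing as percentile falls")

    def payout(self, percentile: float) -> int:
        if not 0.0 <= percentile <= 100.0:
            raise ParameterError("percentile must lie in [0, 100]")
        for bound, pence in self.thresholds:
            if percentile >= bound:
                return pence
        return self.thresholds[-1][1]


@dataclass
class FeedbackEvent:
    trial: int
    mt: float
    percentile: float
    payout: int
    source: str  # "closed_loop" or "random"


def closed_loop_feedback(
    current_mt: float,
    reference_mts,
    schedule: RewardSchedule | None = None,
    trial: int = 0,
) -> FeedbackEvent:
    """Rank the current movement time in the reference window and pay out.

    Percentile = 100 x (fraction of reference MTs strictly slower than
    the current trial); ties do not count in the trial's favour.  A pure
    function of its inputs.
    """
    schedule = schedule or RewardSchedule()
    ref = np.asarray(reference_mts, dtype=float)
    if len(ref) != schedule.window:
        raise ParameterError(f"reference window must hold exactly {schedule.window} trials, got {len(ref)}")
    if current_mt <= 0 or np.any(ref <= 0):
        raise ParameterError("movement times must be positive")
    percentile = 100.0 * float(np.mean(ref > current_mt))
    return FeedbackEvent(trial, float(current_mt), percentile, schedule.payout(percentile), "closed_loop")


def random_feedback(pool, rng: np.random.Generator | int | None = None, trial: int = 0) -> FeedbackEvent:
    """Uniform draw from a pool of previously awarded payouts."""
    pool = list(pool)
    if not pool:
        raise ParameterError("feedback pool is empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    payout = int(pool[int(rng.integers(len(pool)))])
    return FeedbackEvent(trial, float("nan"), float("nan"), payout, "random")


def session_feedback(mts, schedule: RewardSchedule | None = None, carryover=None):
    """Replay the closed-loop schedule over a session of movement times.

    ``carryover`` supplies the reference history for the early trials
    (the previous block's tail); it must hold at least one full window.
    Returns ``(events, total_pence)``; session earnings equal the sum of
    per-trial payouts by construction.
    """
    schedule = schedule or RewardSchedule()
    mts = [float(m) for m in mts]
    history = [float(m) for m in (carryover or [])]
    if len(history) < schedule.window:
        raise ParameterError(
            f"carryover must supply at least {schedule.window} baseline movement times "
            f"(got {len(history)}); seed it with the previous block's tail"
        )
    events = []
    for i, mt in enumerate(mts, start=1):
        ref = history[-schedule.window:]
        ev = closed_loop_feedback(mt, ref, schedule, trial=i)
        events.append(ev)
        history.append(mt)
    return events, sum(ev.payout for ev in events)
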