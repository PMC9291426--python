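"""Participant-bootstrap learning-curve inference.

The trial-wise group mean of a kinematic measure is fit with one of three
curve families,

    poly1:  f(x) = p1 * x + p2        (p2: early-training intercept,
                                       p1: learning rate)
    exp1:   f(x) = a * exp(b * x)
    power1: f(x) = a * x ** b

Uncertainty comes from resampling *participants* with replacement to the
original group size (1,000 draws by default): each draw averages the
resampled participants' trial-wise series and refits the family; 95%
percentile intervals of the parameter draws are the confidence intervals.
Group contrasts difference the draws pairwise and test whether the 95%
interval of the difference excludes zero (the per-group intervals are
also reported for the non-overlap reading).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, FitError, ParameterError

__all__ = [
    "GroupSeries",
    "ModelFit",
    "BootstrapFitResult",
    "ContrastReport",
    "bootstrap_fit",
    "compare_families",
    "group_contrast",
    "baseline_correct",
    "early_training_mean",
]

FAMILIES = ("poly1", "exp1", "power1")
PARAM_NAMES = {"poly1": ("p1", "p2"), "exp1": ("a", "b"), "power1": ("a", "b")}


@dataclass
class GroupSeries:
    """Per-participant, per-trial values of one measure for one group.

    ``values`` has shape (n_participants, n_trials); missing/excluded
    trials are NaN and are ignored in trial-wise means.
    """

    values: np.ndarray
    group: str = ""
    measure: str = ""
    participants: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("GroupSeries.values must be 2-D (participants x trials)")
        if self.participants is None:
            self.participants = np.arange(1, self.values.shape[0] + 1)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class ModelFit:
    family: str
    params: np.ndarray  # (p1, p2) for poly1; (a, b) otherwise
    r_squared: float


@dataclass
class BootstrapFitResult:
    family: str
    group: str
    point: ModelFit
    param_draws: np.ndarray       # (n_boot, 2)
    r_squared_draws: np.ndarray   # (n_boot,)
    ci: dict                      # name -> (lo, hi), incl. "r_squared"
    n_failed: int
    seed: int | None

    @property
    def n_boot(self) -> int:
        return len(self.r_squared_draws)


@dataclass
class ContrastReport:
    parameter: str
    family: str
    groups: tuple[str, str]
    diff_ci: tuple[float, float]
    diff_mean: float
    significant: bool
    group_cis: tuple[tuple[float, float], tuple[float, float]]


def _predict(family: str, params: np.ndarray, x: np.ndarray) -> np.ndarray:
    if family == "poly1":
        return params[0] * x + params[1]
    if family == "exp1":
        return params[0] * np.exp(params[1] * x)
    if family == "power1":
        return params[0] * np.power(x, params[1])
    raise ParameterError(f"unknown family {family!r}; choose from {FAMILIES}")


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _init_params(family: str, x: np.ndarray, y: np.ndarray, rng=None) -> np.ndarray:
    """Log-space initialization for the nonlinear families."""
    pos = y > 0
    jitter = 1.0 if rng is None else float(np.exp(rng.normal(0.0, 0.1)))
    if family == "exp1":
        if pos.sum() >= 2:
            b, loga = np.polyfit(x[pos], np.log(y[pos]), 1)
            return np.array([np.exp(loga) * jitter, b])
        return np.array([max(y[0], 1e-3) * jitter, -0.001])
    if family == "power1":
        if pos.sum() >= 2:
            b, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
            return np.array([np.exp(loga) * jitter, b])
        return np.array([max(y[0], 1e-3) * jitter, -0.1])
    raise ParameterError(family)


def _fit_one(family: str, x: np.ndarray, y: np.ndarray, rng=None) -> ModelFit:
    if family == "poly1":
        p1, p2 = np.polyfit(x, y, 1)
        params = np.array([p1, p2])
    else:
        p0 = _init_params(family, x, y, rng)
        f = (lambda x, a, b: a * np.exp(b * x)) if family == "exp1" else (lambda x, a, b: a * np.power(x, b))
        params, _ = curve_fit(f, x, y, p0=p0, maxfev=5000)
        params = np.asarray(params, dtype=float)
    return ModelFit(family, params, _r_squared(y, _predict(family, params, x)))


def bootstrap_fit(
    series: GroupSeries,
    family: str = "poly1",
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    _draw_indices: np.ndarray | None = None,
) -> BootstrapFitResult:
    """Participant bootstrap of a learning-curve fit.

    Each draw resamples participants with replacement to the original
    group size, averages across participants per trial (NaN-aware) and
    refits; percentile 2.5/97.5 intervals summarize the draws.  The point
    estimate fits the unresampled group mean.  A diverging nonlinear draw
    is refit from a perturbed start; more than 5% failed draws is an
    error.
    """
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}; choose from {FAMILIES}")
    if series.n_participants < 2:
        raise ParameterError("bootstrap needs at least 2 participants")
    if series.n_trials < 3:
        raise ParameterError("bootstrap needs at least 3 trials")
    if rng is None:
        rng = np.random.default_rng(seed)

    P, T = series.n_participants, series.n_trials
    x = np.arange(1, T + 1, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        point_mean = np.nanmean(series.values, axis=0)
    if np.any(~np.isfinite(point_mean)):
        raise DataError("some trials have no finite value in any participant")
    point = _fit_one(family, x, point_mean)

    if _draw_indices is None:
        _draw_indices = rng.integers(0, P, size=(n_boot, P))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(series.values[_draw_indices], axis=1)  # (n_boot, T)

    n_boot = len(_draw_indices)
    params = np.full((n_boot, 2), np.nan)
    r2 = np.full(n_boot, np.nan)
    n_failed = 0
    if family == "poly1":
        A = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(A, means.T, rcond=None)  # (2, n_boot)
        params = beta.T
        resid = means - params @ A.T
        ss_tot = np.sum((means - means.mean(axis=1, keepdims=True)) ** 2, axis=1)
        r2 = 1.0 - np.sum(resid**2, axis=1) / np.where(ss_tot > 0, ss_tot, np.nan)
        r2 = np.where(np.isnan(r2), 1.0, r2)
    else:
        for i in range(n_boot):
            fit = None
            for attempt in range(4):
                try:
                    fit = _fit_one(family, x, means[i], rng if attempt else None)
                    break
                except (RuntimeError, ValueError):
                    continue
            if fit is None:
                n_failed += 1
                continue
            params[i] = fit.params
            r2[i] = fit.r_squared
        if n_failed > 0.05 * n_boot:
            raise FitError(f"{n_failed}/{n_boot} bootstrap draws failed to fit {family}")
        ok = np.isfinite(r2)
        params, r2 = params[ok], r2[ok]

    names = PARAM_NAMES[family]
    ci = {names[k]: tuple(np.percentile(params[:, k], [2.5, 97.5])) for k in range(2)}
    ci["r_squared"] = tuple(np.percentile(r2, [2.5, 97.5]))
    return BootstrapFitResult(family, series.group, point, params, r2, ci, n_failed, seed)


def compare_families(
    series: GroupSeries,
    families=FAMILIES,
    n_boot: int = 1000,
    seed: int | None = None,
):
    """Goodness-of-fit comparison across curve families.

    All families are fit to the *same* bootstrap draws; families are
    ranked by mean r-squared and CI overlap is reported (overlapping
    intervals mean no family is declared significantly better).
    """
    families = list(families)
    if len(families) < 2:
        raise ParameterError("need at least 2 families to compare")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, series.n_participants, size=(n_boot, series.n_participants))
    results = {fam: bootstrap_fit(series, fam, n_boot, seed=seed, rng=rng, _draw_indices=draws)
               for fam in families}
    summary = []
    for fam, res in results.items():
        summary.append(
            {
                "family": fam,
                "mean_r_squared": float(np.mean(res.r_squared_draws)),
                "ci_lo": res.ci["r_squared"][0],
                "ci_hi": res.ci["r_squared"][1],
            }
        )
    summary.sort(key=lambda d: d["mean_r_squared"], reverse=True)
    for rank, row in enumerate(summary, start=1):
        row["rank"] = rank
    best, runner = summary[0], summary[1]
    overlap = best["ci_lo"] <= runner["ci_hi"] and runner["ci_lo"] <= best["ci_hi"]
    return {"ranking": summary, "results": results, "top_two_cis_overlap": bool(overlap)}


def group_contrast(result_a: BootstrapFitResult, result_b: BootstrapFitResult, parameter: str) -> ContrastReport:
    """Bootstrap contrast of one parameter between two groups.

    Differences are taken draw-by-draw (a - b); the contrast is
    significant when the 95% percentile interval of the difference
    excludes zero.
    """
    if result_a.family != result_b.family:
        raise ParameterError("group contrast requires matching curve families")
    names = PARAM_NAMES[result_a.family]
    if parameter not in names:
        raise ParameterError(f"parameter must be one of {names}")
    k = names.index(parameter)
    n = min(len(result_a.param_draws), len(result_b.param_draws))
    diff = result_a.param_draws[:n, k] - result_b.param_draws[:n, k]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return ContrastReport(
        parameter=parameter,
        family=result_a.family,
        groups=(result_a.group, result_b.group),
        diff_ci=(float(lo), float(hi)),
        diff_mean=float(np.mean(diff)),
        significant=bool(lo > 0 or hi < 0),
        group_cis=(result_a.ci[parameter], result_b.ci[parameter]),
    )


def baseline_correct(series: GroupSeries, baseline_values) -> GroupSeries:
    """Subtract each participant's baseline summary from their series.

    ``baseline_values`` is one scalar per participant (e.g. the mean of
    that participant's baseline trials), as an array or a mapping keyed
    by participant id.  Adding a constant to one participant's series and
    baseline leaves the corrected series unchanged.
    """
    if isinstance(baseline_values, dict):
        try:
            base = np.array([float(baseline_values[p]) for p in series.participants])
        except KeyError as e:
            raise DataError(f"missing baseline for participant {e.args[0]!r}") from None
    else:
        base = np.asarray(baseline_values, dtype=float)
        if base.shape != (series.n_participants,):
            raise DataError("need exactly one baseline value per participant")
    if np.any(~np.isfinite(base)):
        raise DataError("baseline values must be finite")
    return GroupSeries(
        values=series.values - base[:, None],
        group=series.group,
        measure=f"{series.measure}_baseline_corrected" if series.measure else "",
        participants=series.participants,
    )


def early_training_mean(series: GroupSeries, n_trials: int = 5) -> np.ndarray:
    """Per-participant mean over the first ``n_trials`` trials."""
    if series.n_trials < n_trials:
        raise DataError(f"need at least {n_trials} trials, have {series.n_trials}")
    early = series.values[:, :n_trials]
    if np.any(~np.isfinite(early)):
        raise DataError("missing values inside the early-training window")
    return early.mean(axis=1)
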