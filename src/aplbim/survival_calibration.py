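"""Estimate monthly transition probabilities from EFS/OS survival series.

Mirrors the two-step spreadsheet-solver procedure used to parameterise the
model: survival curves are first put on an integer monthly grid
(Kaplan-Meier step semantics), then the three transition probabilities are
chosen to minimise the summed percent absolute deviation between the
observed series and the series implied by the cohort recursion.

Because EFS and OS cannot separately identify death-from-stable and
death-from-event well, the default fit ties those two probabilities (the
published estimates are equal within each regimen); the untied
three-parameter form is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .inputs import TransitionProbabilities
from .synthetic_data import SurvivalSeries, deterministic_curves

__all__ = [
    "SurvivalSeries",
    "CalibrationResult",
    "monthly_grid",
    "calibration_objective",
    "calibrate",
]


@dataclass(frozen=True)
class CalibrationResult:
    fitted: TransitionProbabilities
    objective_value: float
    residuals: pd.DataFrame  # per-month observed, predicted, and deviation contributions
    converged: bool
    n_starts: int

    def __post_init__(self):
        if self.objective_value < 0:
            raise ValueError("objective_value must be non-negative")


def _step_interpolate(points: list[tuple[float, float]], months: np.ndarray) -> np.ndarray:
    """Last-observation-carried-forward evaluation of raw curve points at integer months."""
    if not points:
        raise ValueError("empty curve: at least the point (0, 1) is required")
    pts = sorted(points)
    times = np.array([t for t, _ in pts], dtype=float)
    values = np.array([v for _, v in pts], dtype=float)
    problems = []
    if times[0] != 0 or abs(values[0] - 1.0) > 1e-9:
        problems.append("curve must include the point (0, 1)")
    if np.any(times < 0):
        problems.append("times must be non-negative")
    if np.any((values < 0) | (values > 1)):
        problems.append("survival values must lie in [0, 1]")
    if np.any(np.diff(values) > 1e-12):
        problems.append("survival values must be monotone non-increasing (raw input is rejected, not repaired)")
    if problems:
        raise ValueError("invalid raw survival points: " + "; ".join(problems))
    idx = np.searchsorted(times, months, side="right") - 1
    return values[idx]


def monthly_grid(
    efs_points: list[tuple[float, float]],
    os_points: list[tuple[float, float]],
    horizon_months: int | None = None,
) -> SurvivalSeries:
    """Put raw (time, survival) readings on the integer monthly grid.

    Kaplan-Meier estimates are step functions, so evaluation carries the
    last observation forward. The grid runs to ``horizon_months`` or, by
    default, to the last observed time rounded up.
    """
    if horizon_months is None:
        t_max = max(t for t, _ in list(efs_points) + list(os_points))
        horizon_months = int(np.ceil(t_max))
    months = np.arange(horizon_months + 1)
    efs = _step_interpolate(list(efs_points), months)
    os_ = _step_interpolate(list(os_points), months)
    return SurvivalSeries(months=months, efs=efs, os=os_)


def _percent_deviations(probs: TransitionProbabilities, target: SurvivalSeries) -> pd.DataFrame:
    pred = deterministic_curves(probs, target.horizon)
    frame = pd.DataFrame(
        {
            "month": target.months,
            "efs_obs": target.efs,
            "efs_pred": pred.efs,
            "os_obs": target.os,
            "os_pred": pred.os,
        }
    )
    # months >= 1; months with observed survival 0 are excluded (denominator guard)
    live = frame["month"] >= 1
    frame["efs_dev"] = np.where(
        live & (frame["efs_obs"] > 0), np.abs(frame["efs_pred"] - frame["efs_obs"]) / frame["efs_obs"], 0.0
    )
    frame["os_dev"] = np.where(
        live & (frame["os_obs"] > 0), np.abs(frame["os_pred"] - frame["os_obs"]) / frame["os_obs"], 0.0
    )
    return frame


def _objective_fast(p_se: float, p_d: float, p_ed: float, target: SurvivalSeries) -> float:
    """Numpy hot path of the objective (no residual table)."""
    probs = TransitionProbabilities(stable_to_event=p_se, stable_to_death=p_d, event_to_death=p_ed)
    pred = deterministic_curves(probs, target.horizon)
    live = target.months >= 1
    efs_mask = live & (target.efs > 0)
    os_mask = live & (target.os > 0)
    return float(
        (np.abs(pred.efs[efs_mask] - target.efs[efs_mask]) / target.efs[efs_mask]).sum()
        + (np.abs(pred.os[os_mask] - target.os[os_mask]) / target.os[os_mask]).sum()
    )


def calibration_objective(probs: TransitionProbabilities, target: SurvivalSeries) -> float:
    """Summed percent absolute deviation of predicted EFS and OS from the target series."""
    return _objective_fast(probs.stable_to_event, probs.stable_to_death, probs.event_to_death, target)


def _unpack(x: np.ndarray, tied: bool) -> tuple[TransitionProbabilities, float]:
    """Clip a raw optimizer point into the probability simplex; return the boundary violation."""
    x = np.asarray(x, dtype=float)
    violation = float(np.sum(np.maximum(-x, 0) + np.maximum(x - 1, 0)))
    x = np.clip(x, 0.0, 1.0)
    if tied:
        p_se, p_d = x
        p_ed = p_d
    else:
        p_se, p_d, p_ed = x
    if p_se + p_d > 1.0:
        violation += p_se + p_d - 1.0
        scale = 1.0 / (p_se + p_d)
        p_se, p_d = p_se * scale, p_d * scale
        if tied:
            p_ed = p_d
    return TransitionProbabilities(stable_to_event=p_se, stable_to_death=p_d, event_to_death=p_ed), violation


def _initial_guess(target: SurvivalSeries, tied: bool) -> np.ndarray:
    """Moment-style start: monthly exit hazards from the last positive observations."""
    months, efs, os_ = target.months, target.efs, target.os
    pos_e = np.nonzero((months >= 1) & (efs > 0))[0]
    pos_o = np.nonzero((months >= 1) & (os_ > 0))[0]
    p_total = 1.0 - efs[pos_e[-1]] ** (1.0 / months[pos_e[-1]]) if len(pos_e) else 0.5
    p_d = 1.0 - os_[pos_o[-1]] ** (1.0 / months[pos_o[-1]]) if len(pos_o) else 0.5
    p_se = max(p_total - p_d, 0.0)
    return np.array([p_se, p_d] if tied else [p_se, p_d, p_d])


def calibrate(
    target: SurvivalSeries,
    starts: int = 10,
    seed: int = 0,
    tie_death_probs: bool = True,
) -> CalibrationResult:
    """Fit transition probabilities to a survival series by bound-constrained derivative-free search.

    Nelder-Mead is run from a deterministic moment-based start plus
    ``starts`` random interior points; proposals outside [0, 1] (or with
    stable-exit probability above 1) are clipped with a penalty. The best
    run is returned; ``converged`` reflects the optimizer status of that
    run (with a zero-objective short-circuit for exact fits).
    """
    tied = tie_death_probs
    ndim = 2 if tied else 3

    def objective(x: np.ndarray) -> float:
        probs, violation = _unpack(x, tied)
        return (
            _objective_fast(probs.stable_to_event, probs.stable_to_death, probs.event_to_death, target)
            + 1e3 * violation
        )

    rng = np.random.default_rng(seed)
    x0s = [_initial_guess(target, tied)]
    x0s += [rng.uniform(1e-6, 0.1, size=ndim) for _ in range(starts)]

    best = None
    for x0 in x0s:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 6000, "maxfev": 12000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all calibration starts failed")

    fitted, _ = _unpack(best.x, tied)
    frame = _percent_deviations(fitted, target)
    value = float(frame["efs_dev"].sum() + frame["os_dev"].sum())
    return CalibrationResult(
        fitted=fitted,
        objective_value=value,
        residuals=frame,
        converged=bool(best.success) or value < 1e-12,
        n_starts=len(x0s),
    )
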