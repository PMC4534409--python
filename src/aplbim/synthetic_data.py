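"""Synthetic survival inputs with the statistical structure the calibration assumes.

The calibration stage normally consumes monthly EFS/OS series read off
published Kaplan-Meier curves. This module generates such series directly
from known monthly transition probabilities — either exactly (the cohort
recursion in closed form) or with sampling noise from simulated
patient-level event histories — so that every downstream stage can be
tested against a known ground truth.

Also hosts :func:`perturbed_config`, the single-parameter perturbation
primitive used by the one-way sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .inputs import (
    ModelConfig,
    TransitionProbabilities,
    config_to_raw,
    dsa_registry,
    get_param,
    set_param_raw,
    validate_config,
)

logger = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass(frozen=True)
class SurvivalSeries:
    """Paired monthly EFS and OS proportions for one regimen, on an integer month grid from 0.

    Both curves start at 1, lie in [0, 1], are monotone non-increasing,
    and satisfy EFS <= OS pointwise (an event can only precede or coincide
    with death).
    """

    months: np.ndarray
    efs: np.ndarray
    os: np.ndarray

    def __post_init__(self):
        months = np.asarray(self.months, dtype=int)
        efs = np.asarray(self.efs, dtype=float)
        os_ = np.asarray(self.os, dtype=float)
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "efs", efs)
        object.__setattr__(self, "os", os_)
        if not (len(months) == len(efs) == len(os_)) or len(months) == 0:
            raise ValueError("months, efs and os must be equal-length, non-empty")
        if months[0] != 0 or np.any(np.diff(months) != 1):
            raise ValueError("months must be the integer grid 0, 1, 2, ...")
        problems = []
        if abs(efs[0] - 1) > _TOL or abs(os_[0] - 1) > _TOL:
            problems.append("efs(0) and os(0) must equal 1")
        for name, curve in (("efs", efs), ("os", os_)):
            if np.any(curve < -_TOL) or np.any(curve > 1 + _TOL):
                problems.append(f"{name} must lie in [0, 1]")
            if np.any(np.diff(curve) > _TOL):
                problems.append(f"{name} must be monotone non-increasing")
        if np.any(efs > os_ + _TOL):
            problems.append("efs must not exceed os")
        if problems:
            raise ValueError("invalid survival series: " + "; ".join(problems))

    @property
    def horizon(self) -> int:
        return int(self.months[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months, "efs": self.efs, "os": self.os})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalSeries":
        frame = frame.sort_values("month")
        return cls(frame["month"].to_numpy(), frame["efs"].to_numpy(), frame["os"].to_numpy())


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for one synthetic trial arm."""

    transition_probabilities: TransitionProbabilities
    n_patients: int = 500
    horizon_months: int = 54  # follow-up span of the source trial's curves
    random_seed: int = 0
    noise_mode: Literal["deterministic", "sampled"] = "sampled"

    def __post_init__(self):
        if self.horizon_months < 1:
            raise ValueError("horizon_months must be >= 1")
        if self.noise_mode == "sampled" and self.n_patients < 1:
            raise ValueError("n_patients must be >= 1 when sampling")


def deterministic_curves(probs: TransitionProbabilities, horizon_months: int) -> SurvivalSeries:
    """Exact EFS/OS curves implied by the monthly transition probabilities.

    EFS(t) = (1 - p_se - p_sd)^t. OS(t) = S(t) + E(t) where the stable and
    event occupancies follow the monthly cohort recursion
    S(t+1) = S(t)(1 - p_se - p_sd), E(t+1) = E(t)(1 - p_ed) + S(t) p_se.
    """
    p_se, p_sd, p_ed = probs.stable_to_event, probs.stable_to_death, probs.event_to_death
    months = np.arange(horizon_months + 1)
    stay = 1.0 - p_se - p_sd
    efs = stay**months
    os_ = np.empty(horizon_months + 1)
    s, e = 1.0, 0.0
    os_[0] = 1.0
    for t in range(1, horizon_months + 1):
        e = e * (1.0 - p_ed) + s * p_se
        s = s * stay
        os_[t] = s + e
    return SurvivalSeries(months=months, efs=efs, os=os_)


def sampled_curves(spec: SyntheticCohortSpec) -> tuple[SurvivalSeries, pd.DataFrame]:
    """Simulate patient-level event histories and return the empirical step curves.

    Each patient draws a geometric waiting time to leaving the stable
    state (event or death, split by the conditional probability), and —
    if the exit was a non-fatal event — a further geometric time from
    event to death. There is no censoring: every patient is observed to
    event/death or the horizon. The returned series is the empirical
    survival proportion at each month, which for uncensored data equals
    the Kaplan-Meier step function.
    """
    if spec.noise_mode != "sampled":
        raise ValueError("sampled_curves requires noise_mode='sampled'")
    p = spec.transition_probabilities
    rng = np.random.default_rng(spec.random_seed)
    n = spec.n_patients
    p_exit = p.stable_to_event + p.stable_to_death

    if p_exit > 0:
        exit_month = rng.geometric(min(p_exit, 1.0), size=n).astype(float)
        died_on_exit = rng.random(n) < (p.stable_to_death / p_exit)
    else:
        exit_month = np.full(n, np.inf)
        died_on_exit = np.zeros(n, dtype=bool)

    death_month = np.full(n, np.inf)
    death_month[died_on_exit] = exit_month[died_on_exit]
    had_event = np.isfinite(exit_month) & ~died_on_exit
    if had_event.any():
        if p.event_to_death > 0:
            post = rng.geometric(p.event_to_death, size=int(had_event.sum())).astype(float)
            death_month[had_event] = exit_month[had_event] + post
        # p_ed == 0: event patients never die

    months = np.arange(spec.horizon_months + 1)
    efs = (exit_month[None, :] > months[:, None]).mean(axis=1)
    os_ = (death_month[None, :] > months[:, None]).mean(axis=1)
    patients = pd.DataFrame(
        {
            "patient": np.arange(n),
            "event_month": np.where(had_event, exit_month, np.nan),
            "death_month": np.where(np.isfinite(death_month), death_month, np.nan),
        }
    )
    return SurvivalSeries(months=months, efs=efs, os=os_), patients


def perturbed_config(base: ModelConfig, parameter: str, factor: float) -> ModelConfig:
    """Return a copy of ``base`` with one registered scalar multiplied by ``factor``.

    Probability-typed parameters are clamped back into [0, 1] with a
    logged warning. Unknown parameter names are rejected.
    """
    registry = {p.name: p for p in dsa_registry()}
    if parameter not in registry:
        raise KeyError(f"unknown DSA parameter: {parameter!r}")
    raw = config_to_raw(base)
    value = get_param(raw, parameter) * factor
    if registry[parameter].is_probability and not 0.0 <= value <= 1.0:
        clamped = min(max(value, 0.0), 1.0)
        logger.warning("clamping %s from %.6g to %.6g", parameter, value, clamped)
        value = clamped
    set_param_raw(raw, parameter, value)
    return validate_config(raw)
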