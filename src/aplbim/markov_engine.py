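"""Monthly three-state cohort engine: stable disease -> disease event -> death.

Cohorts of fractional patients are propagated through the chain with
constant monthly transition probabilities. The calendar grid runs over the
budget horizon (36 months = 3 years by default); under the mid-year entry
correction each annual cohort enters at calendar month 7, 19 or 31, so a
cohort contributes 6, 18 or 30 cycles to the horizon. Treatment-phase
bookkeeping (induction / consolidation / maintenance / post-treatment)
follows the cohort's months on study and drives the cost engine; patients
who have a disease event discontinue first-line treatment, switch to the
other regimen as second line, and remain in the event state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inputs import PhaseSchedule, RegimenSpec, TransitionProbabilities
from .synthetic_data import SurvivalSeries

STATES = ("stable", "event", "dead")

_CONSERVATION_TOL = 1e-9


def entry_month_for_year(year: int) -> int:
    """Calendar month at which the cohort of entry-year ``year`` starts (mid-year correction)."""
    return 12 * (year - 1) + 7


def step(
    occupancy: np.ndarray, probs: TransitionProbabilities
) -> tuple[np.ndarray, float, float]:
    """One monthly cycle; returns the new (stable, event, dead) vector and incident flows."""
    stable, event, dead = occupancy
    new_events = stable * probs.stable_to_event
    deaths = stable * probs.stable_to_death + event * probs.event_to_death
    new = np.array(
        [
            stable * (1.0 - probs.stable_to_event - probs.stable_to_death),
            event * (1.0 - probs.event_to_death) + new_events,
            dead + deaths,
        ]
    )
    return new, float(new_events), float(deaths)


def phase_of(treatment_month: int, phases: PhaseSchedule) -> tuple[str, int]:
    """Phase name and 1-based cycle within the phase for a given month on study."""
    if treatment_month < 1:
        raise ValueError("treatment_month is 1-based")
    if treatment_month <= phases.induction_months:
        return "induction", treatment_month
    m = treatment_month - phases.induction_months
    if m <= phases.consolidation_months:
        return "consolidation", m
    m -= phases.consolidation_months
    if m <= phases.maintenance_months:
        return "maintenance", m
    return "post_treatment", m - phases.maintenance_months


@dataclass
class CohortTrace:
    """State occupancy and incident flows of one entering cohort on the calendar grid.

    Arrays are indexed by calendar month 1..horizon (index 0 unused).
    ``stable_start`` is the stable occupancy during month m (before that
    month's transition) — the quantity treatment costs weight.
    ``stable``/``event``/``dead`` are end-of-month occupancies.
    """

    regimen: str
    cohort_size: float
    entry_month: int
    horizon: int
    stable_start: np.ndarray
    stable: np.ndarray
    event: np.ndarray
    dead: np.ndarray
    incident_events: np.ndarray
    incident_deaths: np.ndarray
    phase: list[str | None]
    phase_cycle: np.ndarray

    def months_on_study(self, month: int) -> int:
        """1-based month on study at calendar ``month`` (0 before entry)."""
        return max(month - self.entry_month + 1, 0)

    def check_conservation(self) -> None:
        for m in range(self.entry_month, self.horizon + 1):
            total = self.stable[m] + self.event[m] + self.dead[m]
            if abs(total - self.cohort_size) > _CONSERVATION_TOL * max(1.0, self.cohort_size):
                raise AssertionError(f"cohort mass not conserved at month {m}: {total} != {self.cohort_size}")

    def survival_series(self) -> SurvivalSeries:
        """Model-implied EFS/OS on the months-on-study grid (cross-check against the synthetic recursion)."""
        if self.cohort_size <= 0:
            raise ValueError("survival series undefined for an empty cohort")
        n = self.horizon - self.entry_month + 1
        months = np.arange(n + 1)
        efs = np.empty(n + 1)
        os_ = np.empty(n + 1)
        efs[0] = os_[0] = 1.0
        for k in range(1, n + 1):
            m = self.entry_month + k - 1
            efs[k] = self.stable[m] / self.cohort_size
            os_[k] = (self.stable[m] + self.event[m]) / self.cohort_size
        return SurvivalSeries(months=months, efs=efs, os=os_)


def run_cohort(
    regimen: RegimenSpec,
    cohort_size: float,
    entry_month: int,
    horizon: int = 36,
    probs: TransitionProbabilities | None = None,
) -> CohortTrace:
    """Propagate one entering cohort from ``entry_month`` to the end of the horizon.

    All patients enter in stable disease / induction; the treatment phase
    advances with months on study per the regimen's schedule; the trace is
    truncated at the horizon.
    """
    if entry_month > horizon:
        raise ValueError(f"entry_month {entry_month} beyond horizon {horizon}")
    if entry_month < 1:
        raise ValueError("entry_month must be >= 1")
    if cohort_size < 0:
        raise ValueError("cohort_size must be non-negative")
    probs = probs or regimen.transition_probabilities

    shape = horizon + 1
    trace = CohortTrace(
        regimen=regimen.label,
        cohort_size=cohort_size,
        entry_month=entry_month,
        horizon=horizon,
        stable_start=np.zeros(shape),
        stable=np.zeros(shape),
        event=np.zeros(shape),
        dead=np.zeros(shape),
        incident_events=np.zeros(shape),
        incident_deaths=np.zeros(shape),
        phase=[None] * shape,
        phase_cycle=np.zeros(shape, dtype=int),
    )
    occ = np.array([cohort_size, 0.0, 0.0])
    for m in range(entry_month, horizon + 1):
        tm = m - entry_month + 1
        name, cycle = phase_of(tm, regimen.phases)
        trace.phase[m] = name
        trace.phase_cycle[m] = cycle
        trace.stable_start[m] = occ[0]
        occ, new_events, deaths = step(occ, probs)
        trace.stable[m], trace.event[m], trace.dead[m] = occ
        trace.incident_events[m] = new_events
        trace.incident_deaths[m] = deaths
    trace.check_conservation()
    return trace


@dataclass
class ScenarioOccupancy:
    """Elementwise sum of cohort traces for one scenario, plus cumulative entries."""

    horizon: int
    stable: np.ndarray
    event: np.ndarray
    dead: np.ndarray
    entered: np.ndarray  # cumulative patients entered by end of each month

    def year_end_headcounts(self, display: bool = True) -> pd.DataFrame:
        """State occupancy at each year end (months 12, 24, 36), rounded for display."""
        year_ends = [m for m in range(12, self.horizon + 1, 12)]
        data = {}
        for m in year_ends:
            col = f"year_{m // 12}"
            vals = [self.stable[m], self.event[m], self.dead[m]]
            data[col] = [round(v) for v in vals] if display else vals
        return pd.DataFrame(data, index=list(STATES))


def overlay(traces: list[CohortTrace]) -> ScenarioOccupancy:
    """Sum cohort traces that share one calendar grid."""
    if not traces:
        raise ValueError("no traces to overlay")
    horizon = traces[0].horizon
    if any(t.horizon != horizon for t in traces):
        raise ValueError("traces do not share the same calendar grid")
    out = ScenarioOccupancy(
        horizon=horizon,
        stable=np.zeros(horizon + 1),
        event=np.zeros(horizon + 1),
        dead=np.zeros(horizon + 1),
        entered=np.zeros(horizon + 1),
    )
    for t in traces:
        out.stable += t.stable
        out.event += t.event
        out.dead += t.dead
        out.entered[t.entry_month :] += t.cohort_size
    return out
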