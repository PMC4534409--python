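"""Convert cohort traces into euro costs by component and calendar year.

Components: first-line pharmacy, first-line medical, adverse events,
disease event (one-time work-up on each incident event), and second-line
therapy (the opposite regimen's full course, spread monthly and truncated
at the horizon). Costs weight the stable occupancy at the start of each
cycle; patients who have had an event accrue second-line costs only.
All amounts are undiscounted euros; display rounding is to the nearest
€100 and happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inputs import AEUnitCosts, ModelConfig, RegimenSpec
from .markov_engine import CohortTrace, run_cohort, entry_month_for_year

COMPONENTS = ("pharmacy", "medical", "adverse_event", "disease_event", "second_line")

#: one-month lag between an incident event and the first second-line cycle
SECOND_LINE_START_LAG = 1


def round_eur100(x: float) -> float:
    """Display rounding to the nearest €100."""
    return round(x / 100.0) * 100.0


@dataclass
class CostBreakdown:
    """Monthly euro flows per component on the calendar grid (index 0 unused)."""

    horizon: int
    monthly: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for comp in COMPONENTS:
            self.monthly.setdefault(comp, np.zeros(self.horizon + 1))

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        if self.horizon != other.horizon:
            raise ValueError("cannot add breakdowns on different horizons")
        out = CostBreakdown(self.horizon)
        for comp in COMPONENTS:
            out.monthly[comp] = self.monthly[comp] + other.monthly[comp]
        return out

    def yearly(self, component: str) -> np.ndarray:
        arr = self.monthly[component]
        n_years = self.horizon // 12
        return np.array([arr[12 * y + 1 : 12 * (y + 1) + 1].sum() for y in range(n_years)])

    def cumulative(self, component: str) -> float:
        return float(self.monthly[component].sum())

    def yearly_total(self) -> np.ndarray:
        return sum(self.yearly(comp) for comp in COMPONENTS)

    def grand_total(self) -> float:
        return float(sum(self.cumulative(comp) for comp in COMPONENTS))

    def to_frame(self, display: bool = False) -> pd.DataFrame:
        """Component x year table plus cumulative column and total row."""
        rows = []
        for comp in COMPONENTS:
            rows.append([*self.yearly(comp), self.cumulative(comp)])
        rows.append([*self.yearly_total(), self.grand_total()])
        n_years = self.horizon // 12
        frame = pd.DataFrame(
            rows,
            index=[*COMPONENTS, "total"],
            columns=[*(f"year_{y + 1}" for y in range(n_years)), "cumulative"],
        )
        return frame.map(round_eur100) if display else frame


def expected_ae_cost(phase_key: str, regimen: RegimenSpec, ae_unit_costs: AEUnitCosts) -> float:
    """Expected adverse-event cost for one patient spending the given phase cycle on treatment.

    ``phase_key`` is one of ``induction``, ``consolidation_1``,
    ``consolidation_2``, ``consolidation_3``. Sums probability x unit cost
    over the four costed grade 3/4 events.
    """
    probs = getattr(regimen.ae_probabilities, phase_key)
    costs = ae_unit_costs.induction if phase_key == "induction" else ae_unit_costs.consolidation
    return sum(
        getattr(probs, ev) * getattr(costs, ev)
        for ev in ("neutropenia", "thrombocytopenia", "hepatic_toxicity", "fever_unknown_origin")
    )


def _ae_phase_key(phase: str, cycle: int) -> str | None:
    """AE profile slot for a treatment month, if any (induction + first three consolidation cycles)."""
    if phase == "induction":
        return "induction"
    if phase == "consolidation" and cycle <= 3:
        return f"consolidation_{cycle}"
    return None


def first_line_costs(trace: CohortTrace, regimen: RegimenSpec, ae_unit_costs: AEUnitCosts) -> CostBreakdown:
    """Pharmacy, medical and adverse-event costs of the stable population on first-line treatment.

    Phase pharmacy totals are spread uniformly over the cycles of the
    phase, so a patient completing treatment inside the horizon accrues
    exactly the first-line pharmacy total. Post-treatment monitoring
    (per-cycle medical) accrues for stable patients through the horizon.
    """
    out = CostBreakdown(trace.horizon)
    ph, med, phases = regimen.pharmacy, regimen.medical, regimen.phases
    for m in range(trace.entry_month, trace.horizon + 1):
        w = trace.stable_start[m]
        if w == 0:
            continue
        phase = trace.phase[m]
        if phase == "induction":
            out.monthly["pharmacy"][m] += w * ph.induction_total / phases.induction_months
            out.monthly["medical"][m] += w * med.induction_per_cycle
        elif phase == "consolidation":
            out.monthly["pharmacy"][m] += w * ph.consolidation_total / phases.consolidation_months
            out.monthly["medical"][m] += w * med.consolidation_per_cycle
        elif phase == "maintenance":
            out.monthly["pharmacy"][m] += w * ph.maintenance_monthly
            out.monthly["medical"][m] += w * med.maintenance_per_cycle
        else:  # post_treatment
            out.monthly["medical"][m] += w * med.post_treatment_per_cycle
        key = _ae_phase_key(phase, int(trace.phase_cycle[m]))
        if key is not None:
            out.monthly["adverse_event"][m] += w * expected_ae_cost(key, regimen, ae_unit_costs)
    return out


def course_cost(regimen: RegimenSpec) -> float:
    """Total cost of one full treatment course: first-line pharmacy plus on-treatment medical.

    Used as the second-line course total when the regimen is given after
    failure of the other one, unless an explicit ``second_line_total``
    override is configured.
    """
    if regimen.second_line_total is not None:
        return regimen.second_line_total
    med, phases = regimen.medical, regimen.phases
    return (
        regimen.first_line_pharmacy_total
        + med.induction_per_cycle * phases.induction_months
        + med.consolidation_per_cycle * phases.consolidation_months
        + med.maintenance_per_cycle * phases.maintenance_months
    )


def event_and_second_line_costs(
    trace: CohortTrace, regimen: RegimenSpec, second_line_regimen: RegimenSpec
) -> CostBreakdown:
    """One-time disease-event cost plus the second-line course of the opposite regimen.

    Each incident event incurs the one-time disease-event medical cost in
    its month; the switched patients then accrue the second-line course,
    spread uniformly over its treatment duration starting the following
    month and truncated at the horizon.
    """
    out = CostBreakdown(trace.horizon)
    sl_total = course_cost(second_line_regimen)
    sl_months = second_line_regimen.phases.treatment_months
    sl_monthly = sl_total / sl_months if sl_months else 0.0
    for m in range(trace.entry_month, trace.horizon + 1):
        flow = trace.incident_events[m]
        if flow == 0:
            continue
        out.monthly["disease_event"][m] += flow * regimen.disease_event_cost
        first = m + SECOND_LINE_START_LAG
        last = min(first + sl_months - 1, trace.horizon)
        for mm in range(first, last + 1):
            out.monthly["second_line"][mm] += flow * sl_monthly
    return out


def cohort_costs(
    trace: CohortTrace,
    regimen: RegimenSpec,
    second_line_regimen: RegimenSpec,
    ae_unit_costs: AEUnitCosts,
) -> CostBreakdown:
    """All five cost components for one cohort trace."""
    return first_line_costs(trace, regimen, ae_unit_costs) + event_and_second_line_costs(
        trace, regimen, second_line_regimen
    )


def per_patient_costs(config: ModelConfig, regimen_key: str, entry_month: int | None = None) -> CostBreakdown:
    """Cost breakdown for a single patient entering mid-year-1 on the given regimen."""
    entry = entry_month_for_year(1) if entry_month is None else entry_month
    regimen = config.regimens[regimen_key]
    other_key = "atra_chemo" if regimen_key == "ato_atra" else "ato_atra"
    trace = run_cohort(regimen, cohort_size=1.0, entry_month=entry, horizon=config.horizon_months)
    return cohort_costs(trace, regimen, config.regimens[other_key], config.ae_unit_costs)
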