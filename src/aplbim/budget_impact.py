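"""Scenario construction and the yearly budget impact.

The reference (pre-ATO) scenario treats every newly eligible patient with
ATRA+chemotherapy. The new (post-ATO) scenario moves a growing share of
each year's entering cohort to ATO+ATRA per the uptake schedule. The
budget impact is the difference in total scenario cost per calendar year;
the percent increase uses the same-year reference-scenario total as
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cost_engine import CostBreakdown, cohort_costs, round_eur100
from .inputs import ModelConfig, REGIMEN_KEYS, eligible_cohort
from .markov_engine import ScenarioOccupancy, entry_month_for_year, overlay, run_cohort


@dataclass(frozen=True)
class Scenario:
    """Named market-share split of each entry-year cohort over the regimens."""

    name: str
    shares: dict[int, dict[str, float]]  # entry year -> regimen key -> share of new patients

    def __post_init__(self):
        for year, split in self.shares.items():
            for key, share in split.items():
                if key not in REGIMEN_KEYS:
                    raise ValueError(f"unknown regimen {key!r} in scenario {self.name!r}")
                if not 0.0 <= share <= 1.0:
                    raise ValueError(f"share out of [0, 1] for {key!r}, year {year}")
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ValueError(f"scenario {self.name!r} shares for year {year} do not sum to 1")


def reference_scenario(config: ModelConfig) -> Scenario:
    """Pre-ATO world: ATRA+chemotherapy holds the whole market."""
    years = config.horizon_months // 12
    return Scenario("pre-ATO", {y: {"ato_atra": 0.0, "atra_chemo": 1.0} for y in range(1, years + 1)})


def new_scenario(config: ModelConfig) -> Scenario:
    """Post-ATO world: the uptake schedule's share of new patients starts ATO+ATRA."""
    years = config.horizon_months // 12
    return Scenario(
        "post-ATO",
        {
            y: {"ato_atra": config.uptake.share(y), "atra_chemo": 1.0 - config.uptake.share(y)}
            for y in range(1, years + 1)
        },
    )


def scenario_breakdown(scenario: Scenario, config: ModelConfig) -> tuple[CostBreakdown, ScenarioOccupancy]:
    """Run every (entry year, regimen) cohort of a scenario; sum costs and occupancy."""
    cohort = eligible_cohort(config.population).exact
    costs = CostBreakdown(config.horizon_months)
    traces = []
    for year, split in sorted(scenario.shares.items()):
        entry = entry_month_for_year(year)
        for key, share in split.items():
            if share == 0.0 or cohort == 0.0:
                continue
            regimen = config.regimens[key]
            other = config.regimens["atra_chemo" if key == "ato_atra" else "ato_atra"]
            trace = run_cohort(regimen, cohort_size=cohort * share, entry_month=entry, horizon=config.horizon_months)
            traces.append(trace)
            costs = costs + cohort_costs(trace, regimen, other, config.ae_unit_costs)
    if traces:
        occupancy = overlay(traces)
    else:
        h = config.horizon_months
        occupancy = ScenarioOccupancy(h, np.zeros(h + 1), np.zeros(h + 1), np.zeros(h + 1), np.zeros(h + 1))
    return costs, occupancy


def scenario_yearly_cost(scenario: Scenario, config: ModelConfig) -> np.ndarray:
    """Total scenario cost per calendar year (euros, unrounded)."""
    costs, _ = scenario_breakdown(scenario, config)
    return costs.yearly_total()


@dataclass
class BudgetImpactResult:
    """Yearly scenario totals, net impact and percent increase, plus state occupancies."""

    years: np.ndarray
    pre_total: np.ndarray
    post_total: np.ndarray
    pre_occupancy: ScenarioOccupancy
    post_occupancy: ScenarioOccupancy

    @property
    def net(self) -> np.ndarray:
        return self.post_total - self.pre_total

    @property
    def percent_increase(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.pre_total > 0, self.net / self.pre_total, np.nan)

    @property
    def average_net(self) -> float:
        return float(self.net.mean())

    def to_frame(self, display: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "pre_ato_total": self.pre_total,
                "post_ato_total": self.post_total,
                "net_impact": self.net,
                "percent_increase": self.percent_increase,
            },
            index=[f"year_{y}" for y in self.years],
        )
        if display:
            for col in ("pre_ato_total", "post_ato_total", "net_impact"):
                frame[col] = frame[col].map(round_eur100)
            frame["percent_increase"] = (frame["percent_increase"] * 100).round(1)
        return frame


def budget_impact(config: ModelConfig) -> BudgetImpactResult:
    """Run both scenarios on the base population and report the yearly budget impact."""
    pre_costs, pre_occ = scenario_breakdown(reference_scenario(config), config)
    post_costs, post_occ = scenario_breakdown(new_scenario(config), config)
    years = np.arange(1, config.horizon_months // 12 + 1)
    return BudgetImpactResult(
        years=years,
        pre_total=pre_costs.yearly_total(),
        post_total=post_costs.yearly_total(),
        pre_occupancy=pre_occ,
        post_occupancy=post_occ,
    )
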