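"""Model inputs: configuration schema, validation, and the eligible-population funnel.

The budget-impact model is driven entirely by a structured configuration
holding the population funnel, the per-regimen treatment schedules, the
monthly transition probabilities, all unit costs, the adverse-event
profiles, and the uptake (market-share) schedule of the new regimen.
Every input is validated on load; violations are reported together with
the full dotted field path rather than one at a time.

Monetary amounts are euros, undiscounted. Probabilities are per monthly
cycle. The funnel is carried at full precision; integer patient counts
appear only in display output.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

SCHEMA_VERSION = 1

AE_EVENTS = ("neutropenia", "thrombocytopenia", "hepatic_toxicity", "fever_unknown_origin")
AE_PHASES = ("induction", "consolidation_1", "consolidation_2", "consolidation_3")
REGIMEN_KEYS = ("ato_atra", "atra_chemo")


class ConfigError(ValueError):
    """Raised when a configuration fails to parse or violates an invariant.

    ``problems`` lists every offending field (dotted path + message), not
    just the first one found.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid model configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


class PopulationFunnel(BaseModel):
    """National population narrowed down to patients eligible for first-line therapy."""

    total_population: float = Field(ge=0)
    aml_incidence_per_100k: float = Field(ge=0, description="annual age-adjusted AML incidence per 100,000")
    apl_fraction: float = Field(ge=0, le=1, description="proportion of AML that is APL")
    low_int_risk_fraction: float = Field(ge=0, le=1, description="proportion of APL at low/intermediate risk")
    treated_fraction: float = Field(ge=0, le=1, description="proportion of eligible patients receiving first-line treatment")


class TransitionProbabilities(BaseModel):
    """Monthly transition probabilities of the three-state chain."""

    stable_to_event: float = Field(ge=0, le=1)
    stable_to_death: float = Field(ge=0, le=1)
    event_to_death: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _leaving_stable_at_most_one(self) -> "TransitionProbabilities":
        if self.stable_to_event + self.stable_to_death > 1 + 1e-12:
            raise ValueError("stable_to_event + stable_to_death must be <= 1")
        return self


class PhaseSchedule(BaseModel):
    """Treatment-phase durations in monthly cycles."""

    induction_months: int = Field(ge=1)
    consolidation_months: int = Field(ge=0)
    maintenance_months: int = Field(ge=0)

    @property
    def treatment_months(self) -> int:
        return self.induction_months + self.consolidation_months + self.maintenance_months


class AEPhaseProbabilities(BaseModel):
    """Probability of each grade 3/4 adverse event within one treatment phase."""

    neutropenia: float = Field(ge=0, le=1)
    thrombocytopenia: float = Field(ge=0, le=1)
    hepatic_toxicity: float = Field(ge=0, le=1)
    fever_unknown_origin: float = Field(ge=0, le=1)


class AEProfile(BaseModel):
    """Adverse-event probabilities by treatment phase (induction + first three consolidation cycles)."""

    induction: AEPhaseProbabilities
    consolidation_1: AEPhaseProbabilities
    consolidation_2: AEPhaseProbabilities
    consolidation_3: AEPhaseProbabilities


class AEPhaseCosts(BaseModel):
    """Euro cost per adverse event, by event."""

    neutropenia: float = Field(ge=0)
    thrombocytopenia: float = Field(ge=0)
    hepatic_toxicity: float = Field(ge=0)
    fever_unknown_origin: float = Field(ge=0)


class AEUnitCosts(BaseModel):
    induction: AEPhaseCosts
    consolidation: AEPhaseCosts


class PharmacyAllocation(BaseModel):
    """How the first-line pharmacy total is allocated across treatment phases.

    Phase totals are spread uniformly over the cycles of the phase;
    maintenance is given directly as a monthly amount. When
    ``first_line_total`` is present it must equal the sum of the
    allocations (checked at the regimen level, where the maintenance
    duration is known).
    """

    induction_total: float = Field(ge=0)
    consolidation_total: float = Field(ge=0)
    maintenance_monthly: float = Field(ge=0, default=0.0)
    first_line_total: Optional[float] = Field(ge=0, default=None)


class MedicalCosts(BaseModel):
    """Per-cycle medical (non-pharmacy) costs for stable-disease patients."""

    induction_per_cycle: float = Field(ge=0)
    consolidation_per_cycle: float = Field(ge=0)
    maintenance_per_cycle: float = Field(ge=0, default=0.0)
    post_treatment_per_cycle: float = Field(ge=0)


class RegimenSpec(BaseModel):
    """Everything that characterises one first-line regimen."""

    label: str
    phases: PhaseSchedule
    transition_probabilities: TransitionProbabilities
    pharmacy: PharmacyAllocation
    medical: MedicalCosts
    disease_event_cost: float = Field(ge=0)
    second_line_total: Optional[float] = Field(ge=0, default=None)
    ae_probabilities: AEProfile

    @model_validator(mode="after")
    def _pharmacy_allocation_consistent(self) -> "RegimenSpec":
        if self.pharmacy.first_line_total is not None:
            allocated = (
                self.pharmacy.induction_total
                + self.pharmacy.consolidation_total
                + self.pharmacy.maintenance_monthly * self.phases.maintenance_months
            )
            if abs(allocated - self.pharmacy.first_line_total) > 0.01:
                raise ValueError(
                    f"pharmacy allocations sum to {allocated:.2f}, "
                    f"not the declared first-line total {self.pharmacy.first_line_total:.2f}"
                )
        return self

    @property
    def first_line_pharmacy_total(self) -> float:
        return (
            self.pharmacy.induction_total
            + self.pharmacy.consolidation_total
            + self.pharmacy.maintenance_monthly * self.phases.maintenance_months
        )


class UptakeSchedule(BaseModel):
    """Market share of new patients starting the new (ATO+ATRA) regimen, per entry year."""

    year1: float = Field(ge=0, le=1)
    year2: float = Field(ge=0, le=1)
    year3: float = Field(ge=0, le=1)

    def share(self, year: int) -> float:
        return (self.year1, self.year2, self.year3)[year - 1]


class Regimens(BaseModel):
    ato_atra: RegimenSpec
    atra_chemo: RegimenSpec

    def __getitem__(self, key: str) -> RegimenSpec:
        if key not in REGIMEN_KEYS:
            raise KeyError(key)
        return getattr(self, key)


class ModelConfig(BaseModel):
    """Complete, validated input set for the budget-impact model."""

    schema_version: int = SCHEMA_VERSION
    population: PopulationFunnel
    uptake: UptakeSchedule
    horizon_months: int = Field(default=36, ge=1)
    regimens: Regimens
    ae_unit_costs: AEUnitCosts


class EligibleCohort(NamedTuple):
    """Annual number of newly eligible patients; ``exact`` feeds the model, ``display`` the tables."""

    exact: float
    display: int


def eligible_cohort(funnel: PopulationFunnel) -> EligibleCohort:
    """Multiply the population funnel down to the annual eligible patient count.

    The exact (fractional) count is carried through every downstream euro
    total; the rounded integer exists only for table display.
    """
    exact = (
        funnel.total_population
        * funnel.aml_incidence_per_100k
        / 100_000.0
        * funnel.apl_fraction
        * funnel.low_int_risk_fraction
        * funnel.treated_fraction
    )
    return EligibleCohort(exact=exact, display=round(exact))


def funnel_table(funnel: PopulationFunnel) -> pd.DataFrame:
    """Population funnel in the shape of the published estimate table (display-rounded)."""
    rows = []
    n = funnel.total_population
    rows.append(("Total population", f"{funnel.total_population:,.0f}", round(n)))
    n *= funnel.aml_incidence_per_100k / 100_000.0
    rows.append(("Annual AML incidence", f"{funnel.aml_incidence_per_100k} per 100,000", round(n)))
    n *= funnel.apl_fraction
    rows.append(("Proportion of AML that is APL", f"{funnel.apl_fraction:.1%}", round(n)))
    n *= funnel.low_int_risk_fraction
    rows.append(("Low to intermediate risk", f"{funnel.low_int_risk_fraction:.0%}", round(n)))
    n *= funnel.treated_fraction
    rows.append(("Receive first-line treatment", f"{funnel.treated_fraction:.0%}", round(n)))
    return pd.DataFrame(rows, columns=["parameter", "estimated_value", "eligible_population"])


def _format_validation_error(err) -> list[str]:
    problems = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        problems.append(f"{loc}: {e['msg']}")
    return problems


def validate_config(raw: dict) -> ModelConfig:
    """Validate a raw mapping into a :class:`ModelConfig`, reporting every violation."""
    from pydantic import ValidationError

    if not isinstance(raw, dict):
        raise ConfigError(["<root>: configuration must be a mapping"])
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def load_config(path: str | Path) -> ModelConfig:
    """Read and validate a YAML model configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError([f"<parse>: {err}"]) from err
    return validate_config(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML; reloading round-trips to an equal config."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))


def base_case_config() -> ModelConfig:
    """The bundled base case: every published input of the Italian analysis."""
    text = resources.files("aplbim.data").joinpath("base_case.yaml").read_text()
    return validate_config(yaml.safe_load(text))


# --- one-way sensitivity-analysis parameter registry -------------------------

class ParamSpec(NamedTuple):
    name: str  # dotted path into the config
    is_probability: bool


def dsa_registry() -> list[ParamSpec]:
    """Every scalar input that the one-way sensitivity analysis perturbs.

    Grouped parameters (e.g. a regimen's consolidation-phase pharmacy
    total) are perturbed as one unit. Probability-typed entries are
    clamped to [0, 1] after perturbation.
    """
    params: list[ParamSpec] = [
        ParamSpec("population.total_population", False),
        ParamSpec("population.aml_incidence_per_100k", False),
        ParamSpec("population.apl_fraction", True),
        ParamSpec("population.low_int_risk_fraction", True),
        ParamSpec("population.treated_fraction", True),
        ParamSpec("uptake.year1", True),
        ParamSpec("uptake.year2", True),
        ParamSpec("uptake.year3", True),
    ]
    for reg in REGIMEN_KEYS:
        for field in ("stable_to_event", "stable_to_death", "event_to_death"):
            params.append(ParamSpec(f"regimens.{reg}.transition_probabilities.{field}", True))
        for field in ("induction_total", "consolidation_total", "maintenance_monthly"):
            params.append(ParamSpec(f"regimens.{reg}.pharmacy.{field}", False))
        for field in (
            "induction_per_cycle",
            "consolidation_per_cycle",
            "maintenance_per_cycle",
            "post_treatment_per_cycle",
        ):
            params.append(ParamSpec(f"regimens.{reg}.medical.{field}", False))
        params.append(ParamSpec(f"regimens.{reg}.disease_event_cost", False))
        for phase in AE_PHASES:
            for event in AE_EVENTS:
                params.append(ParamSpec(f"regimens.{reg}.ae_probabilities.{phase}.{event}", True))
    for phase in ("induction", "consolidation"):
        for event in AE_EVENTS:
            params.append(ParamSpec(f"ae_unit_costs.{phase}.{event}", False))
    return params


def get_param(config_or_raw, name: str) -> float:
    """Fetch a scalar by dotted path from a config (model or raw mapping)."""
    node = config_or_raw
    for part in name.split("."):
        node = node[part] if isinstance(node, dict) else getattr(node, part)
    return node


def set_param_raw(raw: dict, name: str, value: float) -> None:
    """Set a scalar by dotted path on a raw config mapping.

    Pharmacy allocation fields keep the declared first-line total in sync,
    since that total is the sum of the allocations.
    """
    parts = name.split(".")
    node = raw
    for part in parts[:-1]:
        node = node[part]
    node[parts[-1]] = value
    if parts[-2] == "pharmacy" and parts[-1] != "first_line_total" and node.get("first_line_total") is not None:
        reg = raw
        for part in parts[:-2]:
            reg = reg[part]
        maint_months = reg["phases"]["maintenance_months"]
        node["first_line_total"] = (
            node["induction_total"] + node["consolidation_total"] + node["maintenance_monthly"] * maint_months
        )


def config_to_raw(config: ModelConfig) -> dict:
    return copy.deepcopy(config.model_dump(mode="json"))
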