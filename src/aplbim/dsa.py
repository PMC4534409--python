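"""One-way deterministic sensitivity analysis with tornado ranking.

Each registered scalar input is varied to ``base x (1 - factor)`` and
``base x (1 + factor)`` with everything else held at base case, the full
scenario comparison is rerun, and the third-year net budget impact is
recorded. Parameters are ranked by the spread between their low and high
results (the tornado ordering); ties break alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .budget_impact import budget_impact
from .inputs import ModelConfig, dsa_registry
from .synthetic_data import perturbed_config


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    base_value: float
    low_result: float
    high_result: float
    base_result: float

    @property
    def spread(self) -> float:
        return abs(self.high_result - self.low_result)


def third_year_net_impact(config: ModelConfig) -> float:
    """Default DSA outcome: net budget impact in the final model year."""
    return float(budget_impact(config).net[-1])


def run_dsa(
    config: ModelConfig,
    factor: float = 0.25,
    outcome: Callable[[ModelConfig], float] = third_year_net_impact,
    parameters: list[str] | None = None,
) -> list[TornadoEntry]:
    """Perturb every registered scalar +/- ``factor`` and rank by result spread."""
    registry = [p.name for p in dsa_registry()]
    if parameters is not None:
        unknown = set(parameters) - set(registry)
        if unknown:
            raise KeyError(f"unknown DSA parameters: {sorted(unknown)}")
        registry = list(parameters)
    if not registry:
        raise ValueError("DSA registry is empty")

    from .inputs import get_param

    base_result = outcome(config)
    entries = []
    for name in registry:
        low = outcome(perturbed_config(config, name, 1.0 - factor))
        high = outcome(perturbed_config(config, name, 1.0 + factor))
        entries.append(
            TornadoEntry(
                parameter=name,
                base_value=float(get_param(config, name)),
                low_result=low,
                high_result=high,
                base_result=base_result,
            )
        )
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def tornado_frame(entries: list[TornadoEntry], top: int | None = None) -> pd.DataFrame:
    """Ranked tornado table (widest spread first)."""
    frame = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "base_value": [e.base_value for e in entries],
            "low_result": [e.low_result for e in entries],
            "high_result": [e.high_result for e in entries],
            "spread": [e.spread for e in entries],
        }
    )
    frame["rank"] = range(1, len(frame) + 1)
    return frame.head(top) if top else frame
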