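"""Scenario definitions and randomized model-instance generation.

The reference analysis consists of a base case plus one-way sensitivity
scenarios: two alternative satisfaction profiles (a constant decline per
implant lost, and a proportionally increasing decline), a grid over the
annual failure rate of a denture without implants, and a grid that pins
the repair-period satisfaction adjustment.  Each scenario is expressed as
a set of overrides on the base-case tables.

:func:`random_instance` generates structurally valid random model
configurations (monotone failure modes, bounded monotone satisfaction,
six-implant costs above four-implant costs) so that every downstream stage
can be property-tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .params import (
    CostSchedule,
    FailureRateTable,
    ModelTables,
    SatisfactionTable,
    TriangularDist,
    interpolate_failure_table,
    interpolate_satisfaction,
)

__all__ = [
    "ScenarioSpec",
    "BASE_ANCHORS",
    "base_tables",
    "paper_scenarios",
    "resolve_scenario",
    "random_instance",
]

# Base-case evidence anchors: six-/four-implant annual failure-rate
# distributions, the no-implant denture-failure assumption, satisfaction
# anchors at 6/4/2/0 implants, repair adjustment, and the cost schedule
# (euros; labor anchored at complexity factors 1.0 / 2.3 / 3.5).
BASE_ANCHORS = {
    "implant_six": TriangularDist(0.014, 0.018, 0.023),
    "implant_four": TriangularDist(0.030, 0.037, 0.046),
    "denture_six": TriangularDist(0.015, 0.026, 0.044),
    "denture_four": TriangularDist(0.022, 0.035, 0.069),
    "denture_no_implants": TriangularDist(0.01, 0.05, 0.10),
}
BASE_SATISFACTION_ANCHORS = {6: 0.89, 4: 0.89, 2: 0.84, 0: 0.63}
BASE_REPAIR_ADJUSTMENT = TriangularDist(0.8, 0.9, 0.99)
BASE_COSTS = CostSchedule(
    factors=(1.0, 2.3, 3.5),
    labor={
        "six_new": (1472.67, 2990.86, 4392.27),
        "four_new": (1130.07, 2199.98, 3190.67),
        "repair_implant": (206.68, 267.35, 323.39),
        "repair_denture": (65.19, 84.93, 103.16),
    },
    material={
        "six_new": 5070.30,
        "four_new": 4507.82,
        "repair_implant": 160.00,
        "repair_denture": 50.00,
    },
)

# Alternative satisfaction profiles (full tables, not interpolated).
SCENARIO_A_SATISFACTION = {6: 0.89, 5: 0.85, 4: 0.80, 3: 0.76, 2: 0.72, 1: 0.67, 0: 0.63}
SCENARIO_B_SATISFACTION = {6: 0.89, 5: 0.88, 4: 0.85, 3: 0.82, 2: 0.77, 1: 0.70, 0: 0.63}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of overrides on the base-case model configuration."""

    label: str
    satisfaction_scores: Mapping[int, float] | None = None
    no_implant_failure_rate: float | None = None
    fixed_repair_adjustment: float | None = None


def base_tables(horizon: int = 10) -> ModelTables:
    """The base-case model configuration, built from the evidence anchors."""
    failure = interpolate_failure_table(
        BASE_ANCHORS["implant_six"],
        BASE_ANCHORS["implant_four"],
        BASE_ANCHORS["denture_no_implants"],
        denture_six=BASE_ANCHORS["denture_six"],
        denture_four=BASE_ANCHORS["denture_four"],
    )
    satisfaction = SatisfactionTable(
        scores=interpolate_satisfaction(BASE_SATISFACTION_ANCHORS),
        repair_adjustment=BASE_REPAIR_ADJUSTMENT,
    )
    return ModelTables(
        failure=failure, satisfaction=satisfaction, costs=BASE_COSTS, horizon=horizon
    )


def paper_scenarios() -> list[ScenarioSpec]:
    """The reference scenario suite: base case plus one-way sensitivity.

    Twelve scenarios: base case, satisfaction scenarios A and B, the
    no-implant denture-failure grid {0.00, 0.06, 0.12}, and the fixed
    repair-adjustment grid {0.0, 0.2, 0.4, 0.6, 0.8, 1.0}.  Crossing each
    with the three cost-factor anchors yields the 36 reported thresholds.
    """
    scenarios = [
        ScenarioSpec("base"),
        ScenarioSpec("satisfaction_A", satisfaction_scores=SCENARIO_A_SATISFACTION),
        ScenarioSpec("satisfaction_B", satisfaction_scores=SCENARIO_B_SATISFACTION),
    ]
    for rate in (0.00, 0.06, 0.12):
        scenarios.append(
            ScenarioSpec(f"no_implant_failure_{rate:.2f}", no_implant_failure_rate=rate)
        )
    for adj in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
        scenarios.append(
            ScenarioSpec(f"adjustment_{adj:.1f}", fixed_repair_adjustment=adj)
        )
    return scenarios


def resolve_scenario(
    spec: ScenarioSpec, base: ModelTables | None = None
) -> ModelTables:
    """Apply a scenario's overrides to the base-case configuration."""
    tables = base_tables() if base is None else base
    failure = tables.failure
    satisfaction = tables.satisfaction
    if spec.no_implant_failure_rate is not None:
        denture = dict(failure.denture)
        denture[0] = TriangularDist.point(spec.no_implant_failure_rate)
        failure = FailureRateTable(implant=dict(failure.implant), denture=denture)
    if spec.satisfaction_scores is not None:
        satisfaction = replace(satisfaction, scores=dict(spec.satisfaction_scores))
    if spec.fixed_repair_adjustment is not None:
        satisfaction = replace(
            satisfaction,
            repair_adjustment=TriangularDist.point(spec.fixed_repair_adjustment),
        )
    return replace(tables, failure=failure, satisfaction=satisfaction)


def random_instance(seed: int, horizon: int = 10) -> ModelTables:
    """A structurally valid random model configuration.

    Keeps the analysis' structural assumptions — failure modes strictly
    decreasing in implant count (modes within [0, 0.2]), relative min/max
    bounds shared along the interpolation line so interpolated
    distributions stay in [0, 1], monotone satisfaction anchors in
    [0.5, 1], six-implant costs above four-implant costs — while
    randomising every value.  Reproducible from ``seed``; pathological
    (invariant-violating) inputs are deliberately out of scope.
    """
    rng = np.random.default_rng(seed)

    def failure_pair(mode6_lo: float, mode6_hi: float) -> tuple[TriangularDist, TriangularDist]:
        mode6 = rng.uniform(mode6_lo, mode6_hi)
        mode4 = mode6 * rng.uniform(1.2, 2.2)
        rel_lo = rng.uniform(0.6, 0.9)
        rel_hi = rng.uniform(1.1, 1.6)
        return (
            TriangularDist(mode6 * rel_lo, mode6, mode6 * rel_hi),
            TriangularDist(mode4 * rel_lo, mode4, mode4 * rel_hi),
        )

    implant_six, implant_four = failure_pair(0.005, 0.04)
    denture_six, denture_four = failure_pair(0.01, 0.05)
    no_mode = rng.uniform(0.02, 0.15)
    no_implant = TriangularDist(no_mode * 0.5, no_mode, min(no_mode * 1.8, 0.99))
    failure = interpolate_failure_table(
        implant_six,
        implant_four,
        no_implant,
        denture_six=denture_six,
        denture_four=denture_four,
    )

    s0 = rng.uniform(0.5, 0.7)
    s2 = min(s0 + rng.uniform(0.0, 0.15), 1.0)
    s4 = min(s2 + rng.uniform(0.0, 0.10), 1.0)
    s6 = min(s4 + rng.uniform(0.0, 0.10), 1.0)
    adj_mode = rng.uniform(0.7, 0.95)
    adjustment = TriangularDist(
        max(adj_mode - rng.uniform(0.0, 0.1), 0.0),
        adj_mode,
        min(adj_mode + rng.uniform(0.0, 0.05), 1.0),
    )
    satisfaction = SatisfactionTable(
        scores=interpolate_satisfaction({0: s0, 2: s2, 4: s4, 6: s6}),
        repair_adjustment=adjustment,
    )

    def labor_triple(base_lo: float, base_hi: float) -> tuple[float, float, float]:
        a = rng.uniform(base_lo, base_hi)
        b = a * rng.uniform(1.5, 2.5)
        c = b * rng.uniform(1.2, 1.8)
        return (a, b, c)

    four_labor = labor_triple(800.0, 1500.0)
    six_scale = rng.uniform(1.2, 1.6)
    six_labor = tuple(c * six_scale for c in four_labor)
    four_material = rng.uniform(3000.0, 5000.0)
    costs = CostSchedule(
        factors=(1.0, 2.3, 3.5),
        labor={
            "six_new": six_labor,
            "four_new": four_labor,
            "repair_implant": labor_triple(150.0, 300.0),
            "repair_denture": labor_triple(40.0, 120.0),
        },
        material={
            "six_new": four_material * rng.uniform(1.05, 1.4),
            "four_new": four_material,
            "repair_implant": rng.uniform(80.0, 300.0),
            "repair_denture": rng.uniform(30.0, 100.0),
        },
    )
    return ModelTables(
        failure=failure, satisfaction=satisfaction, costs=costs, horizon=horizon
    )
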