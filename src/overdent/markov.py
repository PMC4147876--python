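"""Markov cohort engine for one overdenture strategy.

The cohort starts with all probability mass at the strategy's initial
implant count (6 or 4) and is propagated through annual cycles.  Within a
cycle, an implant failure and a denture failure can each occur,
independently of one another:

* an implant failure permanently reduces the implant count by one (lost
  implants are never replaced) and triggers a repair priced as "denture
  repair after implant failure";
* a denture failure triggers a "denture repair without implant loss",
  restoring the denture (there is no denture-replacement state);
* repair costs are charged in the cycle the failure occurs.

Satisfaction follows the state-reward convention of cycle-based decision
trees: a cycle accrues the satisfaction score of the state occupied during
that cycle (the start-of-cycle implant count), transitions happen at cycle
end.  A failure at the end of cycle *t* therefore places the repair period
in cycle *t+1*, whose satisfaction is multiplied once by the repair-period
adjustment factor (once even if both failures occurred).  Once all
implants are lost the chain continues at count 0 with the no-implant
denture-failure rate and satisfaction score.  The new-denture cost (labor
plus material/lab) is charged once at entry; no discounting and no
half-cycle correction are applied.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import MAX_IMPLANTS, ModelParameters

__all__ = [
    "Strategy",
    "SIX_IMPLANTS",
    "FOUR_IMPLANTS",
    "Event",
    "CycleEventDistribution",
    "StrategyOutcome",
    "cycle_events",
    "cycle_reward",
    "run_cohort",
    "run_cohort_batch",
]


@dataclass(frozen=True)
class Strategy:
    """A treatment alternative: the model's entry point."""

    initial_count: int

    def __post_init__(self) -> None:
        if self.initial_count not in (6, 4):
            raise ValueError("strategies start with 6 or 4 implants")

    @property
    def label(self) -> str:
        return {6: "six", 4: "four"}[self.initial_count]


SIX_IMPLANTS = Strategy(6)
FOUR_IMPLANTS = Strategy(4)


class Event(enum.Enum):
    """The four disjoint within-cycle outcomes."""

    NEITHER = "neither"
    IMPLANT = "implant_only"
    DENTURE = "denture_only"
    BOTH = "both"


@dataclass(frozen=True)
class CycleEventDistribution:
    """Probabilities of the four disjoint within-cycle events."""

    neither: float
    implant_only: float
    denture_only: float
    both: float

    def __post_init__(self) -> None:
        probs = (self.neither, self.implant_only, self.denture_only, self.both)
        if any(p < 0.0 for p in probs):
            raise ValueError("event probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("event probabilities must sum to 1")

    def __getitem__(self, event: Event) -> float:
        return getattr(self, event.value)


@dataclass(frozen=True)
class StrategyOutcome:
    """Total expected cost (euros) and effectiveness (satisfaction-years)."""

    total_cost: float
    total_effect: float


def cycle_events(n: int, params: ModelParameters) -> CycleEventDistribution:
    """Within-cycle event distribution at ``n`` remaining implants.

    Implant and denture failures occur independently, so the four joint
    probabilities are the products of the marginals.
    """
    if not (0 <= n <= MAX_IMPLANTS):
        raise ValueError(f"implant count must lie in 0-{MAX_IMPLANTS}")
    p_i = float(params.implant_failure[n])
    p_d = float(params.denture_failure[n])
    return CycleEventDistribution(
        neither=(1.0 - p_i) * (1.0 - p_d),
        implant_only=p_i * (1.0 - p_d),
        denture_only=(1.0 - p_i) * p_d,
        both=p_i * p_d,
    )


def cycle_reward(
    n_start: int,
    event: Event,
    params: ModelParameters,
    *,
    in_repair: bool = False,
) -> tuple[float, float]:
    """(cost €, satisfaction fraction) accrued in one cycle.

    ``event`` is this cycle's failure outcome and determines the repair
    cost charged; ``in_repair`` marks a repair period carried over from a
    failure at the end of the previous cycle and multiplies this cycle's
    satisfaction — the score at the occupied (start-of-cycle) implant
    count — once by the repair adjustment.
    """
    implant_failed = event in (Event.IMPLANT, Event.BOTH)
    denture_failed = event in (Event.DENTURE, Event.BOTH)
    if implant_failed and n_start == 0:
        raise ValueError("no implant can fail at count 0")
    cost = 0.0
    if implant_failed:
        cost += params.repair_implant_cost
    if denture_failed:
        cost += params.repair_denture_cost
    satisfaction = float(params.satisfaction[n_start])
    if in_repair:
        satisfaction *= params.repair_adjustment
    return cost, satisfaction


def run_cohort(
    strategy: Strategy, params: ModelParameters, *, trace: bool = False
):
    """Evaluate one strategy over the horizon for one resolved parameter set.

    Returns the :class:`StrategyOutcome`; with ``trace=True`` also a
    :class:`pandas.DataFrame` with one row per cycle (start-of-cycle mass
    per implant count, expected cycle cost, expected cycle satisfaction).
    Deterministic: identical inputs give bit-identical outputs.
    """
    counts = np.arange(MAX_IMPLANTS + 1)
    # cohort mass split by repair flag: sound vs in a carried-over repair period
    m_sound = np.zeros(MAX_IMPLANTS + 1)
    m_sound[strategy.initial_count] = 1.0
    m_repair = np.zeros(MAX_IMPLANTS + 1)
    p_i = params.implant_failure
    p_d = params.denture_failure
    sat = params.satisfaction
    adj = params.repair_adjustment
    c_imp = params.repair_implant_cost
    c_den = params.repair_denture_cost
    per_state_cost = p_i * c_imp + p_d * c_den
    p_any = 1.0 - (1.0 - p_i) * (1.0 - p_d)

    total_cost = params.new_denture_cost(strategy.initial_count)
    total_effect = 0.0
    rows = []
    for cycle in range(1, params.horizon + 1):
        mass = m_sound + m_repair
        cycle_cost = float(mass @ per_state_cost)
        cycle_sat = float(m_sound @ sat + m_repair @ (sat * adj))
        total_cost += cycle_cost
        total_effect += cycle_sat
        if trace:
            rows.append(
                {"cycle": cycle}
                | {f"mass_{n}": mass[n] for n in counts}
                | {"expected_cost_eur": cycle_cost, "expected_satisfaction": cycle_sat}
            )
        # end-of-cycle transition; any failure starts a repair period
        m_repair = mass * (1.0 - p_i) * p_d
        m_repair[:-1] += (mass * p_i)[1:]
        m_sound = mass * (1.0 - p_any)

    outcome = StrategyOutcome(total_cost=total_cost, total_effect=total_effect)
    if trace:
        return outcome, pd.DataFrame(rows)
    return outcome


def run_cohort_batch(
    initial_count: int,
    implant_failure: np.ndarray,
    denture_failure: np.ndarray,
    satisfaction: np.ndarray,
    repair_adjustment: np.ndarray,
    repair_implant_cost: np.ndarray,
    repair_denture_cost: np.ndarray,
    new_denture_cost: np.ndarray,
    horizon: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cohort evaluation across many parameter draws.

    ``implant_failure`` and ``denture_failure`` have shape ``(n_draws, 7)``
    (columns indexed by remaining implant count); satisfaction is the fixed
    point-estimate vector of length 7; the remaining arguments are per-draw
    scalars of shape ``(n_draws,)`` (length-1 arrays broadcast).  Returns
    ``(total_cost, total_effect)`` arrays.  The recursion is identical to
    :func:`run_cohort`, broadcast over the draw axis.
    """
    p_i = np.asarray(implant_failure, dtype=float)
    p_d = np.asarray(denture_failure, dtype=float)
    n_draws = p_i.shape[0]
    sat = np.asarray(satisfaction, dtype=float)
    adj = np.asarray(repair_adjustment, dtype=float)[:, None]
    m_sound = np.zeros((n_draws, MAX_IMPLANTS + 1))
    m_sound[:, initial_count] = 1.0
    m_repair = np.zeros((n_draws, MAX_IMPLANTS + 1))

    per_state_cost = (
        p_i * np.asarray(repair_implant_cost, dtype=float)[:, None]
        + p_d * np.asarray(repair_denture_cost, dtype=float)[:, None]
    )
    sat_repair = sat[None, :] * adj
    p_any = 1.0 - (1.0 - p_i) * (1.0 - p_d)

    total_cost = np.broadcast_to(
        np.asarray(new_denture_cost, dtype=float), (n_draws,)
    ).copy()
    total_effect = np.zeros(n_draws)
    for _ in range(horizon):
        mass = m_sound + m_repair
        total_cost += np.einsum("ij,ij->i", mass, per_state_cost)
        total_effect += m_sound @ sat + np.einsum("ij,ij->i", m_repair, sat_repair)
        m_repair = mass * (1.0 - p_i) * p_d
        m_repair[:, :-1] += (mass * p_i)[:, 1:]
        m_sound = mass * (1.0 - p_any)
    return total_cost, total_effect
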