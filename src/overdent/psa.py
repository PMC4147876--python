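"""Probabilistic sensitivity analysis by Monte Carlo simulation.

Each draw samples every failure-rate distribution and the repair-period
adjustment independently from their triangular laws; satisfaction scores
enter as fixed point estimates.  The complexity cost factor is either held
fixed (acceptability-curve mode, one panel per factor) or itself sampled
from Triangular(1.0, 2.3, 3.5) (cost-effectiveness-plane scatter mode).
Both strategies are evaluated on the same realised parameters within a
draw (common random parameters), so per-draw incremental cost and effect
reflect parameter uncertainty only.

Uniform deviates are consumed from a single ``(n_draws, 15)`` matrix in
row-major order, so extending ``n_draws`` with the same seed leaves the
initial draws bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import FOUR_IMPLANTS, SIX_IMPLANTS, run_cohort_batch
from .params import (
    MAX_IMPLANTS,
    ModelParameters,
    ModelTables,
    TriangularDist,
    triangular_ppf,
)

__all__ = [
    "DEFAULT_N_DRAWS",
    "DEFAULT_SEED",
    "ParameterDraws",
    "PsaResult",
    "draw_parameters",
    "sample_draws",
    "simulate_psa",
]

#: Monte Carlo repetitions of the reference analysis.
DEFAULT_N_DRAWS = 50_000
#: Default RNG seed; overridable everywhere a seed is accepted.
DEFAULT_SEED = 1729

# column layout of the uniform-deviate matrix (one row per draw)
_N_UNIFORMS = 15  # implant failure 1-6, denture failure 0-6, adjustment, cost factor
_COL_IMPLANT = slice(0, 6)  # counts 1..6
_COL_DENTURE = slice(6, 13)  # counts 0..6
_COL_ADJUST = 13
_COL_FACTOR = 14


@dataclass(frozen=True)
class ParameterDraws:
    """Realised parameter values for a batch of Monte Carlo draws.

    ``implant_failure`` / ``denture_failure`` have shape ``(n_draws, 7)``
    indexed by remaining implant count; ``repair_adjustment`` and
    ``cost_factor`` have shape ``(n_draws,)``.
    """

    implant_failure: np.ndarray
    denture_failure: np.ndarray
    repair_adjustment: np.ndarray
    cost_factor: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.implant_failure.shape[0]


@dataclass(frozen=True)
class PsaResult:
    """Paired strategy outcomes across all PSA draws.

    Costs are in euros, effects in satisfaction-years; arrays are indexed
    by draw.  Both strategies share the realised parameters in ``draws``.
    """

    draws: ParameterDraws
    cost_six: np.ndarray
    effect_six: np.ndarray
    cost_four: np.ndarray
    effect_four: np.ndarray
    horizon: int
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.n_draws

    @property
    def incremental_cost(self) -> np.ndarray:
        return self.cost_six - self.cost_four

    @property
    def incremental_effect(self) -> np.ndarray:
        return self.effect_six - self.effect_four

    def scatter_frame(self) -> pd.DataFrame:
        """Long-format (draw, strategy, cost, effect) table of the CE plane."""
        n = self.n_draws
        return pd.DataFrame(
            {
                "draw": np.concatenate([np.arange(n), np.arange(n)]),
                "strategy": ["six"] * n + ["four"] * n,
                "cost_eur": np.concatenate([self.cost_six, self.cost_four]),
                "effect_satisfaction_years": np.concatenate(
                    [self.effect_six, self.effect_four]
                ),
            }
        )


def _resolve_uniforms(
    u: np.ndarray, tables: ModelTables, cost_factor: float | TriangularDist
) -> ParameterDraws:
    """Transform uniform deviates ``(n, 15)`` into realised parameters."""
    n = u.shape[0]
    implant = np.zeros((n, MAX_IMPLANTS + 1))
    denture = np.zeros((n, MAX_IMPLANTS + 1))
    for count in range(1, MAX_IMPLANTS + 1):
        d = tables.failure.implant[count]
        implant[:, count] = triangular_ppf(
            u[:, _COL_IMPLANT][:, count - 1], d.low, d.mode, d.high
        )
    for count in range(MAX_IMPLANTS + 1):
        d = tables.failure.denture[count]
        denture[:, count] = triangular_ppf(
            u[:, _COL_DENTURE][:, count], d.low, d.mode, d.high
        )
    adj_dist = tables.satisfaction.repair_adjustment
    adjustment = triangular_ppf(u[:, _COL_ADJUST], adj_dist.low, adj_dist.mode, adj_dist.high)
    if isinstance(cost_factor, TriangularDist):
        factor = triangular_ppf(
            u[:, _COL_FACTOR], cost_factor.low, cost_factor.mode, cost_factor.high
        )
    else:
        factor = np.full(n, float(cost_factor))
    return ParameterDraws(
        implant_failure=implant,
        denture_failure=denture,
        repair_adjustment=np.atleast_1d(adjustment),
        cost_factor=factor,
    )


def draw_parameters(
    tables: ModelTables,
    cost_factor: float | TriangularDist,
    rng: np.random.Generator,
) -> ModelParameters:
    """Sample one fully resolved parameter set.

    Every failure distribution and the repair adjustment are sampled
    independently through the triangular inverse CDF; satisfaction scores
    are taken as point estimates; the cost factor is fixed or sampled
    according to ``cost_factor``.
    """
    draws = _resolve_uniforms(rng.random((1, _N_UNIFORMS)), tables, cost_factor)
    return ModelParameters(
        implant_failure=draws.implant_failure[0],
        denture_failure=draws.denture_failure[0],
        satisfaction=tables.satisfaction.as_array(),
        repair_adjustment=float(draws.repair_adjustment[0]),
        cost_factor=float(draws.cost_factor[0]),
        costs=tables.costs,
        horizon=tables.horizon,
    )


def sample_draws(
    tables: ModelTables,
    cost_factor: float | TriangularDist,
    n_draws: int,
    seed: int,
) -> ParameterDraws:
    """Sample ``n_draws`` parameter sets reproducibly from ``seed``."""
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_draws, _N_UNIFORMS))
    return _resolve_uniforms(u, tables, cost_factor)


def simulate_psa(
    tables: ModelTables,
    cost_factor: float | TriangularDist = 2.3,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = DEFAULT_SEED,
) -> PsaResult:
    """Run the Monte Carlo PSA: paired cohort outcomes for both strategies.

    Per draw, the six- and four-implant strategies are evaluated by the
    cohort engine on the same realised parameters.  Reproducible for a
    fixed seed; the first ``k`` draws are unchanged when ``n_draws`` is
    increased at the same seed.
    """
    draws = sample_draws(tables, cost_factor, n_draws, seed)
    schedule = tables.costs
    c_imp = (
        schedule.labor_cost("repair_implant", draws.cost_factor)
        + schedule.material["repair_implant"]
    )
    c_den = (
        schedule.labor_cost("repair_denture", draws.cost_factor)
        + schedule.material["repair_denture"]
    )
    sat = tables.satisfaction.as_array()
    results = {}
    for strategy in (SIX_IMPLANTS, FOUR_IMPLANTS):
        item = {6: "six_new", 4: "four_new"}[strategy.initial_count]
        init_cost = (
            schedule.labor_cost(item, draws.cost_factor) + schedule.material[item]
        )
        results[strategy.label] = run_cohort_batch(
            strategy.initial_count,
            draws.implant_failure,
            draws.denture_failure,
            sat,
            draws.repair_adjustment,
            np.atleast_1d(c_imp),
            np.atleast_1d(c_den),
            np.atleast_1d(init_cost),
            tables.horizon,
        )
    return PsaResult(
        draws=draws,
        cost_six=results["six"][0],
        effect_six=results["six"][1],
        cost_four=results["four"][0],
        effect_four=results["four"][1],
        horizon=tables.horizon,
        seed=seed,
    )
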