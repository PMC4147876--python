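"""Independent oracles for the cohort engine and the triangular law.

Deliberately implemented without reusing the package's recursions:
``microsimulate`` samples individual patient trajectories event by event;
``enumerate_paths`` exhaustively enumerates every within-cycle event
sequence (feasible for short horizons).  Both apply the same model
conventions — start-of-cycle satisfaction, repair period (with one
adjustment application) in the cycle following a failure, repair costs at
failure time, at most one implant loss per cycle.
"""

from __future__ import annotations

import itertools

import numpy as np

from overdent.markov import Strategy
from overdent.params import ModelParameters


def microsimulate(
    strategy: Strategy,
    params: ModelParameters,
    n_patients: int,
    rng: np.random.Generator,
):
    """Patient-level Monte Carlo estimate of cohort cost and effect.

    Returns ``(mean_cost, mean_effect, se_cost, se_effect)``.
    """
    counts = np.full(n_patients, strategy.initial_count, dtype=np.int64)
    cost = np.full(n_patients, params.new_denture_cost(strategy.initial_count))
    effect = np.zeros(n_patients)
    in_repair = np.zeros(n_patients, dtype=bool)
    c_imp = params.repair_implant_cost
    c_den = params.repair_denture_cost
    for _ in range(params.horizon):
        sat = params.satisfaction[counts]
        effect += np.where(in_repair, sat * params.repair_adjustment, sat)
        implant_fails = rng.random(n_patients) < params.implant_failure[counts]
        denture_fails = rng.random(n_patients) < params.denture_failure[counts]
        cost += implant_fails * c_imp + denture_fails * c_den
        counts = counts - implant_fails
        in_repair = implant_fails | denture_fails
    se = lambda x: float(np.std(x, ddof=1) / np.sqrt(n_patients))  # noqa: E731
    return float(np.mean(cost)), float(np.mean(effect)), se(cost), se(effect)


def enumerate_paths(strategy: Strategy, params: ModelParameters):
    """Exact expected (cost, effect) by exhaustive event-path enumeration.

    Enumerates all 4**horizon sequences of within-cycle events; only
    usable for short horizons.
    """
    events = ("neither", "implant", "denture", "both")
    total_cost = 0.0
    total_effect = 0.0
    init_cost = params.new_denture_cost(strategy.initial_count)
    c_imp = params.repair_implant_cost
    c_den = params.repair_denture_cost
    for path in itertools.product(events, repeat=params.horizon):
        prob = 1.0
        cost = init_cost
        effect = 0.0
        count = strategy.initial_count
        in_repair = False
        for ev in path:
            sat = params.satisfaction[count]
            effect += sat * params.repair_adjustment if in_repair else sat
            p_i = params.implant_failure[count]
            p_d = params.denture_failure[count]
            p_ev = {
                "neither": (1 - p_i) * (1 - p_d),
                "implant": p_i * (1 - p_d),
                "denture": (1 - p_i) * p_d,
                "both": p_i * p_d,
            }[ev]
            if p_ev == 0.0:
                prob = 0.0
                break
            prob *= p_ev
            if ev in ("implant", "both"):
                cost += c_imp
                count -= 1
            if ev in ("denture", "both"):
                cost += c_den
            in_repair = ev != "neither"
        total_cost += prob * cost
        total_effect += prob * effect
    return total_cost, total_effect


def triangular_cdf(x, low, mode, high):
    """Closed-form triangular CDF (for KS tests and ppf root checks)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if high > low:
        left = (x > low) & (x <= mode)
        out[left] = (x[left] - low) ** 2 / ((high - low) * (mode - low)) if mode > low else 0.0
        right = (x > mode) & (x < high)
        out[right] = 1 - (high - x[right]) ** 2 / ((high - low) * (high - mode)) if high > mode else 1.0
        if mode == low:
            between = (x > low) & (x < high)
            out[between] = 1 - (high - x[between]) ** 2 / (high - low) ** 2
        out[x >= high] = 1.0
    else:
        out[x >= low] = 1.0
    return out
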