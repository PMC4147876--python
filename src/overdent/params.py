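"""Model input parameters for the overdenture cost-effectiveness model.

This module houses every quantity the Markov model consumes:

* triangular (min/mode/max) uncertainty distributions for annual failure
  probabilities and the repair-period satisfaction adjustment,
* the failure-rate table over implant counts 0-6, filled in by linear
  interpolation between the six- and four-implant evidence anchors,
* the patient-satisfaction table (point estimates on a 0-1 scale, where 1
  is full denture satisfaction),
* the treatment cost schedule in euros, with dentist labor costs indexed by
  the German fee-schedule complexity multiplier (1.0 / 2.3 / 3.5) and
  factor-independent material/laboratory costs.

Clinical evidence reports failure rates for bar-retained maxillary
overdentures on six or four implants only; rates for the intermediate (and
extrapolated lower) implant counts lie on the straight line through those
two anchors.  Satisfaction is anchored at 6, 4, 2 and 0 implants and
interpolated piecewise-linearly (arithmetic means for counts 5, 3, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np

__all__ = [
    "TriangularDist",
    "FailureRateTable",
    "SatisfactionTable",
    "CostSchedule",
    "ModelTables",
    "ModelParameters",
    "LABOR_ITEMS",
    "MATERIAL_ITEMS",
    "triangular_mean",
    "sample_triangular",
    "triangular_ppf",
    "interpolate_failure_table",
    "interpolate_satisfaction",
    "labor_cost_at_factor",
]

#: Cost items carrying a labor component (indexed by complexity factor).
LABOR_ITEMS = ("six_new", "four_new", "repair_implant", "repair_denture")
#: Cost items carrying a factor-independent material/lab component.
MATERIAL_ITEMS = ("six_new", "four_new", "repair_implant", "repair_denture")

MAX_IMPLANTS = 6


@dataclass(frozen=True)
class TriangularDist:
    """A triangular distribution given by minimum, mode and maximum.

    The degenerate case ``low == mode == high`` is permitted and represents
    a point mass (used e.g. for structurally certain quantities and for
    one-way sensitivity analyses that pin a parameter).
    """

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mode <= self.high):
            raise ValueError(
                f"triangular distribution requires low <= mode <= high, "
                f"got ({self.low}, {self.mode}, {self.high})"
            )

    @classmethod
    def point(cls, value: float) -> "TriangularDist":
        """Point mass at ``value`` (degenerate triangular)."""
        return cls(value, value, value)

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    @property
    def mean(self) -> float:
        return (self.low + self.mode + self.high) / 3.0

    def ppf(self, u):
        """Inverse cumulative distribution function at ``u`` in [0, 1]."""
        return triangular_ppf(u, self.low, self.mode, self.high)


def triangular_mean(d: TriangularDist) -> float:
    """Mean of a triangular distribution, ``(low + mode + high) / 3``."""
    return d.mean


def triangular_ppf(u, low, mode, high):
    """Vectorised inverse CDF of the triangular law.

    Accepts scalars or arrays for every argument (numpy broadcasting).
    Handles the degenerate point mass ``low == high`` by returning ``low``.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u > 1.0)):
        raise ValueError("u must lie in [0, 1]")
    low = np.asarray(low, dtype=float)
    mode = np.asarray(mode, dtype=float)
    high = np.asarray(high, dtype=float)
    span = high - low
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(span > 0.0, (mode - low) / np.where(span > 0.0, span, 1.0), 0.0)
        left = low + np.sqrt(u * span * (mode - low))
        right = high - np.sqrt((1.0 - u) * span * (high - mode))
    out = np.where(span == 0.0, low, np.where(u < fc, left, right))
    out = np.clip(out, low, high)  # guard against roundoff leaving the support
    if out.ndim == 0:
        return float(out)
    return out


def sample_triangular(d: TriangularDist, u: float):
    """Map a uniform deviate ``u`` through the triangular inverse CDF.

    Strictly increasing in ``u`` whenever ``low < high``; the output never
    leaves ``[low, high]``.
    """
    return d.ppf(u)


def _check_unit_interval(d: TriangularDist, what: str) -> None:
    if not (0.0 <= d.low and d.high <= 1.0):
        raise ValueError(f"{what} bounds must lie in [0, 1], got {d}")


@dataclass(frozen=True)
class FailureRateTable:
    """Annual failure-probability distributions per remaining implant count.

    ``implant[n]`` is the distribution of the annual probability that one
    of the ``n`` remaining implants fails; ``denture[n]`` the annual
    probability that the overdenture itself fails while ``n`` implants
    remain.  Count 0 has no implants left to fail, so ``implant[0]`` is the
    structural point mass at zero.
    """

    implant: Mapping[int, TriangularDist]
    denture: Mapping[int, TriangularDist]

    def __post_init__(self) -> None:
        counts = set(range(MAX_IMPLANTS + 1))
        if set(self.implant) != counts or set(self.denture) != counts:
            raise ValueError("failure tables must cover implant counts 0-6")
        for n in counts:
            _check_unit_interval(self.implant[n], f"implant-failure[{n}]")
            _check_unit_interval(self.denture[n], f"denture-failure[{n}]")
        if self.implant[0] != TriangularDist.point(0.0):
            raise ValueError("implant failure at count 0 must be the point mass at 0")
        for n in range(2, MAX_IMPLANTS + 1):
            if not self.implant[n].mode < self.implant[n - 1].mode:
                raise ValueError("implant-failure mode must strictly decrease with count")
            if not self.denture[n].mode < self.denture[n - 1].mode:
                raise ValueError("denture-failure mode must strictly decrease with count")

    def modes(self) -> tuple[np.ndarray, np.ndarray]:
        """(implant, denture) modal rates as arrays indexed by count 0-6."""
        pi = np.array([self.implant[n].mode for n in range(MAX_IMPLANTS + 1)])
        pd_ = np.array([self.denture[n].mode for n in range(MAX_IMPLANTS + 1)])
        return pi, pd_


@dataclass(frozen=True)
class SatisfactionTable:
    """Denture-satisfaction point estimates and the repair adjustment.

    Satisfaction is on a 0-1 scale (1 = full satisfaction) per remaining
    implant count; it is never sampled in PSA.  ``repair_adjustment`` is the
    multiplicative factor applied to a cycle's satisfaction when a failure
    (and hence a repair period) occurs in that cycle.
    """

    scores: Mapping[int, float]
    repair_adjustment: TriangularDist = field(
        default_factory=lambda: TriangularDist(0.8, 0.9, 0.99)
    )

    def __post_init__(self) -> None:
        if set(self.scores) != set(range(MAX_IMPLANTS + 1)):
            raise ValueError("satisfaction table must cover implant counts 0-6")
        for n, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"satisfaction[{n}]={s} outside [0, 1]")
        for n in range(1, MAX_IMPLANTS + 1):
            if self.scores[n] < self.scores[n - 1]:
                raise ValueError("satisfaction must be non-decreasing in implant count")
        _check_unit_interval(self.repair_adjustment, "repair adjustment")

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[n] for n in range(MAX_IMPLANTS + 1)])


@dataclass(frozen=True)
class CostSchedule:
    """Treatment cost schedule in euros.

    ``labor[item]`` gives the dentist labor cost at each anchor of the
    complexity ``factors`` grid (non-decreasing in the factor); ``material``
    the factor-independent material/laboratory cost.  Items: ``six_new`` /
    ``four_new`` (new overdenture on 6 / 4 implants), ``repair_implant``
    (denture repair after an implant failure), ``repair_denture`` (denture
    repair without implant loss).
    """

    factors: tuple[float, ...]
    labor: Mapping[str, tuple[float, ...]]
    material: Mapping[str, float]

    def __post_init__(self) -> None:
        if list(self.factors) != sorted(self.factors) or len(self.factors) < 1:
            raise ValueError("cost factors must be a non-empty increasing grid")
        if set(self.labor) != set(LABOR_ITEMS) or set(self.material) != set(MATERIAL_ITEMS):
            raise ValueError(f"cost schedule must price exactly {LABOR_ITEMS}")
        for item, row in self.labor.items():
            if len(row) != len(self.factors):
                raise ValueError(f"labor[{item}] must have one value per factor anchor")
            if any(c < 0 for c in row) or list(row) != sorted(row):
                raise ValueError(f"labor[{item}] must be >= 0 and non-decreasing in factor")
        if any(c < 0 for c in self.material.values()):
            raise ValueError("material costs must be >= 0")
        for six, four in zip(self.labor["six_new"], self.labor["four_new"]):
            if not six > four:
                raise ValueError("six-implant new-denture labor must exceed four-implant")
        if not self.material["six_new"] > self.material["four_new"]:
            raise ValueError("six-implant material cost must exceed four-implant")

    def labor_cost(self, item: str, factor) -> float:
        return labor_cost_at_factor(self, item, factor)

    def total_cost(self, item: str, factor):
        """Labor at ``factor`` plus the material/lab component, in euros."""
        return self.labor_cost(item, factor) + self.material[item]


def labor_cost_at_factor(schedule: CostSchedule, item: str, factor):
    """Dentist labor cost (in euros) for ``item`` at a complexity ``factor``.

    Anchor factors return the schedule's printed value exactly; factors in
    between are piecewise-linearly interpolated between the two nearest
    anchors (the printed columns are not scalar multiples of each other, so
    multiplying the factor-1.0 column would misprice intermediate factors).
    """
    if item not in schedule.labor:
        raise KeyError(f"unknown cost item {item!r}; expected one of {LABOR_ITEMS}")
    factor = np.asarray(factor, dtype=float)
    lo, hi = schedule.factors[0], schedule.factors[-1]
    if np.any((factor < lo) | (factor > hi)):
        raise ValueError(f"cost factor must lie in [{lo}, {hi}]")
    out = np.interp(factor, schedule.factors, schedule.labor[item])
    if out.ndim == 0:
        return float(out)
    return out


def _line_through(six: float, four: float, count: int) -> float:
    """Straight line through (6, six) and (4, four), evaluated at count.

    Computed in exact decimal arithmetic on the shortest decimal
    representation of the anchors, so that interpolating a table printed
    in decimals reproduces the printed decimal cells bit-exactly (naive
    binary float arithmetic is off by 1 ulp in several cells).
    """
    a6, a4 = Fraction(repr(six)), Fraction(repr(four))
    return float(a4 + (a6 - a4) * (count - 4) / 2)


def interpolate_failure_table(
    six: TriangularDist,
    four: TriangularDist,
    no_implant_denture: TriangularDist,
    *,
    denture_six: TriangularDist | None = None,
    denture_four: TriangularDist | None = None,
) -> FailureRateTable:
    """Build the full failure-rate table from the evidence anchors.

    Parameters
    ----------
    six, four
        Implant-failure distributions with 6 resp. 4 implants.
    no_implant_denture
        Denture-failure distribution once all implants are lost.
    denture_six, denture_four
        Denture-failure distributions with 6 resp. 4 implants.

    Each of low/mode/high for counts 5, 3, 2, 1 lies on the straight line
    through the six- and four-implant anchors (extrapolated below 4
    implants).  Implant failure at count 0 is the structural point mass at
    zero.  Any interpolated or extrapolated bound leaving [0, 1] is an
    error.
    """
    if denture_six is None or denture_four is None:
        raise TypeError("denture_six and denture_four anchors are required")
    if not six.mode < four.mode:
        raise ValueError("six-implant failure mode must lie below the four-implant mode")
    if not denture_six.mode < denture_four.mode:
        raise ValueError("six-implant denture-failure mode must lie below four-implant")

    def fill(anchor6: TriangularDist, anchor4: TriangularDist) -> dict[int, TriangularDist]:
        table = {6: anchor6, 4: anchor4}
        for n in (5, 3, 2, 1):
            trip = [
                _line_through(getattr(anchor6, f_), getattr(anchor4, f_), n)
                for f_ in ("low", "mode", "high")
            ]
            if trip[0] < 0.0 or trip[2] > 1.0:
                raise ValueError(
                    f"interpolated failure bounds at count {n} leave [0, 1]: {trip}"
                )
            table[n] = TriangularDist(*trip)
        return table

    implant = fill(six, four)
    implant[0] = TriangularDist.point(0.0)
    denture = fill(denture_six, denture_four)
    denture[0] = no_implant_denture
    return FailureRateTable(implant=implant, denture=denture)


def interpolate_satisfaction(anchors: Mapping[int, float]) -> dict[int, float]:
    """Fill satisfaction for counts 5, 3, 1 from anchors at {6, 4, 2, 0}.

    Piecewise-linear through the four anchors: each odd count is the
    arithmetic mean of its adjacent anchors.  Anchors must be bounded in
    [0, 1] and non-decreasing in implant count.
    """
    if set(anchors) != {6, 4, 2, 0}:
        raise ValueError("satisfaction anchors must be given at counts {6, 4, 2, 0}")
    for n, s in anchors.items():
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"satisfaction anchor [{n}]={s} outside [0, 1]")
    for lo, hi in ((0, 2), (2, 4), (4, 6)):
        if anchors[hi] < anchors[lo]:
            raise ValueError("satisfaction anchors must be non-decreasing in count")
    scores = dict(anchors)
    for n in (5, 3, 1):
        # exact decimal midpoint (see _line_through)
        scores[n] = float(
            (Fraction(repr(anchors[n - 1])) + Fraction(repr(anchors[n + 1]))) / 2
        )
    return dict(sorted(scores.items()))


@dataclass(frozen=True)
class ModelTables:
    """One complete, unresolved model configuration.

    Bundles the failure-rate distributions, satisfaction table and cost
    schedule that a scenario defines; the PSA resolves this to concrete
    :class:`ModelParameters` per Monte Carlo draw.
    """

    failure: FailureRateTable
    satisfaction: SatisfactionTable
    costs: CostSchedule
    horizon: int = 10

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1 cycle")

    def at_modes(self, cost_factor: float = 2.3) -> "ModelParameters":
        """Resolve every distribution at its mode (deterministic base run)."""
        pi, pd_ = self.failure.modes()
        return ModelParameters(
            implant_failure=pi,
            denture_failure=pd_,
            satisfaction=self.satisfaction.as_array(),
            repair_adjustment=self.satisfaction.repair_adjustment.mode,
            cost_factor=cost_factor,
            costs=self.costs,
            horizon=self.horizon,
        )


@dataclass(frozen=True)
class ModelParameters:
    """A fully resolved parameter set for one cohort evaluation.

    Arrays are indexed by remaining implant count 0-6.  All probabilities
    and the repair adjustment lie in [0, 1].
    """

    implant_failure: np.ndarray
    denture_failure: np.ndarray
    satisfaction: np.ndarray
    repair_adjustment: float
    cost_factor: float
    costs: CostSchedule
    horizon: int = 10

    def __post_init__(self) -> None:
        for name in ("implant_failure", "denture_failure", "satisfaction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (MAX_IMPLANTS + 1,):
                raise ValueError(f"{name} must have one entry per implant count 0-6")
            if np.any((arr < 0.0) | (arr > 1.0)):
                raise ValueError(f"{name} values must lie in [0, 1]")
            object.__setattr__(self, name, arr)
        if self.implant_failure[0] != 0.0:
            raise ValueError("implant failure probability at count 0 must be 0")
        if not (0.0 <= self.repair_adjustment <= 1.0):
            raise ValueError("repair adjustment must lie in [0, 1]")
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1 cycle")

    @property
    def repair_implant_cost(self) -> float:
        """Cost of a denture repair after an implant failure, in euros."""
        return self.costs.total_cost("repair_implant", self.cost_factor)

    @property
    def repair_denture_cost(self) -> float:
        """Cost of a denture repair without implant loss, in euros."""
        return self.costs.total_cost("repair_denture", self.cost_factor)

    def new_denture_cost(self, initial_count: int) -> float:
        item = {6: "six_new", 4: "four_new"}[initial_count]
        return self.costs.total_cost(item, self.cost_factor)
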