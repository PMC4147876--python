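"""YAML configuration files for model tables.

A configuration stores the evidence anchors (not the interpolated table):
six-/four-implant failure distributions, the no-implant denture-failure
assumption, satisfaction given either as ``anchors`` at counts {6,4,2,0}
(interpolated on load) or as a full ``scores`` map, the repair adjustment
and the cost schedule.  Floats are written with Python's shortest
round-trip ``repr``, so printed decimal values survive a load/dump cycle
bit-exactly.  The packaged fixtures ``base``, ``scenario_a`` and
``scenario_b`` encode the reference analysis.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .params import (
    CostSchedule,
    LABOR_ITEMS,
    ModelTables,
    SatisfactionTable,
    TriangularDist,
    interpolate_failure_table,
    interpolate_satisfaction,
)

__all__ = ["load_tables", "loads_tables", "dumps_tables", "dump_tables", "packaged_config"]

_FAILURE_KEYS = (
    "implant_six",
    "implant_four",
    "denture_six",
    "denture_four",
    "denture_no_implants",
)


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


def _dist_to_obj(d: TriangularDist) -> dict:
    return {"low": d.low, "mode": d.mode, "high": d.high}


def _dist_from_obj(obj, field: str) -> TriangularDist:
    if not isinstance(obj, dict) or set(obj) != {"low", "mode", "high"}:
        raise ConfigError(f"{field}: expected a {{low, mode, high}} mapping")
    try:
        return TriangularDist(float(obj["low"]), float(obj["mode"]), float(obj["high"]))
    except ValueError as exc:
        raise ConfigError(f"{field}: {exc}") from exc


def loads_tables(text: str) -> ModelTables:
    """Parse a configuration document into :class:`ModelTables`."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    for section in ("failure_rates", "satisfaction", "costs"):
        if section not in doc:
            raise ConfigError(f"{section}: missing section")
    fr = doc["failure_rates"]
    missing = [k for k in _FAILURE_KEYS if k not in fr]
    if missing:
        raise ConfigError(f"failure_rates: missing {missing}")
    dists = {k: _dist_from_obj(fr[k], f"failure_rates.{k}") for k in _FAILURE_KEYS}
    try:
        failure = interpolate_failure_table(
            dists["implant_six"],
            dists["implant_four"],
            dists["denture_no_implants"],
            denture_six=dists["denture_six"],
            denture_four=dists["denture_four"],
        )
    except ValueError as exc:
        raise ConfigError(f"failure_rates: {exc}") from exc

    sat = doc["satisfaction"]
    try:
        if "scores" in sat:
            scores = {int(k): float(v) for k, v in sat["scores"].items()}
        elif "anchors" in sat:
            anchors = {int(k): float(v) for k, v in sat["anchors"].items()}
            scores = interpolate_satisfaction(anchors)
        else:
            raise ConfigError("satisfaction: needs either 'scores' or 'anchors'")
        satisfaction = SatisfactionTable(
            scores=scores,
            repair_adjustment=_dist_from_obj(
                sat["repair_adjustment"], "satisfaction.repair_adjustment"
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"satisfaction: {exc}") from exc

    c = doc["costs"]
    try:
        costs = CostSchedule(
            factors=tuple(float(f) for f in c["factors"]),
            labor={k: tuple(float(x) for x in v) for k, v in c["labor"].items()},
            material={k: float(v) for k, v in c["material"].items()},
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"costs: {exc}") from exc

    horizon = int(doc.get("horizon", 10))
    try:
        return ModelTables(
            failure=failure, satisfaction=satisfaction, costs=costs, horizon=horizon
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def dumps_tables(tables: ModelTables, *, satisfaction_anchors: bool | None = None) -> str:
    """Serialise a configuration back to its YAML document.

    ``satisfaction_anchors`` controls whether satisfaction is written as
    the four anchors (only possible when the odd counts are exactly their
    interpolants, the default in that case) or as the full score map.
    """
    scores = dict(tables.satisfaction.scores)
    anchors = {n: scores[n] for n in (6, 4, 2, 0)}
    is_interpolant = interpolate_satisfaction(anchors) == dict(sorted(scores.items()))
    if satisfaction_anchors is None:
        satisfaction_anchors = is_interpolant
    if satisfaction_anchors and not is_interpolant:
        raise ValueError("satisfaction scores are not interpolants of their anchors")
    failure = tables.failure
    doc = {
        "horizon": tables.horizon,
        "failure_rates": {
            "implant_six": _dist_to_obj(failure.implant[6]),
            "implant_four": _dist_to_obj(failure.implant[4]),
            "denture_six": _dist_to_obj(failure.denture[6]),
            "denture_four": _dist_to_obj(failure.denture[4]),
            "denture_no_implants": _dist_to_obj(failure.denture[0]),
        },
        "satisfaction": {
            ("anchors" if satisfaction_anchors else "scores"): (
                anchors if satisfaction_anchors else {n: scores[n] for n in range(6, -1, -1)}
            ),
            "repair_adjustment": _dist_to_obj(tables.satisfaction.repair_adjustment),
        },
        "costs": {
            "factors": list(tables.costs.factors),
            "labor": {item: list(tables.costs.labor[item]) for item in LABOR_ITEMS},
            "material": {item: tables.costs.material[item] for item in LABOR_ITEMS},
        },
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def load_tables(path: str | Path) -> ModelTables:
    """Load and validate a configuration file."""
    return loads_tables(Path(path).read_text(encoding="utf-8"))


def dump_tables(tables: ModelTables, path: str | Path, **kwargs) -> None:
    Path(path).write_text(dumps_tables(tables, **kwargs), encoding="utf-8")


def packaged_config(name: str) -> str:
    """Text of a packaged fixture: ``base``, ``scenario_a`` or ``scenario_b``."""
    return (
        resources.files("overdent.data").joinpath(f"{name}.yaml").read_text("utf-8")
    )
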