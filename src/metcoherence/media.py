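"""Growth media: reference medium, random media, and their application.

A medium is a set of bounds on exchange reactions.  Uptake is a negative
lower bound (flux into the cell); secretion stays open by default.  The
reference medium enables uptake for a configured nutrient list (carbon
sources at a higher rate than amino/fatty acids) and leaves oxygen
consumption unconstrained.  Random media select a uniform fraction (4% to
100%) of all exchanges and give them uniform bounds in [-20, 0] and
[0, 20]; a configurable always-available set (oxygen, protons, sulfate,
phosphate, water) is uptake-enabled in every draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .model_core import INTERNAL_INF, MetabolicModel, ModelError

__all__ = [
    "Medium",
    "MediaConfig",
    "reference_medium",
    "random_medium",
    "apply_medium",
    "save_medium_json",
    "load_medium_json",
]

logger = logging.getLogger(__name__)


@dataclass
class Medium:
    """Exchange-reaction bounds defining an environment."""

    bounds: dict[str, tuple[float, float]]
    label: str = "medium"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ModelError(
                    f"medium {self.label!r}: lb > ub for exchange {rid!r}")

    def uptake_enabled(self) -> set[str]:
        return {rid for rid, (lb, _) in self.bounds.items() if lb < 0}


@dataclass
class MediaConfig:
    """Nutrient -> exchange mapping and medium-generation settings.

    ``nutrient_uptake`` maps exchange ids to uptake-rate magnitudes for the
    reference medium.  Defaults (carbon sources -10, amino/fatty acids -1)
    are conventions, not measured rates, and are meant to be overridden per
    model dialect.
    """

    nutrient_uptake: dict[str, float] = field(default_factory=dict)
    oxygen_exchange: str | None = None
    always_available: tuple[str, ...] = ()
    secretion_ub: float = INTERNAL_INF
    random_lb_interval: tuple[float, float] = (-20.0, 0.0)
    random_ub_interval: tuple[float, float] = (0.0, 20.0)
    random_fraction_interval: tuple[float, float] = (0.04, 1.0)

    @classmethod
    def from_dict(cls, data: dict) -> "MediaConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "always_available" in kwargs:
            kwargs["always_available"] = tuple(kwargs["always_available"])
        for key in ("random_lb_interval", "random_ub_interval",
                    "random_fraction_interval"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def reference_medium(model: MetabolicModel, config: MediaConfig) -> Medium:
    """Minimal reference medium: uptake only for configured nutrients.

    Configured nutrients get their configured uptake rate; the oxygen
    exchange is left unconstrained (lb = -INTERNAL_INF); every other
    exchange is uptake-blocked with secretion open.  Configured nutrients
    without a matching exchange are skipped with a warning.
    """
    exchanges = set(model.exchange_reactions)
    bounds: dict[str, tuple[float, float]] = {
        rid: (0.0, config.secretion_ub) for rid in sorted(exchanges)}
    for rid, rate in config.nutrient_uptake.items():
        if rid not in exchanges:
            logger.warning("configured nutrient exchange %r not in model, "
                           "skipped", rid)
            continue
        bounds[rid] = (-abs(rate), config.secretion_ub)
    if config.oxygen_exchange:
        if config.oxygen_exchange in exchanges:
            bounds[config.oxygen_exchange] = (-INTERNAL_INF, config.secretion_ub)
        else:
            logger.warning("oxygen exchange %r not in model, skipped",
                           config.oxygen_exchange)
    for rid in config.always_available:
        if rid in exchanges:
            bounds[rid] = (-INTERNAL_INF, config.secretion_ub)
    return Medium(bounds=bounds, label="reference")


def random_medium(model: MetabolicModel, rng: np.random.Generator | int,
                  config: MediaConfig, label: str = "random") -> Medium:
    """Draw a random medium.

    A fraction f ~ U(fraction interval) of all exchanges is selected
    (without replacement); each selected exchange gets lb ~ U(lb interval)
    and ub ~ U(ub interval).  The always-available set is uptake-enabled
    (lb = -INTERNAL_INF) in every draw; unselected exchanges are
    uptake-blocked with secretion open.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    exchanges = sorted(model.exchange_reactions)
    if not exchanges:
        raise ModelError("model has no exchange reactions")
    lo, hi = config.random_fraction_interval
    fraction = float(rng.uniform(lo, hi))
    n_select = max(1, int(round(fraction * len(exchanges))))
    selected = sorted(rng.choice(exchanges, size=n_select, replace=False))
    bounds: dict[str, tuple[float, float]] = {
        rid: (0.0, config.secretion_ub) for rid in exchanges}
    for rid in selected:
        lb = float(rng.uniform(*config.random_lb_interval))
        ub = float(rng.uniform(*config.random_ub_interval))
        bounds[rid] = (lb, ub)
    for rid in config.always_available:
        if rid in bounds:
            bounds[rid] = (-INTERNAL_INF, config.secretion_ub)
    return Medium(bounds=bounds, label=label,
                  meta={"fraction": fraction, "selected": list(selected)})


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of *model* with exchange bounds overwritten by *medium*.

    Idempotent; non-exchange bounds are untouched.  Referencing a
    non-exchange reaction is a validation error.
    """
    exchanges = set(model.exchange_reactions)
    for rid in medium.bounds:
        if rid not in exchanges:
            raise ModelError(
                f"medium {medium.label!r} references non-exchange reaction {rid!r}")
    new = model.copy()
    for rid, (lb, ub) in medium.bounds.items():
        rxn = new.reactions[rid]
        rxn.lower_bound = lb
        rxn.upper_bound = ub
    new.metadata["medium"] = medium.label
    return new


def save_medium_json(medium: Medium, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"label": medium.label,
                   "bounds": {r: list(b) for r, b in medium.bounds.items()},
                   "meta": medium.meta}, fh, indent=2)


def load_medium_json(path: str) -> Medium:
    with open(path) as fh:
        data = json.load(fh)
    return Medium(bounds={r: (float(b[0]), float(b[1]))
                          for r, b in data["bounds"].items()},
                  label=data.get("label", "medium"),
                  meta=data.get("meta", {}))
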