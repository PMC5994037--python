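"""Length-of-stay sampling per subspecialty unit.

A patient admitted to a unit occupies one slot of its capacity for a
random length of stay (LOS) drawn from a per-subspecialty distribution.
Supported families: lognormal (the usual right-skewed choice for
emergency LOS), exponential, and a degenerate point mass (useful for
hand-traceable scenarios).  Parameters are in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import Subspecialty

__all__ = ["LosDistribution", "LosModel", "sample_los", "mean_los", "default_los_model"]

_FAMILIES = {"lognormal", "exponential", "point_mass"}


@dataclass(frozen=True)
class LosDistribution:
    """One LOS distribution: ``lognormal(mu, sigma)`` with ``mu`` on the
    log-minute scale, ``exponential(mean)``, or ``point_mass(value)``."""

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown LOS family {self.family!r}")
        p = self.params
        if self.family == "lognormal":
            if "mu" not in p or "sigma" not in p:
                raise ValueError("lognormal requires mu and sigma")
            if p["sigma"] < 0:
                raise ValueError("lognormal sigma must be non-negative")
        elif self.family == "exponential":
            if p.get("mean", 0) <= 0:
                raise ValueError("exponential requires mean > 0")
        else:  # point_mass
            if p.get("value", 0) <= 0:
                raise ValueError("point_mass requires value > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "lognormal":
            return float(rng.lognormal(self.params["mu"], self.params["sigma"]))
        if self.family == "exponential":
            return float(rng.exponential(self.params["mean"]))
        return float(self.params["value"])

    def mean(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2)
        if self.family == "exponential":
            return float(self.params["mean"])
        return float(self.params["value"])


@dataclass(frozen=True)
class LosModel:
    """Per-subspecialty LOS distributions."""

    distributions: Mapping[Subspecialty, LosDistribution]

    def _dist(self, subspecialty: Subspecialty) -> LosDistribution:
        try:
            return self.distributions[subspecialty]
        except KeyError:
            raise KeyError(f"no LOS distribution configured for {subspecialty.value}") from None

    def sample(self, subspecialty: Subspecialty, rng: np.random.Generator) -> float:
        return self._dist(subspecialty).sample(rng)

    def mean(self, subspecialty: Subspecialty) -> float:
        return self._dist(subspecialty).mean()

    @classmethod
    def point_mass(cls, value: float) -> "LosModel":
        """Degenerate model with the same fixed LOS for every subspecialty."""
        d = LosDistribution("point_mass", {"value": value})
        return cls({s: d for s in Subspecialty})

    @classmethod
    def exponential(cls, mean: float) -> "LosModel":
        d = LosDistribution("exponential", {"mean": mean})
        return cls({s: d for s in Subspecialty})


def sample_los(model: LosModel, subspecialty: Subspecialty, rng: np.random.Generator) -> float:
    """One strictly positive LOS draw; deterministic per rng state."""
    return model.sample(subspecialty, rng)


def mean_los(model: LosModel, subspecialty: Subspecialty) -> float:
    """Analytic mean of the configured distribution."""
    return model.mean(subspecialty)


def _lognormal_with_mean(mean_minutes: float, sigma: float) -> LosDistribution:
    mu = math.log(mean_minutes) - sigma**2 / 2
    return LosDistribution("lognormal", {"mu": mu, "sigma": sigma})


def default_los_model() -> LosModel:
    """Placeholder lognormal LOS model with per-unit means of a few hours.

    The original study's distribution parameters are not published;
    these defaults are plausible-scale stand-ins for exploratory runs
    and are meant to be overridden from the experiment configuration.
    """
    means = {
        Subspecialty.GENERAL_INTERNAL_MEDICINE: 240.0,
        Subspecialty.TRAUMA_SURGERY: 180.0,
        Subspecialty.NEUROLOGY: 300.0,
        Subspecialty.PEDIATRICS: 150.0,
        Subspecialty.CHEST_PAIN_UNIT: 210.0,
    }
    return LosModel({s: _lognormal_with_mean(m, 0.6) for s, m in means.items()})
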