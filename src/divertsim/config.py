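"""Experiment configuration: one YAML/JSON file describing network,
length-of-stay model, arrival generator, and status-quo schedule
statistics."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .arrivals import GeneratorConfig
from .los import LosDistribution, LosModel, default_los_model
from .network import Network, Subspecialty, build_network, default_network_config, estimate_capacities

__all__ = ["Experiment", "load_experiment", "default_experiment", "example_config_dict", "resolve_network"]


@dataclass(frozen=True)
class Experiment:
    network: Network
    generator: GeneratorConfig
    los: LosModel
    sq_mean_closed: float = 308.0
    sq_mean_open: float = 1101.0
    #: Seed of the single capacity-sizing pretest replication.
    capacity_seed: int = 20_160_107


def _parse_los(block: dict | None) -> LosModel:
    if not block:
        return default_los_model()
    dists = {}
    for sub_name, spec in block.items():
        sub = Subspecialty(sub_name)
        family = spec["family"]
        params = {k: float(v) for k, v in spec.items() if k != "family"}
        if family == "lognormal" and "mean" in params and "mu" not in params:
            sigma = params.get("sigma", 0.0)
            params = {"mu": math.log(params["mean"]) - sigma**2 / 2, "sigma": sigma}
        dists[sub] = LosDistribution(family, params)
    missing = [s.value for s in Subspecialty if s not in dists]
    if missing:
        raise ValueError(f"LOS block missing subspecialties: {', '.join(missing)}")
    return LosModel(dists)


def _parse_generator(block: dict | None) -> GeneratorConfig:
    if not block:
        return GeneratorConfig()
    kwargs: dict = {}
    for key in ("horizon", "expected_total"):
        if key in block:
            kwargs[key] = float(block[key])
    if "diurnal_profile" in block:
        kwargs["diurnal_profile"] = tuple(float(x) for x in block["diurnal_profile"])
    for key in ("subspecialty_mixture", "coverage"):
        if key in block:
            kwargs[key] = {Subspecialty(k): float(v) for k, v in block[key].items()}
    if "hospital_weights" in block:
        kwargs["hospital_weights"] = {
            Subspecialty(k): {u: float(w) for u, w in v.items()}
            for k, v in block["hospital_weights"].items()
        }
    return GeneratorConfig(**kwargs)


def load_experiment(path) -> Experiment:
    """Load an experiment description from a YAML or JSON file."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict) or "network" not in cfg:
        raise ValueError(f"{path}: expected a mapping with a 'network' block")
    sq = cfg.get("status_quo") or {}
    return Experiment(
        network=build_network(cfg["network"]),
        generator=_parse_generator(cfg.get("generator")),
        los=_parse_los(cfg.get("los")),
        sq_mean_closed=float(sq.get("mean_closed", 308.0)),
        sq_mean_open=float(sq.get("mean_open", 1101.0)),
        capacity_seed=int(cfg.get("capacity_seed", 20_160_107)),
    )


def default_experiment() -> Experiment:
    """The built-in synthetic experiment (default network, generator, LOS)."""
    return Experiment(
        network=build_network(default_network_config()),
        generator=GeneratorConfig(),
        los=default_los_model(),
    )


def resolve_network(experiment: Experiment, seed: int | None = None) -> Network:
    """Resolve ``auto`` capacities from a never-close pretest replication.

    Units with explicitly configured capacities keep them; each ``auto``
    unit gets the peak simultaneous census it saw during one unbounded
    pretest run driven by the experiment's generator.
    """
    from .arrivals import generate_arrivals

    net = experiment.network
    auto_units = [u.unit_id for u in net.real_units() if u.capacity is None]
    if not auto_units:
        return net
    s = experiment.capacity_seed if seed is None else seed
    stream = generate_arrivals(experiment.generator, net, seed=s)
    estimated = estimate_capacities(net, stream, experiment.los, seed=s)
    return net.with_capacities({uid: estimated[uid] for uid in auto_units})


def example_config_dict() -> dict:
    """A complete example configuration mirroring the built-in defaults."""
    gen = GeneratorConfig()
    return {
        "network": default_network_config(),
        "generator": {
            "horizon": gen.horizon,
            "expected_total": gen.expected_total,
            "diurnal_profile": [round(x, 6) for x in gen.diurnal_profile],
            "subspecialty_mixture": {s.value: round(p, 6) for s, p in gen.subspecialty_mixture.items()},
            "coverage": {s.value: p for s, p in gen.coverage.items()},
        },
        "los": {
            s.value: {"family": d.family, **{k: round(v, 6) for k, v in d.params.items()}}
            for s, d in default_los_model().distributions.items()
        },
        "status_quo": {"mean_closed": 308.0, "mean_open": 1101.0},
        "capacity_seed": 20_160_107,
    }
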