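"""Hospital network model: subspecialty units, geographic diversion, capacity sizing.

The modelled system is a city-wide emergency network: five subspecialty
areas (general internal medicine, trauma surgery, neurology, pediatrics,
chest pain unit), each offered by a handful of hospitals, plus one
always-open *virtual* overflow facility per subspecialty that stands in
for every hospital outside the model.  When a unit refuses an ambulance,
the patient is diverted once — to the geographically closest peer unit of
the same subspecialty — and, if that peer is unavailable too, to the
virtual facility.  No further search is performed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

__all__ = [
    "Subspecialty",
    "HospitalUnit",
    "Network",
    "build_network",
    "diversion_target",
    "estimate_capacities",
    "write_capacities_csv",
    "default_network_config",
    "VIRTUAL_HOSPITAL_ID",
]

VIRTUAL_HOSPITAL_ID = "VIRTUAL"

#: Sentinel accepted in configs for capacities resolved by pretest simulation.
AUTO = "auto"


class Subspecialty(str, Enum):
    """The five most frequently assigned subspecialty unit types."""

    GENERAL_INTERNAL_MEDICINE = "general_internal_medicine"
    TRAUMA_SURGERY = "trauma_surgery"
    NEUROLOGY = "neurology"
    PEDIATRICS = "pediatrics"
    CHEST_PAIN_UNIT = "chest_pain_unit"


@dataclass(frozen=True)
class HospitalUnit:
    """One subspecialty department of one hospital.

    ``capacity`` is the number of patients the unit can hold at once;
    ``None`` means not yet resolved (the ``auto`` sentinel) and
    ``math.inf`` means unbounded (virtual units only).
    ``location`` is a planar coordinate pair in arbitrary units; only
    relative Euclidean distances matter.
    """

    unit_id: str
    hospital_id: str
    subspecialty: Subspecialty
    capacity: float | None
    location: tuple[float, float]
    is_virtual: bool = False

    def __post_init__(self) -> None:
        if self.is_virtual:
            if self.capacity != math.inf:
                raise ValueError(f"virtual unit {self.unit_id} must be unbounded")
        elif self.capacity is not None:
            if not (self.capacity == math.inf or (float(self.capacity).is_integer() and self.capacity >= 1)):
                raise ValueError(
                    f"unit {self.unit_id}: capacity must be a positive integer, "
                    f"math.inf, or None (auto); got {self.capacity!r}"
                )


@dataclass(frozen=True)
class Network:
    """Immutable hospital network with a precomputed diversion map.

    ``closest_peer`` maps every real unit to the identifier of its
    geographically closest real peer of the same subspecialty (Euclidean
    distance on the configured coordinates, ties broken by
    lexicographically smallest unit id).  ``virtual_unit`` maps each
    subspecialty to its overflow facility.
    """

    units: Mapping[str, HospitalUnit]
    closest_peer: Mapping[str, str]
    virtual_unit: Mapping[Subspecialty, str]

    def real_units(self) -> list[HospitalUnit]:
        return [u for u in self.units.values() if not u.is_virtual]

    def unit(self, unit_id: str) -> HospitalUnit:
        try:
            return self.units[unit_id]
        except KeyError:
            raise KeyError(f"unknown unit {unit_id!r}") from None

    def with_capacities(self, capacities: Mapping[str, float]) -> "Network":
        """Return a copy with the given real-unit capacities resolved."""
        units = dict(self.units)
        for uid, cap in capacities.items():
            u = self.unit(uid)
            if u.is_virtual:
                raise ValueError(f"cannot set capacity of virtual unit {uid}")
            units[uid] = replace(u, capacity=float(cap))
        return Network(units=units, closest_peer=self.closest_peer, virtual_unit=self.virtual_unit)

    def unbounded(self) -> "Network":
        """Return a copy in which every real unit has infinite capacity.

        Used for the capacity-sizing pretest pass.
        """
        return self.with_capacities({u.unit_id: math.inf for u in self.real_units()})

    def resolved(self) -> bool:
        return all(u.capacity is not None for u in self.units.values())


def _euclidean(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def unit_id_for(hospital_id: str, subspecialty: Subspecialty) -> str:
    return f"{hospital_id}:{subspecialty.value}"


def build_network(config: Mapping) -> Network:
    """Construct a :class:`Network` from a parsed configuration mapping.

    Expected structure (YAML/JSON)::

        hospitals:
          - id: H1
            x: 0.0
            y: 0.0
            units:
              general_internal_medicine: auto   # or a positive integer
              trauma_surgery: 12

    One virtual overflow unit is appended per subspecialty present.
    Raises ``ValueError`` on duplicate hospital ids, missing
    coordinates, or a subspecialty offered by fewer than two hospitals.
    """
    hospitals = config.get("hospitals") or []
    if not hospitals:
        raise ValueError("config lists no hospitals")

    units: dict[str, HospitalUnit] = {}
    seen_hospitals: set[str] = set()
    for h in hospitals:
        hid = str(h.get("id", "")).strip()
        if not hid:
            raise ValueError("hospital entry without id")
        if hid in seen_hospitals:
            raise ValueError(f"duplicate hospital id {hid!r}")
        seen_hospitals.add(hid)
        if "x" not in h or "y" not in h or h["x"] is None or h["y"] is None:
            raise ValueError(f"hospital {hid}: missing coordinates")
        loc = (float(h["x"]), float(h["y"]))
        declared = h.get("units") or {}
        if not declared:
            raise ValueError(f"hospital {hid} declares no units")
        for sub_name, cap in declared.items():
            sub = Subspecialty(sub_name)
            if isinstance(cap, str):
                if cap.lower() != AUTO:
                    raise ValueError(f"hospital {hid}/{sub.value}: bad capacity {cap!r}")
                capacity: float | None = None
            elif cap is None:
                capacity = None
            else:
                capacity = float(cap)
                if not (capacity.is_integer() and capacity >= 1):
                    raise ValueError(f"hospital {hid}/{sub.value}: capacity must be a positive integer")
            uid = unit_id_for(hid, sub)
            if uid in units:
                raise ValueError(f"duplicate unit id {uid!r}")
            units[uid] = HospitalUnit(
                unit_id=uid, hospital_id=hid, subspecialty=sub, capacity=capacity, location=loc
            )

    by_sub: dict[Subspecialty, list[HospitalUnit]] = {}
    for u in units.values():
        by_sub.setdefault(u.subspecialty, []).append(u)
    for sub, members in by_sub.items():
        if len(members) < 2:
            raise ValueError(f"subspecialty {sub.value} has fewer than 2 real units")

    # Closest-peer map: minimum Euclidean distance, tie broken by unit id.
    closest: dict[str, str] = {}
    for sub, members in by_sub.items():
        for u in members:
            best = min(
                (m for m in members if m.unit_id != u.unit_id),
                key=lambda m: (_euclidean(u.location, m.location), m.unit_id),
            )
            closest[u.unit_id] = best.unit_id

    virtual: dict[Subspecialty, str] = {}
    for sub in by_sub:
        vid = unit_id_for(VIRTUAL_HOSPITAL_ID, sub)
        units[vid] = HospitalUnit(
            unit_id=vid,
            hospital_id=VIRTUAL_HOSPITAL_ID,
            subspecialty=sub,
            capacity=math.inf,
            location=(math.nan, math.nan),
            is_virtual=True,
        )
        virtual[sub] = vid

    return Network(units=units, closest_peer=closest, virtual_unit=virtual)


def diversion_target(
    network: Network,
    subspecialty: Subspecialty,
    origin_unit: str,
    closed_units: set[str] | frozenset[str],
) -> str:
    """Destination of a patient refused by ``origin_unit``.

    Exactly one diversion iteration is attempted: the precomputed
    geographically closest peer if it is not in ``closed_units``
    (callers include units at capacity in that set), otherwise the
    subspecialty's virtual overflow unit.  No search over the remaining
    open units is performed.
    """
    origin = network.unit(origin_unit)
    if origin.is_virtual:
        raise ValueError(f"virtual unit {origin_unit} cannot be a diversion origin")
    peer = network.closest_peer[origin_unit]
    if peer not in closed_units:
        return peer
    return network.virtual_unit[subspecialty]


def estimate_capacities(network: Network, arrivals, los_model, seed: int) -> dict[str, int]:
    """Size real units from a never-close, unbounded-capacity pretest run.

    Each unit's capacity is set to the highest number of patients
    simultaneously present in it during one simulation replication with
    the given seed; units that receive no patients get the floor of 1 so
    the crowding index stays defined.
    """
    from .engine import run_simulation  # local import to avoid a cycle
    from .policies import PolicySpec

    if not arrivals.records:
        raise ValueError("cannot estimate capacities from an empty arrival stream")
    log, _ = run_simulation(
        network.unbounded(), arrivals, los_model, PolicySpec.never_close(), seed=seed
    )
    peak: dict[str, int] = {u.unit_id: 0 for u in network.real_units()}
    for rec in log.records:
        if rec.event == "admit" and rec.unit_id in peak:
            peak[rec.unit_id] = max(peak[rec.unit_id], int(rec.census_after))
    return {uid: max(1, p) for uid, p in peak.items()}


def write_capacities_csv(capacities: Mapping[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "capacity"])
        for uid in sorted(capacities):
            w.writerow([uid, capacities[uid]])


def default_network_config() -> dict:
    """A synthetic five-hospital network on planar coordinates.

    Mirrors the modelled city's structure — five hospitals offering each
    subspecialty, only four of them running a pediatrics department —
    with invented coordinates; no real geography is encoded.
    """
    all_subs = [s.value for s in Subspecialty]
    no_peds = [s for s in all_subs if s != Subspecialty.PEDIATRICS.value]
    coords = {"H1": (0.0, 0.0), "H2": (6.0, 1.0), "H3": (2.0, 7.0), "H4": (8.0, 6.0), "H5": (4.0, 3.0)}
    hospitals = []
    for hid, (x, y) in coords.items():
        subs = no_peds if hid == "H5" else all_subs
        hospitals.append({"id": hid, "x": x, "y": y, "units": {s: AUTO for s in subs}})
    return {"hospitals": hospitals}
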