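"""Synthetic ambulance arrival streams and status-quo closure schedules.

The generator emulates the statistical structure of a city dispatch
system's arrival stream over a one-week horizon: a non-homogeneous
Poisson process with a diurnal intensity profile (overnight trough,
steep morning rise around 07:00-08:00, daytime plateau, evening
decline), a fixed subspecialty case mix, and per-subspecialty coverage
fractions routing the uncovered remainder directly to the virtual
overflow facility.  Status-quo closure schedules are drawn from an
alternating renewal process with exponential open and closed durations.

All times are minutes from horizon start; there is no calendar handling.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import Network, Subspecialty

__all__ = [
    "ArrivalRecord",
    "ArrivalStream",
    "GeneratorConfig",
    "ClosureSchedule",
    "generate_arrivals",
    "generate_status_quo_schedule",
    "read_arrivals_csv",
    "write_arrivals_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "DEFAULT_MIXTURE",
    "DEFAULT_COVERAGE",
    "DEFAULT_DIURNAL_PROFILE",
]

_SUBS = list(Subspecialty)

#: Relative case-mix frequencies of the five subspecialty unit types
#: (general internal medicine, trauma surgery, neurology, pediatrics,
#: chest pain unit), renormalized to sum to 1.
DEFAULT_MIXTURE: dict[Subspecialty, float] = dict(
    zip(_SUBS, (float(x) for x in np.array([0.4838, 0.3712, 0.0543, 0.0469, 0.0437]) / 0.9999))
)

#: Probability that an arrival of each subspecialty is covered by one of
#: the modelled units rather than going straight to the virtual facility.
DEFAULT_COVERAGE: dict[Subspecialty, float] = dict(
    zip(_SUBS, [0.504, 0.4995, 0.9691, 1.0, 0.5394])
)

# Piecewise-constant 24-bin diurnal curve: trough 02:00-06:00, steep rise
# 07:00-08:00, plateau 10:00-18:00, evening decline.  Normalized to mean 1
# below; the bin values are configuration, not measured data.
_RAW_PROFILE = np.array(
    [0.60, 0.50, 0.35, 0.30, 0.30, 0.35, 0.50, 0.90,
     1.40, 1.60, 1.70, 1.70, 1.70, 1.70, 1.60, 1.60,
     1.60, 1.50, 1.30, 1.10, 1.00, 0.90, 0.80, 0.70]
)
DEFAULT_DIURNAL_PROFILE: tuple[float, ...] = tuple(float(x) for x in _RAW_PROFILE / _RAW_PROFILE.mean())


@dataclass(frozen=True)
class ArrivalRecord:
    """One ambulance patient: arrival time, triaged subspecialty, assigned unit."""

    patient_id: int
    time: float
    subspecialty: Subspecialty
    assigned_unit: str


@dataclass(frozen=True)
class ArrivalStream:
    """Time-sorted arrivals over a finite horizon (minutes)."""

    records: tuple[ArrivalRecord, ...]
    horizon: float

    def __post_init__(self) -> None:
        times = [r.time for r in self.records]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("arrival records must be sorted by time")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")
        if times and (times[0] < 0 or times[-1] >= self.horizon):
            raise ValueError("arrival times must lie in [0, horizon)")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic arrival process.

    Defaults reproduce the study conditions: 2476 expected arrivals over
    a 7-day horizon (about 14 per hour), the five-way subspecialty
    mixture, and the per-subspecialty coverage fractions.
    """

    horizon: float = 10_080.0
    expected_total: float = 2476.0
    diurnal_profile: tuple[float, ...] = DEFAULT_DIURNAL_PROFILE
    subspecialty_mixture: Mapping[Subspecialty, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    coverage: Mapping[Subspecialty, float] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE)
    )
    #: Per-subspecialty assignment weights over real units; None = uniform.
    hospital_weights: Mapping[Subspecialty, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.expected_total < 0:
            raise ValueError("expected_total must be non-negative")
        prof = np.asarray(self.diurnal_profile, dtype=float)
        if prof.shape != (24,) or (prof < 0).any():
            raise ValueError("diurnal_profile must be 24 non-negative hourly multipliers")
        mix = np.array([self.subspecialty_mixture.get(s, 0.0) for s in _SUBS], dtype=float)
        if (mix < 0).any() or mix.sum() <= 0:
            raise ValueError("subspecialty_mixture must be non-negative with positive sum")
        for s, c in self.coverage.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coverage[{Subspecialty(s).value}] must be in [0, 1]")

    def mixture_vector(self) -> np.ndarray:
        mix = np.array([self.subspecialty_mixture.get(s, 0.0) for s in _SUBS], dtype=float)
        return mix / mix.sum()

    def profile_vector(self) -> np.ndarray:
        prof = np.asarray(self.diurnal_profile, dtype=float)
        mean = prof.mean()
        return prof / mean if mean > 0 else prof


@dataclass(frozen=True)
class ClosureSchedule:
    """Per-unit closed intervals ``[start, end)`` in minutes, disjoint and sorted."""

    intervals: Mapping[str, tuple[tuple[float, float], ...]]
    horizon: float

    def __post_init__(self) -> None:
        for uid, ivs in self.intervals.items():
            prev_end = -np.inf
            for start, end in ivs:
                if end <= start:
                    raise ValueError(f"{uid}: empty or inverted interval [{start}, {end})")
                if start < prev_end:
                    raise ValueError(f"{uid}: overlapping or unsorted intervals")
                if start < 0 or end > self.horizon:
                    raise ValueError(f"{uid}: interval [{start}, {end}) outside horizon")
                prev_end = end

    def closed_fraction(self, unit_id: str | None = None) -> float:
        """Fraction of the horizon spent closed (mean over units if no id given)."""
        if unit_id is not None:
            ivs = self.intervals.get(unit_id, ())
            return sum(e - s for s, e in ivs) / self.horizon
        if not self.intervals:
            return 0.0
        return float(np.mean([self.closed_fraction(u) for u in self.intervals]))


def generate_arrivals(config: GeneratorConfig, network: Network, seed: int) -> ArrivalStream:
    """Draw one synthetic arrival stream.

    Arrival times follow a non-homogeneous Poisson process simulated by
    thinning against the diurnal profile, with base rate
    ``expected_total / horizon`` per minute.  Each arrival is triaged a
    subspecialty from the mixture; with the subspecialty's coverage
    probability it is assigned to a real unit drawn by
    ``hospital_weights`` (uniform by default), otherwise to the virtual
    overflow unit.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    profile = config.profile_vector()
    base = config.expected_total / config.horizon  # per minute
    lam_max = base * profile.max()

    if lam_max <= 0:
        return ArrivalStream(records=(), horizon=config.horizon)

    # Homogeneous candidates at lam_max, thinned by profile/max.
    n_cand = rng.poisson(lam_max * config.horizon)
    cand = np.sort(rng.uniform(0.0, config.horizon, size=n_cand))
    hour_bin = (cand // 60).astype(int) % 24
    keep = rng.uniform(size=n_cand) < profile[hour_bin] / profile.max()
    times = cand[keep]

    n = times.size
    mix = config.mixture_vector()
    sub_idx = rng.choice(len(_SUBS), size=n, p=mix)
    covered = rng.uniform(size=n)

    real_by_sub: dict[Subspecialty, list[str]] = {
        s: sorted(u.unit_id for u in network.real_units() if u.subspecialty == s)
        for s in _SUBS
    }

    records = []
    for i in range(n):
        sub = _SUBS[sub_idx[i]]
        cov = config.coverage.get(sub, 1.0)
        pool = real_by_sub.get(sub, [])
        if pool and covered[i] < cov:
            if config.hospital_weights and sub in config.hospital_weights:
                w = np.array([config.hospital_weights[sub].get(u, 0.0) for u in pool], dtype=float)
                unit = pool[rng.choice(len(pool), p=w / w.sum())]
            else:
                unit = pool[rng.integers(len(pool))]
        else:
            unit = network.virtual_unit[sub]
        records.append(
            ArrivalRecord(patient_id=i + 1, time=float(times[i]), subspecialty=sub, assigned_unit=unit)
        )
    return ArrivalStream(records=tuple(records), horizon=config.horizon)


def generate_status_quo_schedule(
    unit_ids: Sequence[str],
    horizon: float,
    mean_closed: float = 308.0,
    mean_open: float = 1101.0,
    seed: int = 0,
) -> ClosureSchedule:
    """Synthesize closure schedules as an alternating renewal process.

    Per unit, open gaps and closed durations are drawn independently
    from exponential distributions with the given means (defaults: the
    observed mean closed duration of 308 min and the mean inter-closure
    interval of 1101 min), truncated at the horizon.
    """
    if mean_closed <= 0 or mean_open <= 0:
        raise ValueError("mean_closed and mean_open must be positive")
    rng = np.random.default_rng(seed)
    intervals: dict[str, tuple[tuple[float, float], ...]] = {}
    for uid in unit_ids:
        t = 0.0
        ivs: list[tuple[float, float]] = []
        while True:
            t += rng.exponential(mean_open)
            if t >= horizon:
                break
            end = min(t + rng.exponential(mean_closed), horizon)
            ivs.append((t, end))
            t = end
            if t >= horizon:
                break
        intervals[uid] = tuple(ivs)
    return ClosureSchedule(intervals=intervals, horizon=horizon)


_CSV_HEADER = ["patient_id", "time_min", "subspecialty", "assigned_unit"]


def write_arrivals_csv(stream: ArrivalStream, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for r in stream.records:
            w.writerow([r.patient_id, repr(r.time), r.subspecialty.value, r.assigned_unit])


def read_arrivals_csv(path, network: Network | None = None, horizon: float | None = None) -> ArrivalStream:
    """Read an arrival stream, validating each row.

    Malformed rows raise ``ValueError`` naming the offending line;
    unsorted input is sorted with a warning.  If a network is supplied,
    assigned units are checked to exist and match the subspecialty.
    """
    records: list[ArrivalRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _CSV_HEADER:
            raise ValueError(f"{path}: expected header {','.join(_CSV_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                pid = int(row[0])
                t = float(row[1])
                sub = Subspecialty(row[2].strip())
                unit = row[3].strip()
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}, line {lineno}: malformed row ({exc})") from None
            if t < 0:
                raise ValueError(f"{path}, line {lineno}: negative arrival time {t}")
            if network is not None:
                u = network.unit(unit)
                if u.subspecialty is not sub:
                    raise ValueError(
                        f"{path}, line {lineno}: unit {unit} is {u.subspecialty.value}, "
                        f"record says {sub.value}"
                    )
            records.append(ArrivalRecord(patient_id=pid, time=t, subspecialty=sub, assigned_unit=unit))

    times = [r.time for r in records]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        warnings.warn(f"{path}: arrival times not sorted; sorting", stacklevel=2)
        records.sort(key=lambda r: (r.time, r.patient_id))
    if horizon is None:
        horizon = (max(t for t in times) + 1.0) if times else 0.0
        horizon = max(horizon, float(np.ceil(horizon)))
    return ArrivalStream(records=tuple(records), horizon=horizon)


def write_schedule_csv(schedule: ClosureSchedule, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", "start_min", "end_min"])
        for uid in sorted(schedule.intervals):
            for start, end in schedule.intervals[uid]:
                w.writerow([uid, repr(start), repr(end)])


def read_schedule_csv(path, horizon: float) -> ClosureSchedule:
    intervals: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["unit_id", "start_min", "end_min"]:
            raise ValueError(f"{path}: expected header unit_id,start_min,end_min")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                uid, start, end = row[0].strip(), float(row[1]), float(row[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}, line {lineno}: malformed row ({exc})") from None
            intervals.setdefault(uid, []).append((start, end))
    return ClosureSchedule(
        intervals={u: tuple(sorted(ivs)) for u, ivs in intervals.items()}, horizon=horizon
    )
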