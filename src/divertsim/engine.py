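"""Discrete-event kernel for the hospital-network diversion simulation.

Processes one arrival stream over the network under a single closure
policy.  The event queue is a binary heap ordered by time with
deterministic tie-breaking: departures first (a departing patient frees
capacity for a simultaneous arrival), then reopen timers, then schedule
transitions, then arrivals; equal-rank ties fall back to insertion
order.  Everything is logged, and every run is fully reproducible from
its seed.

Semantics of one arrival:

* assigned to a virtual unit — admitted there unconditionally;
* assigned unit open and below capacity — admitted; length of stay is
  drawn, a departure is scheduled, and the unit's close trigger is
  evaluated;
* otherwise — diverted once, to the precomputed geographically closest
  peer if that peer is open and below capacity (the peer's close
  trigger is evaluated after the admission), else to the virtual
  overflow unit.

Departures decrement the census and, under threshold-reopen policies,
evaluate the reopen condition.  A reopen timer reopens the unit and
immediately re-evaluates the close trigger, so a still-crowded unit may
re-close at the same instant.  Patients still in service when the
horizon ends keep their outcome but are flagged ``in_system_at_end``;
closures still open are truncated at the horizon.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from . import metrics as _metrics
from .arrivals import ArrivalStream, ClosureSchedule, GeneratorConfig, generate_arrivals, generate_status_quo_schedule
from .los import LosModel
from .network import Network, diversion_target
from .policies import (
    ClosureState,
    PolicyKind,
    PolicySpec,
    crowding_index,
    should_close,
    should_reopen,
)

__all__ = [
    "Outcome",
    "PatientOutcome",
    "LogRecord",
    "EventLog",
    "run_simulation",
    "run_replications",
    "write_event_log_csv",
]

# Tie ranks at equal event times.
_RANK_DEPART = 0
_RANK_REOPEN_TIMER = 1
_RANK_SCHED_REOPEN = 2
_RANK_SCHED_CLOSE = 3
_RANK_ARRIVAL = 4


class Outcome(Enum):
    TREATED_PRIMARY = "treated_primary"
    DIVERTED_ALTERNATIVE = "diverted_alternative"
    DIVERTED_OVERFLOW = "diverted_overflow"


@dataclass
class PatientOutcome:
    patient_id: int
    outcome: Outcome
    intended_unit: str
    treating_unit: str
    admit_time: float
    depart_time: float | None = None
    in_system_at_end: bool = False


@dataclass(frozen=True)
class LogRecord:
    """One state transition: arrival, admit, divert, depart, close, reopen.

    ``census_after``/``ci_after`` refer to the named unit after the
    transition; ``ci_after`` is ``None`` for unbounded (virtual) units.
    """

    time: float
    event: str
    unit_id: str
    patient_id: int | None
    census_after: int
    ci_after: float | None


@dataclass(frozen=True)
class EventLog:
    records: tuple[LogRecord, ...]
    horizon: float


class _Sim:
    def __init__(
        self,
        network: Network,
        arrivals: ArrivalStream,
        los_model: LosModel,
        policy: PolicySpec,
        schedule: ClosureSchedule | None,
        seed: int,
    ):
        if not network.resolved():
            raise ValueError("network has unresolved (auto) capacities; run estimate_capacities first")
        if policy.kind is PolicyKind.SCHEDULE_REPLAY and schedule is None:
            raise ValueError("SCHEDULE_REPLAY policy requires a closure schedule")
        if policy.kind is not PolicyKind.SCHEDULE_REPLAY and schedule is not None:
            raise ValueError(f"policy {policy.label} does not take a schedule")

        self.network = network
        self.policy = policy
        self.horizon = arrivals.horizon
        self.rng = np.random.default_rng(seed)
        self.los_model = los_model

        self.census: dict[str, int] = {uid: 0 for uid in network.units}
        self.state: dict[str, ClosureState] = {
            u.unit_id: ClosureState() for u in network.real_units()
        }
        self.occ_integral: dict[str, float] = {uid: 0.0 for uid in network.units}
        self.last_change: dict[str, float] = {uid: 0.0 for uid in network.units}
        self.outcomes: dict[int, PatientOutcome] = {}
        self.records: list[LogRecord] = []

        self.heap: list[tuple] = []
        self.seq = 0
        for rec in arrivals.records:
            self.network.unit(rec.assigned_unit)  # raises on unknown unit
            self._push(rec.time, _RANK_ARRIVAL, ("arrival", rec))
        if schedule is not None:
            for uid, ivs in schedule.intervals.items():
                self.network.unit(uid)
                for start, end in ivs:
                    if start < self.horizon:
                        self._push(start, _RANK_SCHED_CLOSE, ("sched_close", uid))
                    if end < self.horizon:
                        self._push(end, _RANK_SCHED_REOPEN, ("sched_reopen", uid))

    def _push(self, time: float, rank: int, payload: tuple) -> None:
        heapq.heappush(self.heap, (time, rank, self.seq, payload))
        self.seq += 1

    def _ci(self, uid: str) -> float | None:
        cap = self.network.unit(uid).capacity
        if math.isinf(cap):
            return None
        return crowding_index(self.census[uid], cap)

    def _log(self, time: float, event: str, uid: str, pid: int | None) -> None:
        self.records.append(
            LogRecord(
                time=time,
                event=event,
                unit_id=uid,
                patient_id=pid,
                census_after=self.census[uid],
                ci_after=self._ci(uid),
            )
        )

    def _bump_integral(self, uid: str, t: float) -> None:
        self.occ_integral[uid] += self.census[uid] * (t - self.last_change[uid])
        self.last_change[uid] = t

    # -- transitions -------------------------------------------------------

    def _available(self, uid: str) -> bool:
        u = self.network.unit(uid)
        if u.is_virtual:
            return True
        if uid in self.state and self.state[uid].is_closed:
            return False
        return self.census[uid] < u.capacity

    def _admit(self, t: float, patient, uid: str) -> None:
        rec = patient
        self._bump_integral(uid, t)
        self.census[uid] += 1
        self._log(t, "admit", uid, rec.patient_id)
        u = self.network.unit(uid)
        if uid == rec.assigned_unit:
            outcome = Outcome.TREATED_PRIMARY
        elif u.is_virtual:
            outcome = Outcome.DIVERTED_OVERFLOW
        else:
            outcome = Outcome.DIVERTED_ALTERNATIVE
        self.outcomes[rec.patient_id] = PatientOutcome(
            patient_id=rec.patient_id,
            outcome=outcome,
            intended_unit=rec.assigned_unit,
            treating_unit=uid,
            admit_time=t,
        )
        los = self.los_model.sample(rec.subspecialty, self.rng)
        self._push(t + los, _RANK_DEPART, ("depart", uid, rec.patient_id))
        # Close trigger fires at the admission that reaches the threshold.
        if (
            not u.is_virtual
            and self.policy.kind in (PolicyKind.THRESHOLD_REOPEN, PolicyKind.TIMED)
            and not self.state[uid].is_closed
            and should_close(self.policy, self.census[uid], u.capacity)
        ):
            self._close(t, uid)

    def _close(self, t: float, uid: str) -> None:
        reopen_at = None
        if self.policy.kind is PolicyKind.TIMED:
            reopen_at = t + self.policy.duration
            self._push(reopen_at, _RANK_REOPEN_TIMER, ("reopen_timer", uid))
        self.state[uid].close(t, reopen_at)
        self._log(t, "close", uid, None)

    def _reopen(self, t: float, uid: str) -> None:
        self.state[uid].reopen(t)
        self._log(t, "reopen", uid, None)

    def _on_arrival(self, t: float, rec) -> None:
        uid = rec.assigned_unit
        self._log(t, "arrival", uid, rec.patient_id)
        if self.network.unit(uid).is_virtual or self._available(uid):
            self._admit(t, rec, uid)
            return
        unavailable = {
            u.unit_id
            for u in self.network.real_units()
            if u.subspecialty is rec.subspecialty and not self._available(u.unit_id)
        }
        target = diversion_target(self.network, rec.subspecialty, uid, unavailable)
        self._log(t, "divert", uid, rec.patient_id)
        self._admit(t, rec, target)

    def _on_depart(self, t: float, uid: str, pid: int) -> None:
        self._bump_integral(uid, t)
        self.census[uid] -= 1
        self._log(t, "depart", uid, pid)
        out = self.outcomes[pid]
        out.depart_time = t
        u = self.network.unit(uid)
        if (
            not u.is_virtual
            and self.policy.kind is PolicyKind.THRESHOLD_REOPEN
            and self.state[uid].is_closed
            and should_reopen(self.policy, self.state[uid], self.census[uid], u.capacity, t)
        ):
            self._reopen(t, uid)

    def _on_reopen_timer(self, t: float, uid: str) -> None:
        u = self.network.unit(uid)
        if not self.state[uid].is_closed:
            return
        self._reopen(t, uid)
        if should_close(self.policy, self.census[uid], u.capacity):
            self._close(t, uid)

    def run(self) -> tuple[EventLog, "_metrics.RunMetrics"]:
        while self.heap:
            t, rank, _, payload = heapq.heappop(self.heap)
            if t > self.horizon:
                break
            kind = payload[0]
            if kind == "arrival":
                self._on_arrival(t, payload[1])
            elif kind == "depart":
                self._on_depart(t, payload[1], payload[2])
            elif kind == "reopen_timer":
                self._on_reopen_timer(t, payload[1])
            elif kind == "sched_close":
                uid = payload[1]
                if not self.state[uid].is_closed:
                    self.state[uid].close(t)
                    self._log(t, "close", uid, None)
            elif kind == "sched_reopen":
                uid = payload[1]
                if self.state[uid].is_closed:
                    self._reopen(t, uid)

        for uid in self.network.units:
            self._bump_integral(uid, self.horizon)
        for st in self.state.values():
            st.finalize(self.horizon)
        for out in self.outcomes.values():
            if out.depart_time is None:
                out.in_system_at_end = True

        log = EventLog(records=tuple(self.records), horizon=self.horizon)
        raw = _metrics.RawCollectors(
            counts=_metrics.count_outcomes(self.outcomes.values(), self.network),
            closures={uid: tuple(st.completed_closures) for uid, st in self.state.items()},
            occ_integral=dict(self.occ_integral),
        )
        metrics = _metrics.build_metrics(raw, self.network, self.horizon)
        return log, metrics


def run_simulation(
    network: Network,
    arrivals: ArrivalStream,
    los_model: LosModel,
    policy: PolicySpec,
    schedule: ClosureSchedule | None = None,
    seed: int = 0,
    return_outcomes: bool = False,
):
    """Simulate one arrival stream under one policy.

    Returns ``(EventLog, RunMetrics)``, or
    ``(EventLog, RunMetrics, {patient_id: PatientOutcome})`` when
    ``return_outcomes`` is set.  Deterministic per seed.
    """
    sim = _Sim(network, arrivals, los_model, policy, schedule, seed)
    log, metrics = sim.run()
    if return_outcomes:
        return log, metrics, sim.outcomes
    return log, metrics


def _derive_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def run_replications(
    network: Network,
    generator_config: GeneratorConfig,
    los_model: LosModel,
    policies: Sequence[PolicySpec],
    n_reps: int,
    base_seed: int,
    sq_mean_closed: float = 308.0,
    sq_mean_open: float = 1101.0,
) -> dict[str, "_metrics.PolicySummary"]:
    """Run each policy arm over ``n_reps`` independently generated streams.

    Within a replication every arm sees the same arrival stream (paired
    comparison); length-of-stay draws use an arm-specific seed derived
    from ``base_seed``.  The SQ arm replays a freshly synthesized
    status-quo schedule per replication.  Returns one
    :class:`~divertsim.metrics.PolicySummary` per policy label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    per_arm: dict[str, list["_metrics.RunMetrics"]] = {p.label: [] for p in policies}
    real_uids = sorted(u.unit_id for u in network.real_units())
    for rep in range(n_reps):
        stream = generate_arrivals(
            generator_config, network, seed=_derive_seed(base_seed, rep, 0)
        )
        for arm_idx, policy in enumerate(policies):
            schedule = None
            if policy.kind is PolicyKind.SCHEDULE_REPLAY:
                schedule = generate_status_quo_schedule(
                    real_uids,
                    generator_config.horizon,
                    mean_closed=sq_mean_closed,
                    mean_open=sq_mean_open,
                    seed=_derive_seed(base_seed, rep, 1),
                )
            _, metrics = run_simulation(
                network,
                stream,
                los_model,
                policy,
                schedule=schedule,
                seed=_derive_seed(base_seed, rep, 2 + arm_idx),
            )
            per_arm[policy.label].append(metrics)
    return {
        label: _metrics.PolicySummary.from_runs(label, runs)
        for label, runs in per_arm.items()
    }


def write_event_log_csv(log: EventLog, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_min", "event", "unit_id", "patient_id", "census_after", "ci_after"])
        for r in log.records:
            w.writerow(
                [
                    repr(r.time),
                    r.event,
                    r.unit_id,
                    "" if r.patient_id is None else r.patient_id,
                    r.census_after,
                    "" if r.ci_after is None else repr(r.ci_after),
                ]
            )
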