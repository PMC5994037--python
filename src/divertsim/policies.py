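"""Crowding index and the closure/reopening rules.

A unit's *crowding index* (CI) is its current census divided by its
capacity: CI = 1 means full occupancy, CI = 0.8 means 80% occupied.

Nine policy variants are modelled, plus two pseudo-policies:

========  =====================================================
label     rule
========  =====================================================
P1_100    close when CI = 1, reopen when CI < 1
P1_80     close when CI = 1, reopen when CI = 0.8
P1_60     close when CI = 1, reopen when CI = 0.6
P2_6      close when CI = 1, reopen after 6 h
P2_12     close when CI = 1, reopen after 12 h
P2_24     close when CI = 1, reopen after 24 h
P3_80_6   close when CI = 0.8, reopen after 6 h
P3_80_12  close when CI = 0.8, reopen after 12 h
P3_80_24  close when CI = 0.8, reopen after 24 h
SQ        replay an externally supplied closure schedule
OPEN      never close (pretest / capacity-sizing runs)
========  =====================================================

Fractional CI thresholds meet integer censuses conservatively: the
close trigger uses the ceiling of ``trigger_ci * capacity`` and the
reopen condition the floor of ``reopen_ci * capacity`` — the unit
closes no later and reopens no earlier than the real-valued rule.
When trigger and reopen CI coincide (P1_100) the reopen census bound is
lowered by one so the two conditions are never simultaneously true.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .arrivals import ClosureSchedule

__all__ = [
    "PolicyKind",
    "PolicySpec",
    "ClosureState",
    "POLICY_LABELS",
    "crowding_index",
    "should_close",
    "should_reopen",
    "schedule_is_closed",
]

_EPS = 1e-9  # guards ceil/floor against float representation of CI fractions


class PolicyKind(Enum):
    THRESHOLD_REOPEN = "threshold_reopen"
    TIMED = "timed"
    SCHEDULE_REPLAY = "schedule_replay"
    NEVER_CLOSE = "never_close"


@dataclass(frozen=True)
class PolicySpec:
    """One closure/reopening rule.

    ``trigger_ci`` is the crowding index at which an open unit closes;
    ``reopen_ci`` (threshold policies) the index at or below which it
    reopens; ``duration`` (timed policies) the fixed closure length in
    minutes.
    """

    kind: PolicyKind
    label: str
    trigger_ci: float | None = None
    reopen_ci: float | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.kind is PolicyKind.THRESHOLD_REOPEN:
            if not (self.trigger_ci and 0 < self.trigger_ci <= 1):
                raise ValueError("threshold policy needs trigger_ci in (0, 1]")
            if self.reopen_ci is None or not (0 < self.reopen_ci <= self.trigger_ci):
                raise ValueError("threshold policy needs 0 < reopen_ci <= trigger_ci")
        elif self.kind is PolicyKind.TIMED:
            if not (self.trigger_ci and 0 < self.trigger_ci <= 1):
                raise ValueError("timed policy needs trigger_ci in (0, 1]")
            if not self.duration or self.duration <= 0:
                raise ValueError("timed policy needs a positive duration")

    @classmethod
    def threshold(cls, label: str, trigger_ci: float, reopen_ci: float) -> "PolicySpec":
        return cls(PolicyKind.THRESHOLD_REOPEN, label, trigger_ci=trigger_ci, reopen_ci=reopen_ci)

    @classmethod
    def timed(cls, label: str, trigger_ci: float, duration: float) -> "PolicySpec":
        return cls(PolicyKind.TIMED, label, trigger_ci=trigger_ci, duration=duration)

    @classmethod
    def schedule_replay(cls) -> "PolicySpec":
        return cls(PolicyKind.SCHEDULE_REPLAY, "SQ")

    @classmethod
    def never_close(cls) -> "PolicySpec":
        return cls(PolicyKind.NEVER_CLOSE, "OPEN")

    @classmethod
    def from_label(cls, label: str) -> "PolicySpec":
        try:
            return POLICY_LABELS[label]
        except KeyError:
            raise ValueError(
                f"unknown policy label {label!r}; known: {', '.join(POLICY_LABELS)}"
            ) from None


POLICY_LABELS: dict[str, PolicySpec] = {
    "P1_100": PolicySpec.threshold("P1_100", 1.0, 1.0),
    "P1_80": PolicySpec.threshold("P1_80", 1.0, 0.8),
    "P1_60": PolicySpec.threshold("P1_60", 1.0, 0.6),
    "P2_6": PolicySpec.timed("P2_6", 1.0, 360.0),
    "P2_12": PolicySpec.timed("P2_12", 1.0, 720.0),
    "P2_24": PolicySpec.timed("P2_24", 1.0, 1440.0),
    "P3_80_6": PolicySpec.timed("P3_80_6", 0.8, 360.0),
    "P3_80_12": PolicySpec.timed("P3_80_12", 0.8, 720.0),
    "P3_80_24": PolicySpec.timed("P3_80_24", 0.8, 1440.0),
    "SQ": PolicySpec.schedule_replay(),
    "OPEN": PolicySpec.never_close(),
}


@dataclass
class ClosureState:
    """Per-unit closure bookkeeping during a simulation run."""

    is_closed: bool = False
    closed_since: float | None = None
    scheduled_reopen: float | None = None
    completed_closures: list[tuple[float, float]] = field(default_factory=list)

    def close(self, clock: float, reopen_at: float | None = None) -> None:
        if self.is_closed:
            raise RuntimeError("close() on a closed unit")
        self.is_closed = True
        self.closed_since = clock
        self.scheduled_reopen = reopen_at

    def reopen(self, clock: float) -> None:
        if not self.is_closed:
            raise RuntimeError("reopen() on an open unit")
        assert self.closed_since is not None
        self.completed_closures.append((self.closed_since, clock))
        self.is_closed = False
        self.closed_since = None
        self.scheduled_reopen = None

    def finalize(self, horizon: float) -> None:
        """Truncate a closure still open at horizon end."""
        if self.is_closed:
            assert self.closed_since is not None
            if horizon > self.closed_since:
                self.completed_closures.append((self.closed_since, horizon))
            self.is_closed = False
            self.closed_since = None
            self.scheduled_reopen = None


def crowding_index(census: int, capacity: float) -> float:
    """census / capacity, exact, no rounding; 0.0 for unbounded capacity."""
    if capacity is None or capacity <= 0:
        raise ValueError("capacity must be >= 1")
    if census < 0:
        raise ValueError("census must be non-negative")
    if math.isinf(capacity):
        return 0.0
    return census / capacity


def _trigger_census(policy: PolicySpec, capacity: float) -> float:
    return math.ceil(policy.trigger_ci * capacity - _EPS)


def should_close(policy: PolicySpec, census: int, capacity: float) -> bool:
    """Whether an open unit must close now.

    True iff census has reached the trigger occupancy
    ``ceil(trigger_ci * capacity)``.  Pseudo-policies never close.
    """
    if policy.kind not in (PolicyKind.THRESHOLD_REOPEN, PolicyKind.TIMED):
        return False
    if math.isinf(capacity):
        return False
    return census >= _trigger_census(policy, capacity)


def should_reopen(
    policy: PolicySpec,
    state: ClosureState,
    census: int,
    capacity: float,
    clock: float,
) -> bool:
    """Whether a closed unit must reopen now.

    Threshold policies reopen when census is at or below
    ``floor(reopen_ci * capacity)``, minus one when the reopen and
    trigger indices coincide (so "reopen when CI < 1" means census
    strictly below capacity).  Timed policies reopen once the fixed
    closure duration has elapsed.
    """
    if policy.kind is PolicyKind.THRESHOLD_REOPEN:
        bound = math.floor(policy.reopen_ci * capacity + _EPS)
        if policy.reopen_ci == policy.trigger_ci:
            bound -= 1
        return census <= bound
    if policy.kind is PolicyKind.TIMED:
        assert state.closed_since is not None
        return clock >= state.closed_since + policy.duration
    return False


def schedule_is_closed(schedule: ClosureSchedule, unit_id: str, clock: float) -> bool:
    """Whether ``clock`` falls in one of the unit's closed intervals [start, end)."""
    if unit_id not in schedule.intervals:
        raise KeyError(f"schedule does not cover unit {unit_id!r}")
    for start, end in schedule.intervals[unit_id]:
        if start <= clock < end:
            return True
        if clock < start:
            break
    return False
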