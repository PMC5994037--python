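"""Outcome metrics, log replay, and report writing.

Every quantity the simulation reports — treated and diverted counts,
closure durations and inter-closure intervals, utilized capacity — can
be recomputed from the event log alone; :func:`summarize` does exactly
that and must agree with the engine's online collectors field by field,
which makes the log a self-contained audit trail.

Table arithmetic helpers (:func:`relative_frequencies`,
:func:`coverage_product`, :func:`divert_treat_ratio`) implement the
derived-column computations of the study's summary tables.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .network import Network

if TYPE_CHECKING:  # pragma: no cover
    from .engine import EventLog, PatientOutcome

__all__ = [
    "UnitCounts",
    "UnitMetrics",
    "RunMetrics",
    "PolicySummary",
    "RawCollectors",
    "summarize",
    "divert_treat_ratio",
    "relative_frequencies",
    "coverage_product",
    "write_summary",
    "write_metrics",
]


@dataclass(frozen=True)
class UnitCounts:
    """Patient-flow counts attributed to one unit."""

    treated_primary: int = 0
    diverted_out_alternative: int = 0
    diverted_out_overflow: int = 0
    diverted_in: int = 0


@dataclass(frozen=True)
class UnitMetrics:
    counts: UnitCounts
    closures: tuple[tuple[float, float], ...]
    closure_total: float
    closure_count: int
    mean_closure: float | None
    mean_interclosure: float | None
    closure_fraction: float  # percent of horizon
    time_avg_census: float
    mean_utilized_capacity: float | None  # None for unbounded units


@dataclass(frozen=True)
class RunMetrics:
    """All outcome metrics of one simulation run.

    Totals cover the real (modelled) units: ``treated`` counts patients
    admitted to their originally assigned real unit,
    ``diverted_alternative``/``diverted_overflow`` those refused by it,
    and ``virtual_assigned`` patients routed straight to the overflow
    facility at triage.  ``closure_fraction`` is the mean per-unit
    percentage of the horizon spent closed; ``forced_assignments`` is
    an outcome variable named in the study design without a definition
    and is reported as a fixed zero placeholder.
    """

    horizon: float
    per_unit: Mapping[str, UnitMetrics]
    treated: int
    diverted_alternative: int
    diverted_overflow: int
    virtual_assigned: int
    closure_total: float
    closure_count: int
    mean_closure: float | None
    mean_interclosure: float | None
    closure_fraction: float
    mean_utilized_capacity: float | None
    forced_assignments: int = 0

    @property
    def diverted(self) -> int:
        return self.diverted_alternative + self.diverted_overflow


@dataclass(frozen=True)
class RawCollectors:
    """The engine's online collectors (also reconstructible from the log)."""

    counts: Mapping[str, UnitCounts]
    closures: Mapping[str, tuple[tuple[float, float], ...]]
    occ_integral: Mapping[str, float]


def count_outcomes(outcomes: Iterable["PatientOutcome"], network: Network) -> dict[str, UnitCounts]:
    acc = {
        uid: {"treated_primary": 0, "diverted_out_alternative": 0, "diverted_out_overflow": 0, "diverted_in": 0}
        for uid in network.units
    }
    for out in outcomes:
        if out.treating_unit == out.intended_unit:
            acc[out.intended_unit]["treated_primary"] += 1
        else:
            if network.unit(out.treating_unit).is_virtual:
                acc[out.intended_unit]["diverted_out_overflow"] += 1
            else:
                acc[out.intended_unit]["diverted_out_alternative"] += 1
            acc[out.treating_unit]["diverted_in"] += 1
    return {uid: UnitCounts(**v) for uid, v in acc.items()}


def _closure_stats(closures: Sequence[tuple[float, float]], horizon: float):
    total = sum(e - s for s, e in closures)
    count = len(closures)
    mean_closure = total / count if count else None
    gaps = [closures[i + 1][0] - closures[i][1] for i in range(count - 1)]
    mean_inter = sum(gaps) / len(gaps) if gaps else None
    fraction = 100.0 * total / horizon
    return total, count, mean_closure, mean_inter, fraction


def build_metrics(raw: RawCollectors, network: Network, horizon: float) -> RunMetrics:
    """Assemble :class:`RunMetrics` from raw collectors (online or replayed)."""
    per_unit: dict[str, UnitMetrics] = {}
    for uid, unit in network.units.items():
        closures = raw.closures.get(uid, ())
        total, count, mean_c, mean_i, frac = _closure_stats(closures, horizon)
        occ = raw.occ_integral.get(uid, 0.0)
        cap = unit.capacity
        util = None if (cap is None or math.isinf(cap)) else occ / (horizon * cap)
        per_unit[uid] = UnitMetrics(
            counts=raw.counts.get(uid, UnitCounts()),
            closures=tuple(closures),
            closure_total=total,
            closure_count=count,
            mean_closure=mean_c,
            mean_interclosure=mean_i,
            closure_fraction=frac,
            time_avg_census=occ / horizon,
            mean_utilized_capacity=util,
        )

    real = [u.unit_id for u in network.real_units()]
    virtual = [uid for uid in network.units if uid not in real]
    treated = sum(per_unit[u].counts.treated_primary for u in real)
    div_alt = sum(per_unit[u].counts.diverted_out_alternative for u in real)
    div_ovf = sum(per_unit[u].counts.diverted_out_overflow for u in real)
    virt_assigned = sum(per_unit[u].counts.treated_primary for u in virtual)
    closure_total = sum(per_unit[u].closure_total for u in real)
    closure_count = sum(per_unit[u].closure_count for u in real)
    all_closures = [per_unit[u].mean_closure for u in real if per_unit[u].mean_closure is not None]
    mean_closure = closure_total / closure_count if closure_count else None
    gaps = []
    for u in real:
        cl = per_unit[u].closures
        gaps.extend(cl[i + 1][0] - cl[i][1] for i in range(len(cl) - 1))
    mean_inter = sum(gaps) / len(gaps) if gaps else None
    utils = [per_unit[u].mean_utilized_capacity for u in real if per_unit[u].mean_utilized_capacity is not None]
    return RunMetrics(
        horizon=horizon,
        per_unit=per_unit,
        treated=treated,
        diverted_alternative=div_alt,
        diverted_overflow=div_ovf,
        virtual_assigned=virt_assigned,
        closure_total=closure_total,
        closure_count=closure_count,
        mean_closure=mean_closure,
        mean_interclosure=mean_inter,
        closure_fraction=100.0 * closure_total / (horizon * len(real)) if real else 0.0,
        mean_utilized_capacity=float(np.mean(utils)) if utils else None,
    )


def summarize(log: "EventLog", network: Network, horizon: float | None = None) -> RunMetrics:
    """Recompute all run metrics from the event log alone.

    Replays the log record by record — census by cumulative admits and
    departures, closures from close/reopen pairs (an unmatched close is
    truncated at the horizon), occupancy integrals between census
    changes — and must equal the engine's online collectors exactly.
    Raises ``ValueError`` if the replayed census ever goes negative
    (a corrupted log).
    """
    if horizon is None:
        horizon = log.horizon
    census: dict[str, int] = {uid: 0 for uid in network.units}
    last: dict[str, float] = {uid: 0.0 for uid in network.units}
    occ: dict[str, float] = {uid: 0.0 for uid in network.units}
    open_close: dict[str, float] = {}
    closures: dict[str, list[tuple[float, float]]] = {uid: [] for uid in network.units}
    intended: dict[int, str] = {}
    treating: dict[int, str] = {}

    for rec in log.records:
        uid = rec.unit_id
        if rec.event == "arrival":
            intended[rec.patient_id] = uid
        elif rec.event == "admit":
            occ[uid] += census[uid] * (rec.time - last[uid])
            last[uid] = rec.time
            census[uid] += 1
            treating[rec.patient_id] = uid
        elif rec.event == "depart":
            occ[uid] += census[uid] * (rec.time - last[uid])
            last[uid] = rec.time
            census[uid] -= 1
            if census[uid] < 0:
                raise ValueError(f"corrupted log: negative census on {uid} at t={rec.time}")
        elif rec.event == "close":
            open_close[uid] = rec.time
        elif rec.event == "reopen":
            closures[uid].append((open_close.pop(uid), rec.time))
        # "divert" records carry no state change for the intended unit

    for uid, start in open_close.items():
        if horizon > start:
            closures[uid].append((start, horizon))
    for uid in network.units:
        occ[uid] += census[uid] * (horizon - last[uid])

    counts_acc = {
        uid: {"treated_primary": 0, "diverted_out_alternative": 0, "diverted_out_overflow": 0, "diverted_in": 0}
        for uid in network.units
    }
    for pid, tuid in treating.items():
        iuid = intended[pid]
        if tuid == iuid:
            counts_acc[iuid]["treated_primary"] += 1
        else:
            if network.unit(tuid).is_virtual:
                counts_acc[iuid]["diverted_out_overflow"] += 1
            else:
                counts_acc[iuid]["diverted_out_alternative"] += 1
            counts_acc[tuid]["diverted_in"] += 1

    raw = RawCollectors(
        counts={uid: UnitCounts(**v) for uid, v in counts_acc.items()},
        closures={uid: tuple(ivs) for uid, ivs in closures.items() if not network.unit(uid).is_virtual},
        occ_integral=occ,
    )
    return build_metrics(raw, network, horizon)


# -- table arithmetic ------------------------------------------------------


def divert_treat_ratio(mean_diverted: float, mean_treated: float) -> float | None:
    """Diverted-to-treated ratio; ``None`` (undefined) when nothing was treated
    but patients were diverted."""
    if mean_treated > 0:
        return mean_diverted / mean_treated
    return None if mean_diverted > 0 else 0.0


def relative_frequencies(absolute: Sequence[float]) -> list[float]:
    """Normalize a column of absolute percentages to relative percentages."""
    if any(a < 0 for a in absolute):
        raise ValueError("absolute frequencies must be non-negative")
    total = sum(absolute)
    if total <= 0:
        raise ValueError("absolute frequencies sum to zero")
    return [100.0 * a / total for a in absolute]


def coverage_product(absolute: Sequence[float], covered: Sequence[float]) -> float:
    """Overall coverage: sum of absolute-frequency × covered-fraction products.

    Both arguments are percentage columns; the result is the percentage
    of all patients represented by the modelled units.
    """
    if len(absolute) != len(covered):
        raise ValueError("columns must have equal length")
    if any(not 0 <= c <= 100 for c in covered):
        raise ValueError("covered percentages must be in [0, 100]")
    return sum(a * c / 100.0 for a, c in zip(absolute, covered))


# -- policy-arm aggregation ------------------------------------------------


@dataclass(frozen=True)
class PolicySummary:
    """Per-arm aggregation across replications."""

    label: str
    n_reps: int
    treated: tuple[float, ...]
    diverted: tuple[float, ...]
    closure_total: tuple[float, ...]
    closure_fraction: tuple[float, ...]
    closure_count: tuple[float, ...]
    mean_closure_per_rep: tuple[float | None, ...]
    mean_interclosure_per_rep: tuple[float | None, ...]

    @classmethod
    def from_runs(cls, label: str, runs: Sequence[RunMetrics]) -> "PolicySummary":
        return cls(
            label=label,
            n_reps=len(runs),
            treated=tuple(float(m.treated) for m in runs),
            diverted=tuple(float(m.diverted) for m in runs),
            closure_total=tuple(m.closure_total for m in runs),
            closure_fraction=tuple(m.closure_fraction for m in runs),
            closure_count=tuple(float(m.closure_count) for m in runs),
            mean_closure_per_rep=tuple(m.mean_closure for m in runs),
            mean_interclosure_per_rep=tuple(m.mean_interclosure for m in runs),
        )

    @property
    def mean_treated(self) -> float:
        return float(np.mean(self.treated))

    @property
    def mean_diverted(self) -> float:
        return float(np.mean(self.diverted))

    @property
    def sd_treated(self) -> float:
        return float(np.std(self.treated, ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def sd_diverted(self) -> float:
        return float(np.std(self.diverted, ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def ratio_diverted_treated(self) -> float | None:
        return divert_treat_ratio(self.mean_diverted, self.mean_treated)

    @property
    def ratios_per_rep(self) -> tuple[float | None, ...]:
        return tuple(divert_treat_ratio(d, t) for d, t in zip(self.diverted, self.treated))

    @property
    def mean_closure_total(self) -> float:
        return float(np.mean(self.closure_total))

    @property
    def mean_closure_fraction(self) -> float:
        return float(np.mean(self.closure_fraction))

    @property
    def mean_closure(self) -> float | None:
        vals = [v for v in self.mean_closure_per_rep if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_interclosure(self) -> float | None:
        vals = [v for v in self.mean_interclosure_per_rep if v is not None]
        return float(np.mean(vals)) if vals else None


_SUMMARY_COLUMNS = [
    "policy",
    "mean_treated",
    "mean_diverted",
    "ratio",
    "closure_total_min",
    "closure_fraction_pct",
    "mean_closure_min",
    "mean_interclosure_min",
]


def _summary_row(s: PolicySummary) -> dict:
    return {
        "policy": s.label,
        "mean_treated": s.mean_treated,
        "mean_diverted": s.mean_diverted,
        "ratio": s.ratio_diverted_treated,
        "closure_total_min": s.mean_closure_total,
        "closure_fraction_pct": s.mean_closure_fraction,
        "mean_closure_min": s.mean_closure,
        "mean_interclosure_min": s.mean_interclosure,
    }


def write_summary(summaries: Mapping[str, PolicySummary] | Sequence[PolicySummary], csv_path, json_path=None) -> None:
    """Write the per-arm comparison as CSV (and optionally a JSON mirror).

    Undefined quantities (ratio with zero treated, inter-closure time
    with fewer than two closures) become empty CSV cells and JSON null.
    """
    if isinstance(summaries, Mapping):
        rows = [_summary_row(s) for s in summaries.values()]
    else:
        rows = [_summary_row(s) for s in summaries]
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SUMMARY_COLUMNS)
        for row in rows:
            w.writerow(["" if row[c] is None else (row[c] if c == "policy" else repr(float(row[c]))) for c in _SUMMARY_COLUMNS])
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")


def write_metrics(metrics: RunMetrics, path) -> None:
    """Write one run's metrics as JSON (totals plus per-unit detail)."""
    payload = {
        "horizon_min": metrics.horizon,
        "treated": metrics.treated,
        "diverted_alternative": metrics.diverted_alternative,
        "diverted_overflow": metrics.diverted_overflow,
        "virtual_assigned": metrics.virtual_assigned,
        "forced_assignments": metrics.forced_assignments,
        "closure_total_min": metrics.closure_total,
        "closure_count": metrics.closure_count,
        "mean_closure_min": metrics.mean_closure,
        "mean_interclosure_min": metrics.mean_interclosure,
        "closure_fraction_pct": metrics.closure_fraction,
        "mean_utilized_capacity": metrics.mean_utilized_capacity,
        "per_unit": {
            uid: {
                "treated_primary": um.counts.treated_primary,
                "diverted_out_alternative": um.counts.diverted_out_alternative,
                "diverted_out_overflow": um.counts.diverted_out_overflow,
                "diverted_in": um.counts.diverted_in,
                "closure_total_min": um.closure_total,
                "closure_count": um.closure_count,
                "mean_closure_min": um.mean_closure,
                "mean_interclosure_min": um.mean_interclosure,
                "closure_fraction_pct": um.closure_fraction,
                "time_avg_census": um.time_avg_census,
                "mean_utilized_capacity": um.mean_utilized_capacity,
            }
            for uid, um in metrics.per_unit.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
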