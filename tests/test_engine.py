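import math

import numpy as np
import pytest

from divertsim.arrivals import ClosureSchedule, GeneratorConfig, generate_arrivals
from divertsim.engine import LogRecord, Outcome, run_replications, run_simulation, _derive_seed
from divertsim.los import LosModel
from divertsim.metrics import summarize
from divertsim.network import Subspecialty, build_network
from divertsim.policies import POLICY_LABELS, PolicySpec

from conftest import make_stream, poisson_stream, trauma_pair_config

TRAUMA = Subspecialty.TRAUMA_SURGERY
A, B = "A:trauma_surgery", "B:trauma_surgery"


def test_empty_stream_gives_empty_log_and_zero_metrics(trauma_pair):
    log, m = run_simulation(
        trauma_pair, make_stream([]), LosModel.point_mass(60.0), POLICY_LABELS["P1_100"], seed=0
    )
    assert log.records == ()
    assert (m.treated, m.diverted, m.closure_count, m.closure_total) == (0, 0, 0, 0.0)


def hand_trace_run(trauma_pair):
    # One unit of capacity 2 under P1_100; arrivals at t = 0, 10, 20 with
    # fixed LOS 100: the unit closes at the second admission, the third
    # patient is diverted to the peer, and the first departure reopens it.
    stream = make_stream([0.0, 10.0, 20.0], unit=A, horizon=200.0)
    return run_simulation(
        trauma_pair, stream, LosModel.point_mass(100.0), POLICY_LABELS["P1_100"],
        seed=0, return_outcomes=True,
    )


def test_hand_traced_event_log(trauma_pair):
    log, m, outcomes = hand_trace_run(trauma_pair)
    expected = (
        LogRecord(0.0, "arrival", A, 1, 0, 0.0),
        LogRecord(0.0, "admit", A, 1, 1, 0.5),
        LogRecord(10.0, "arrival", A, 2, 1, 0.5),
        LogRecord(10.0, "admit", A, 2, 2, 1.0),
        LogRecord(10.0, "close", A, None, 2, 1.0),
        LogRecord(20.0, "arrival", A, 3, 2, 1.0),
        LogRecord(20.0, "divert", A, 3, 2, 1.0),
        LogRecord(20.0, "admit", B, 3, 1, 0.2),
        LogRecord(100.0, "depart", A, 1, 1, 0.5),
        LogRecord(100.0, "reopen", A, None, 1, 0.5),
        LogRecord(110.0, "depart", A, 2, 0, 0.0),
        LogRecord(120.0, "depart", B, 3, 0, 0.0),
    )
    assert log.records == expected
    assert m.treated == 2
    assert m.diverted_alternative == 1 and m.diverted_overflow == 0
    assert m.closure_count == 1
    assert m.closure_total == 90.0
    assert m.per_unit[A].closures == ((10.0, 100.0),)
    assert outcomes[3].outcome is Outcome.DIVERTED_ALTERNATIVE
    assert outcomes[3].intended_unit == A and outcomes[3].treating_unit == B


def test_littles_law_never_close(trauma_pair):
    # M/D/inf sanity check: time-average census = rate x mean LOS.
    rate, los, horizon = 0.2, 50.0, 100_000.0
    stream = poisson_stream(rate, horizon, unit=A, rng=np.random.default_rng(4))
    _, m = run_simulation(
        trauma_pair.unbounded(), stream, LosModel.point_mass(los),
        PolicySpec.never_close(), seed=0,
    )
    target = rate * los
    se = math.sqrt(rate * los**2 / horizon)  # var of the time average, M/G/inf
    assert abs(m.per_unit[A].time_avg_census - target) < 3 * se


def test_double_diversion_goes_to_virtual():
    net = build_network(trauma_pair_config(cap_a=1, cap_b=1))
    stream = make_stream([0.0, 1.0, 2.0], unit=A, horizon=50.0)
    _, m, outcomes = run_simulation(
        net, stream, LosModel.point_mass(10.0), POLICY_LABELS["P1_100"],
        seed=0, return_outcomes=True,
    )
    assert outcomes[1].outcome is Outcome.TREATED_PRIMARY
    assert outcomes[2].outcome is Outcome.DIVERTED_ALTERNATIVE
    assert outcomes[3].outcome is Outcome.DIVERTED_OVERFLOW
    assert net.unit(outcomes[3].treating_unit).is_virtual
    assert m.diverted_overflow == 1


def test_departure_processed_before_simultaneous_arrival(trauma_pair):
    # The departing patient frees capacity: the arrival at t = 100 is
    # admitted rather than diverted.
    net = build_network(trauma_pair_config(cap_a=1, cap_b=1))
    stream = make_stream([0.0, 100.0], unit=A, horizon=400.0)
    _, m = run_simulation(
        net, stream, LosModel.point_mass(100.0), POLICY_LABELS["P1_100"], seed=0
    )
    assert m.treated == 2 and m.diverted == 0


def test_virtual_assigned_admitted_unconditionally(trauma_pair):
    vid = trauma_pair.virtual_unit[TRAUMA]
    stream = make_stream([1.0, 1.0 + 1e-9, 2.0], unit=vid, horizon=50.0)
    _, m, outcomes = run_simulation(
        trauma_pair, stream, LosModel.point_mass(500.0), POLICY_LABELS["P1_100"],
        seed=0, return_outcomes=True,
    )
    assert all(o.outcome is Outcome.TREATED_PRIMARY for o in outcomes.values())
    assert m.virtual_assigned == 3 and m.treated == 0


def test_timed_closures_have_exact_duration():
    net = build_network(trauma_pair_config(cap_a=2, cap_b=2))
    rng = np.random.default_rng(11)
    stream = poisson_stream(0.05, 20_000.0, unit=A, rng=rng)
    for label in ("P2_6", "P2_12", "P2_24", "P3_80_6", "P3_80_12", "P3_80_24"):
        policy = POLICY_LABELS[label]
        _, m = run_simulation(net, stream, LosModel.exponential(200.0), policy, seed=3)
        for uid in (A, B):
            closures = m.per_unit[uid].closures
            assert len(closures) > 0 if uid == A else True
            for i, (s, e) in enumerate(closures):
                if i < len(closures) - 1:
                    assert e - s == pytest.approx(policy.duration)
                else:
                    assert (e - s == pytest.approx(policy.duration)) or e == 20_000.0


def test_threshold_census_never_exceeds_capacity():
    net = build_network(trauma_pair_config(cap_a=2, cap_b=3))
    stream = poisson_stream(0.1, 10_000.0, unit=A, rng=np.random.default_rng(12))
    for label in ("P1_100", "P1_80", "P1_60", "P2_6", "P3_80_6"):
        log, _ = run_simulation(net, stream, LosModel.exponential(150.0), POLICY_LABELS[label], seed=5)
        for rec in log.records:
            cap = net.unit(rec.unit_id).capacity
            if not math.isinf(cap):
                assert rec.census_after <= cap


def test_schedule_replay_empty_equals_never_close(trauma_pair):
    stream = poisson_stream(0.05, 5_000.0, unit=A, rng=np.random.default_rng(13))
    empty = ClosureSchedule(intervals={A: (), B: ()}, horizon=5_000.0)
    los = LosModel.exponential(120.0)
    log_sq, m_sq = run_simulation(
        trauma_pair, stream, los, PolicySpec.schedule_replay(), schedule=empty, seed=9
    )
    log_open, m_open = run_simulation(trauma_pair, stream, los, PolicySpec.never_close(), seed=9)
    assert log_sq.records == log_open.records
    assert m_sq == m_open


def test_schedule_replay_closure_fraction_matches_schedule(trauma_pair):
    sched = ClosureSchedule(
        intervals={A: ((100.0, 400.0), (900.0, 1000.0)), B: ((0.0, 50.0),)},
        horizon=1000.0,
    )
    stream = make_stream([500.0], unit=A, horizon=1000.0)
    _, m = run_simulation(
        trauma_pair, stream, LosModel.point_mass(10.0), PolicySpec.schedule_replay(),
        schedule=sched, seed=0,
    )
    assert m.per_unit[A].closures == ((100.0, 400.0), (900.0, 1000.0))
    assert m.per_unit[B].closures == ((0.0, 50.0),)
    assert m.closure_fraction == pytest.approx(100.0 * sched.closed_fraction())


def test_schedule_policy_mismatch_rejected(trauma_pair):
    stream = make_stream([1.0])
    sched = ClosureSchedule(intervals={A: ()}, horizon=stream.horizon)
    with pytest.raises(ValueError):
        run_simulation(trauma_pair, stream, LosModel.point_mass(1.0),
                       PolicySpec.schedule_replay(), schedule=None, seed=0)
    with pytest.raises(ValueError):
        run_simulation(trauma_pair, stream, LosModel.point_mass(1.0),
                       POLICY_LABELS["P1_100"], schedule=sched, seed=0)


def test_unknown_assigned_unit_rejected(trauma_pair):
    stream = make_stream([1.0], unit="Z:trauma_surgery")
    with pytest.raises(KeyError):
        run_simulation(trauma_pair, stream, LosModel.point_mass(1.0),
                       POLICY_LABELS["P1_100"], seed=0)


def test_same_seed_identical_log(trauma_pair):
    stream = poisson_stream(0.08, 3_000.0, unit=A, rng=np.random.default_rng(14))
    los = LosModel.exponential(100.0)
    runs = [run_simulation(trauma_pair, stream, los, POLICY_LABELS["P2_6"], seed=21)
            for _ in range(2)]
    assert runs[0][0] == runs[1][0]
    assert runs[0][1] == runs[1][1]
    log_other, _ = run_simulation(trauma_pair, stream, los, POLICY_LABELS["P2_6"], seed=22)
    assert log_other.records != runs[0][0].records


def test_conservation_and_replay_equivalence_randomized(resolved_default):
    # Every arrival maps to exactly one outcome, and recomputing the
    # metrics from the log reproduces the online collectors exactly.
    exp, net = resolved_default
    cfg = GeneratorConfig(horizon=1440.0, expected_total=300.0)
    labels = ["P1_100", "P1_80", "P2_6", "P3_80_12"]
    for i in range(20):
        stream = generate_arrivals(cfg, net, seed=300 + i)
        policy = POLICY_LABELS[labels[i % len(labels)]]
        log, m, outcomes = run_simulation(
            net, stream, exp.los, policy, seed=600 + i, return_outcomes=True
        )
        assert len(outcomes) == len(stream)
        by_kind = {k: sum(1 for o in outcomes.values() if o.outcome is k) for k in Outcome}
        assert sum(by_kind.values()) == len(stream)
        assert m.treated + m.virtual_assigned == by_kind[Outcome.TREATED_PRIMARY]
        assert m.diverted_alternative == by_kind[Outcome.DIVERTED_ALTERNATIVE]
        assert m.diverted_overflow == by_kind[Outcome.DIVERTED_OVERFLOW]
        assert summarize(log, net) == m


class TestRunReplications:
    def test_single_rep_equals_single_run(self, resolved_default):
        exp, net = resolved_default
        cfg = GeneratorConfig(horizon=1440.0, expected_total=200.0)
        summ = run_replications(net, cfg, exp.los, [POLICY_LABELS["P1_100"]],
                                n_reps=1, base_seed=5)
        s = summ["P1_100"]
        stream = generate_arrivals(cfg, net, seed=_derive_seed(5, 0, 0))
        _, m = run_simulation(net, stream, exp.los, POLICY_LABELS["P1_100"],
                              seed=_derive_seed(5, 0, 2))
        assert s.n_reps == 1
        assert s.treated == (float(m.treated),)
        assert s.diverted == (float(m.diverted),)
        assert s.mean_closure_total == m.closure_total

    def test_identical_policy_and_seed_identical_summary(self, resolved_default):
        exp, net = resolved_default
        cfg = GeneratorConfig(horizon=1440.0, expected_total=200.0)
        a = run_replications(net, cfg, exp.los, [POLICY_LABELS["P2_12"]], n_reps=3, base_seed=8)
        b = run_replications(net, cfg, exp.los, [POLICY_LABELS["P2_12"]], n_reps=3, base_seed=8)
        assert a == b

    def test_invalid_rep_count_rejected(self, resolved_default):
        exp, net = resolved_default
        with pytest.raises(ValueError):
            run_replications(net, exp.generator, exp.los, [POLICY_LABELS["P1_100"]],
                             n_reps=0, base_seed=1)

    def test_mean_treated_matches_exhaustive_enumeration(self):
        # Two capacity-1 units, arrivals at t = 0, 100, 200 all assigned
        # to A, exponential LOS with mean 150, policy P1_100.  Exhaustive
        # enumeration of the outcome tree gives
        # E[treated at A] = 1 + 2p with p = P(LOS <= 100).
        net = build_network(trauma_pair_config(cap_a=1, cap_b=1))
        stream = make_stream([0.0, 100.0, 200.0], unit=A, horizon=2_000.0)
        los = LosModel.exponential(150.0)
        n = 400
        treated = np.array([
            run_simulation(net, stream, los, POLICY_LABELS["P1_100"], seed=i)[1].treated
            for i in range(n)
        ])
        p = 1.0 - math.exp(-100.0 / 150.0)
        expected = 1.0 + 2.0 * p
        se = treated.std(ddof=1) / math.sqrt(n)
        assert abs(treated.mean() - expected) < 3 * se
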