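# Methods

## The system being modelled

`divertsim` simulates ambulance patient flow through the emergency
subspecialty units of a city hospital network. Each unit is a capacity-
bounded service station: an admitted patient occupies one slot for a
random length of stay (LOS) and then departs. A unit may *close* —
declare itself unavailable to new ambulances — either because a policy
rule fires or because a replayed schedule says so. A patient arriving at
a closed or full unit is diverted **once**: to the geographically closest
peer unit of the same subspecialty if that peer can admit, otherwise to a
virtual overflow facility that is always open and unbounded. The
single-iteration rule reflects the operational reality that a second
diversion would in practice reach one of the many smaller hospitals
outside the model, which is exactly what the virtual facility represents.
The closest peer is precomputed from Euclidean distances on configured
planar coordinates (ties broken by lexicographically smallest unit id);
road distances and travel times are out of scope, and the shipped
coordinates are synthetic.

Walk-in patients are not modelled: the arrival stream represents
ambulance assignments only.

## Event mechanics

The kernel is a classic event-list simulation on a binary heap. At equal
times, departures are processed before reopen timers, then schedule
transitions, then arrivals — so a departing patient frees capacity for a
simultaneous arrival, and a schedule boundary takes effect before the
arrival that coincides with it. Remaining ties fall back to insertion
order. Policy rules are evaluated only at events (each admission, each
departure, and timer expiries), not continuously; since census changes
only at events, nothing is missed.

Patients admitted via diversion occupy capacity at the receiving unit and
can trigger its closure; their LOS is drawn at the receiving unit (it is
the same subspecialty, so the distribution is unchanged). Patients still
in service at the end of the horizon keep their outcome and are flagged
`in_system_at_end`; closures still open are truncated at the horizon.

Every state transition (arrival, admit, divert, depart, close, reopen) is
logged with the census and crowding index after it. `summarize()` rebuilds
all metrics from the log alone and is required — and tested — to equal the
online collectors exactly, which makes the log a sufficient audit trail.

## Crowding index and closure rules

CI = census / capacity. Fractional thresholds meet integer censuses
conservatively: a unit closes when census reaches
`ceil(trigger_ci * capacity)` and (threshold policies) reopens when census
is at or below `floor(reopen_ci * capacity)`; when the trigger and reopen
indices coincide (close at CI = 1, reopen when CI < 1) the reopen bound is
lowered by one so the two conditions are mutually exclusive. Whether the
original rules were strict or non-strict at the boundary is not
documented anywhere; this convention closes no later and reopens no
earlier than the real-valued rule and is fixed here.

Timed policies (fixed 6/12/24-h closures, triggered at CI = 1 or CI = 0.8)
reopen exactly `duration` minutes after closing; if the census still meets
the trigger at that instant the unit re-closes immediately, so every
completed closure has exactly the configured length except at most a final
horizon-truncated one. Schedule replay imposes closures verbatim with no
additional cap; capacity bounds still apply to admissions. The never-close
pseudo-policy exists for pretest (capacity-sizing) runs.

## Capacity estimation

Capacities marked `auto` are resolved by one never-close, unbounded
pretest replication with a dedicated, logged seed: each unit's capacity is
the maximum simultaneous census it saw, floored at 1 so the crowding index
is always defined. A single replication is used deliberately — the
pretest defines the capacity standard, it does not estimate a
population parameter — and the seed is part of the experiment
configuration (`capacity_seed`).

## Synthetic arrival generator

Arrival times follow a non-homogeneous Poisson process simulated by
thinning a homogeneous process at the peak rate. The base rate is
`expected_total / horizon`; defaults are 2476 expected arrivals over a
10,080-minute (7-day) week, ≈ 14/h. The intensity is modulated by a 24-bin
piecewise-constant diurnal profile normalized to mean 1; the default bins
encode the qualitative shape of observed assignment curves — trough at
02:00–06:00, steep rise at 07:00–08:00, plateau 10:00–18:00, evening
decline — the exact bin values being configuration, not measured data.
Weekday and seasonal effects are not modelled.

Each arrival is triaged a subspecialty from the relative case-mix
(defaults 0.4838 / 0.3712 / 0.0543 / 0.0469 / 0.0437 for internal
medicine, trauma, neurology, pediatrics, chest pain, renormalized), then
routed to a modelled unit with the subspecialty's coverage probability
(0.504 / 0.4995 / 0.9691 / 1.0 / 0.5394) or directly to the virtual
facility otherwise. Assignment among a subspecialty's real units is
uniform by default because per-hospital shares are not published;
`hospital_weights` overrides it.

Status-quo closure schedules are an alternating renewal process per unit:
open gaps and closed durations drawn independently from exponential
distributions with means 1101 min and 308 min. Only the means of the
observed processes are available; exponential is the maximum-entropy
family consistent with a mean and is isolated behind
`generate_status_quo_schedule` so another family can be substituted. The
means are applied per unit (the pooled-versus-per-unit attribution of the
observed statistics is not documented); the long-run closed fraction is
308/(308+1101) ≈ 21.9 % either way.

What the generator does **not** emulate: autocorrelation between
consecutive days, weekday structure, dependence between arrival bursts and
closures (in the real system closures follow arrival surges with a lag),
and per-hospital heterogeneity in demand. Tests passing on this generator
therefore validate the mechanics and internal consistency of the
simulator, not forecasts for any real network.

## Length of stay

Per-subspecialty distributions: lognormal, exponential, or point mass,
parameters in minutes. The study that the LOS structure follows
distinguishes emergency from non-emergency patients, but its parameters
for this setting are not recoverable; the shipped defaults (lognormal,
means 150–300 min, σ = 0.6) are clearly labelled placeholders, and every
test that depends on LOS states its parameters explicitly.

## Metrics conventions

Per run: `treated` counts patients admitted to their originally assigned
real unit; `diverted_alternative` / `diverted_overflow` count patients
refused by it; `virtual_assigned` counts patients triaged directly to the
overflow facility (they are "treated" there in conservation terms but not
mixed into the policy comparison, which concerns the modelled units).
`closure_fraction` is the mean per-unit percentage of the horizon spent
closed; `mean_interclosure` is the mean gap between the end of one closure
and the start of the next within a unit, pooled across units, and is
undefined (null in reports) with fewer than two closures. Utilized
capacity is the time-average census divided by capacity. *Forced
assignments* is named among the study's outcome variables but never
defined; it is reported as a fixed zero with the field reserved.
Replication summaries report the ratio of mean diverted to mean treated
per arm; internal computation is full precision, tables round to two
decimals.

## Replication and seeding

`run_replications` pairs arms: within a replication every policy sees the
same arrival stream, so arm contrasts are paired comparisons.
Per-replication and per-arm seeds are derived from the base seed via
`numpy` seed sequences; identical calls are bit-identical, and a single
replication equals the corresponding single `run_simulation` call.

## Problem sizes in the shipped tests

The default study conditions (2476 arrivals/week, 24 real units) are used
wherever the property under test concerns the full system: the policy-
ordering check runs 50 paired replications of the six timed arms, and the
conservation/replay check runs 100 randomized one-day scenarios across all
policy kinds. Closed-form checks use dedicated small systems: Little's law
on a single unbounded unit over 10⁵ minutes; an exhaustively enumerable
three-patient, two-unit, capacity-one scenario whose expected treated
count is 1 + 2·P(LOS ≤ 100) in closed form; renewal statistics of the
schedule generator over 10⁶–2·10⁶ minutes. Stochastic assertions use
3-standard-error tolerances derived from the corresponding closed forms,
never tuned constants.

## Known limitations

- Absolute treated/diverted counts are not comparable to any real
  network's: they depend on the synthetic arrival stream, placeholder LOS
  parameters, and pretest capacities. Only orderings and internal
  arithmetic are meaningful.
- One policy applies network-wide per run; per-hospital heterogeneous
  policies and partial (sub-unit) closures are not supported.
- The diversion rule never re-ranks peers when the closest one is closed;
  that is a modelling commitment (see above), not an optimization target.
- No mortality, staffing, or intra-hospital transfer modelling.
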