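# Methods

## Overview

`ballastnet` models ship-borne aquatic invasions as a three-stage chain:
a species must be **alien** to the receiving port, it must be
**introduced** there alive via ballast discharge, and it must
**establish** in the local environment. Route risks are combined into a
weighted directed network, the network is decomposed into s-shells to
measure each port's capacity to relay invasions onward, and the two
views — exposure and spreading power — are merged into one triggering
score.

## Risk kernels

The three per-arrival probabilities are independent and multiply. Their
published calibrations are species- and dataset-specific, so the package
treats them as parametric strategy kernels constrained only by the
qualitative behaviour the theory demands (monotonicity, probability
range):

| parameter | meaning | unit | default |
|---|---|---|---|
| `lambda_d` | characteristic distance of `P(Alien)` | km | 5000 |
| `mu` | per-volume introduction rate in `P(Intro) = 1 − e^{−μV}` | 1/m³ | 0.001 |
| `p_max` | establishment probability at a perfect environmental match | – | 0.1 |
| `sigma_T` | temperature niche width | °C | 3 |
| `sigma_S` | salinity niche width | PSU | 5 |
| `alien_direction` | whether alienness grows or shrinks with distance | – | increasing |
| `survival_decay_per_hour` | optional in-transit mortality on `P(Intro)` | 1/h | 0 (off) |

Two readings of the distance kernel circulate in the literature: that
biogeographic separation makes a species more likely to be alien
(`P(Alien) = 1 − e^{−d/λ}`, the default), and that invasion pressure is
inversely proportional to route distance (`λ/(λ+d)`, available as
`alien_direction="decreasing"`). Both are shipped; neither is endorsed.
The in-transit survival decay is provided but off by default, since
voyage duration is observable in AIS data but not part of the core
aggregation model.

Defaults were chosen once for plausibility at global scale — e.g.
`μ = 0.001`/m³ puts the introduction probability of a typical 1000 m³
discharge at `1 − 1/e ≈ 0.63`, and `σ_T = 3 °C` makes establishment
negligible across more than ~10 °C of temperature mismatch — and are
overridable everywhere (API, YAML config, CLI).

Numerics: survival products run in log space (`log1p`) once a route has
more than 50 arrivals, and the port-level aggregation always does, so
`log(1 − P_j) = Σ log(1 − P_ij)` holds to round-off. A single incoming
route returns its weight bit-exactly.

## Ingest

A **port call** is a maximal run of consecutive same-ship pings whose
navigational status is in the in-port set (default {1 anchored, 2 not
in operation}; statuses 7 fishing and 8 under way, and all other codes,
count as at sea) and whose position lies within `radius_km` (default
10 km) of the same nearest port, lasting at least `min_dwell_hours`
(default 2 h). Neither radius nor dwell has a canonical value in the
literature; both are configurable. An in-port-status ping that is
within radius of no port breaks any open run rather than being skipped:
a ship anchored mid-ocean is not in port. Nearest-port resolution uses
a KD-tree on unit-sphere coordinates (chord length is monotone in
great-circle distance, so Euclidean nearest is also spherical nearest).

Consecutive calls at distinct ports become a voyage; same-port call
pairs are dropped (the invasion network has no self-loops). Ballast
volume joins from the discharge log on (ship, destination port,
discharge date within the call's arrival–departure date window, UTC);
each log entry is consumed by at most one call, earliest first, so
adjacent visits cannot double-count a discharge. Voyages with no log
coverage fall back to `default_volume_m3` (1000 m³) — real discharge
registries (e.g. the US NBIC) cover only a fraction of world ports.

Distances are haversine on a 6371 km sphere. Sea-route distances are
systematically longer; `RouteAggregate.distance_km` can be overridden
with routed values where available.

## s-core decomposition

With out-degree `d` and outgoing weight sum `Σw`, the combined degree is
`d' = [d^α (Σw)^β]^{1/(α+β)}`; α = β = 1 by default (then
`d' = √(d·Σw)`), and β = 0 recovers the classic out-degree k-core.
Degree and weight sum use **outgoing** edges only: the quantity measures
spreading capability, not exposure.

Peeling: the first threshold `s_0` is the global minimum `d'`; every
node with `d' ≤ s_k` (absolute tolerance 1e−12) is removed in sweeps,
recomputing `d'` on the induced subgraph after each sweep until the
stage stabilises; the removed set is shell `k` and the survivors'
minimum `d'` is `s_{k+1} > s_k`. Sweep removal is equivalent to
removing one minimum node at a time; the package carries a deliberately
naive one-at-a-time oracle (`s_core_decompose_oracle`, ties broken by
node id) and the equivalence is asserted over hundreds of random graphs
in the test suite. Nodes without out-edges form shell 0 at `s_0 = 0`.
Downstream consumers use the ordinal shell index `k`; the real-valued
thresholds are retained alongside.

One subtlety found while validating: a node's *ordinal* shell index is
not monotone under edge deletion (removing an edge elsewhere can split
a lower shell in two, shifting the ordinals above it), while the
peeling *threshold* of a node's shell is. The monotonicity property is
therefore stated and tested on thresholds.

## Trigger

`R(j) = θ·P̃_j(Inv) + (1−θ)·s̃(j)`, θ = 0.5 by default. Normalisation is
min-max over the current port set (order-preserving and simple); an
average-rank alternative is available behind `normalization="rank"`. A
constant component normalises to all zeros, making it inert without
disturbing the ranking. Ranking ties break by normalized invaded risk,
then port id, so output is total-ordered and deterministic. No
canonical trigger threshold exists; reports always contain the full
ranking along with the `R ≥ T` flag (T defaults to 0.5).

## Synthetic world

The generator emulates the pipeline's three data sources:

- **Ports**: uniform over lon ∈ [−180°, 180°], lat ∈ [−60°, 60°] (the
  band avoids polar degeneracies); water temperature
  `28·cos(lat) + N(0, 1.5)` °C clipped to [−2, 32]; salinity
  `35 + N(0, 2)` PSU clipped to [25, 40].
- **Traffic**: each ship random-walks over ports, choosing destinations
  with probability proportional to attractiveness — designated hub
  ports carry a `hub_boost` multiplier — at a fixed 30 km/h over
  great-circle tracks, with a 6 h dwell between voyages.
- **Ballast**: lognormal volumes (μ = 7, σ = 1; median ≈ 1100 m³),
  logged against ship, destination and arrival date.
- **AIS**: status-8 pings every 2 h along the great-circle track and
  status-1 pings at the port position during dwells, including pings
  exactly at arrival and departure instants; the stream is shuffled to
  exercise ingest sorting.

The reference scenario is 60 ports, 5 hubs at 8× attraction, 40 ships
and a 120-day window — small enough that the full pipeline runs in
under a second, dense enough that hub structure is recoverable. All
randomness flows from one integer seed through independent per-stage
substreams, so any stage can be regenerated alone and all output is
bit-reproducible.

What the generator does *not* emulate — shipping-lane geometry,
seasonality, AIS dropout and position noise, port capacity, fleet
heterogeneity — bounds what passing tests show: they validate the
machinery (exact voyage recovery, risk aggregation identities,
decomposition correctness, determinism), not the calibration of any
kernel against field data.

A consequence of the synthetic design worth knowing: hubs are placed
uniformly in latitude, so roughly one world in four plants a hub above
|lat| ≈ 50° whose ~13–17 °C water sits more than 8 °C from the warm
port majority. Under the default σ_T = 3 °C niche width such a hub is
*correctly* scored as a weak stepping stone — its incoming and outgoing
route risks are all near zero — and it will not reach the top of the
composite ranking however much traffic it attracts. Hub-recovery rates
on uniformly-placed hubs therefore plateau around 75–85%, a property of
the environmental kernel, not a retrieval failure.

## Problem sizes

Tests and the acceptance script use: 200 random digraphs of ≤ 12 nodes
for oracle equivalence, 100 graphs of 100 nodes for nestedness, 50 for
the k-core reduction, 20 seeded worlds each for AIS round-trip and
planted-hub recovery, and a 200-port world for the rank-correlation
check — sizes at which the naive oracle is still exact and the full
suite completes in well under a minute.

## Known limitations

- Great-circle distances understate true sea routes (Suez/Panama, land
  avoidance); injected routed distances are supported but not computed.
- The kernels are monotone parametric stand-ins; calibrating them to a
  species assemblage or discharge survival data is out of scope.
- Environments are annual means; no seasonality in establishment.
- Hull fouling, the second major invasion pathway, is not modelled.
- The trigger threshold T is a policy choice; the package reports the
  full ranking rather than recommending a value.
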