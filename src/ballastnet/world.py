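"""Seeded synthetic world: ports, traffic, ballast and AIS streams.

Emulates the three data sources the pipeline consumes — a port registry
with latitude-structured water temperature and salinity, gravity-style
ship traffic in which a few designated hub ports attract a multiple of
the ordinary traffic, lognormal ballast discharge volumes, and AIS ping
streams along great-circle tracks with anchored dwells in port.  Every
output is reproducible bit-for-bit from the world seed; independent
substreams per stage let each stage be regenerated on its own.

What it deliberately does not emulate: shipping-lane geometry (tracks
are great circles), seasonality, port capacity, AIS dropout or position
noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Mapping

import numpy as np

from .geo import great_circle_distance_km, interpolate_great_circle
from .ingest import AISRecord, BallastRecord, Port, Voyage

#: Fixed cruising speed used to time voyages, km/h.
SHIP_SPEED_KMH = 30.0
#: In-port dwell between voyages, hours (clears the 2 h ingest default).
DWELL_HOURS = 6.0
#: Start of the simulated calendar.
EPOCH = datetime(2014, 1, 1, tzinfo=timezone.utc)

_STAGE_PORTS, _STAGE_VOYAGES, _STAGE_SHUFFLE = 0, 1, 2

__all__ = [
    "WorldSpec", "generate_ports", "hub_port_ids", "generate_voyages",
    "generate_ais_stream", "SHIP_SPEED_KMH", "DWELL_HOURS", "EPOCH",
]


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic shipping world.

    Defaults describe the package's reference scenario: 60 ports of
    which 5 are hubs attracting 8x the ordinary traffic, 40 ships
    sailing for 120 days, pings every 2 h, and lognormal ballast
    discharges with median ``exp(ballast_mu)`` ~ 1100 m3 per call.
    """

    n_ports: int = 60
    n_ships: int = 40
    duration_days: int = 120
    hub_ports: int = 5
    hub_boost: float = 8.0
    ping_interval_hours: float = 2.0
    ballast_mu: float = 7.0
    ballast_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ports, self.n_ships, self.duration_days) <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.hub_ports <= self.n_ports):
            raise ValueError("hub_ports must be between 0 and n_ports")
        if self.hub_ports and self.hub_boost <= 1.0:
            raise ValueError("hub_boost must exceed 1")
        if self.ping_interval_hours <= 0:
            raise ValueError("ping_interval_hours must be positive")


def _rng(spec: WorldSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(spec.seed), stage)))


def generate_ports(spec: WorldSpec) -> dict[str, Port]:
    """Ports uniform over lon in [-180, 180], lat in [-60, 60].

    Mean water temperature follows ``28 cos(lat)`` degC with N(0, 1.5)
    noise clipped to [-2, 32]; salinity is 35 PSU with N(0, 2) noise
    clipped to [25, 40] — a crude but latitude-coherent ocean.
    """
    rng = _rng(spec, _STAGE_PORTS)
    n = spec.n_ports
    lon = rng.uniform(-180.0, 180.0, n)
    lat = rng.uniform(-60.0, 60.0, n)
    temp = np.clip(28.0 * np.cos(np.radians(lat)) + rng.normal(0.0, 1.5, n),
                   -2.0, 32.0)
    sal = np.clip(35.0 + rng.normal(0.0, 2.0, n), 25.0, 40.0)
    width = max(3, len(str(n - 1)))
    ports = {}
    for i in range(n):
        pid = f"P{i:0{width}d}"
        ports[pid] = Port(pid, f"Port {i:0{width}d}", float(lon[i]), float(lat[i]),
                          float(temp[i]), float(sal[i]))
    return ports


def hub_port_ids(ports: Mapping[str, Port], spec: WorldSpec) -> list[str]:
    """The designated hub ports: the first ``hub_ports`` ids in sorted order
    (port positions are i.i.d., so this is an unbiased designation)."""
    return sorted(ports)[: spec.hub_ports]


def generate_voyages(
    ports: Mapping[str, Port],
    spec: WorldSpec,
) -> tuple[list[Voyage], list[BallastRecord]]:
    """Seeded random-walk traffic with hub attraction.

    Each ship starts at an attraction-weighted random port at the epoch,
    dwells 6 h, then repeatedly sails to a destination drawn with
    probability proportional to attractiveness (hubs get ``hub_boost``,
    all other ports 1), never its current port.  Voyage time is the
    great-circle distance at 30 km/h, rounded to whole seconds; ships
    stop once the next arrival would pass the simulation horizon.  Every
    arrival discharges a lognormal ballast volume, logged against the
    ship, destination and arrival date.  Returns the ground-truth voyage
    list and the matching discharge log.
    """
    if len(ports) < 2:
        raise ValueError("need at least two ports")
    rng = _rng(spec, _STAGE_VOYAGES)
    pids = sorted(ports)
    hubs = set(hub_port_ids(ports, spec))
    attract = np.array([spec.hub_boost if p in hubs else 1.0 for p in pids])
    horizon = EPOCH + timedelta(days=spec.duration_days)
    dwell = timedelta(hours=DWELL_HOURS)
    idx = {p: i for i, p in enumerate(pids)}

    voyages: list[Voyage] = []
    log: list[BallastRecord] = []
    width = max(2, len(str(spec.n_ships - 1)))
    for s in range(spec.n_ships):
        ship = f"S{s:0{width}d}"
        current = pids[rng.choice(len(pids), p=attract / attract.sum())]
        clock = EPOCH + dwell  # initial dwell at the starting port
        while True:
            w = attract.copy()
            w[idx[current]] = 0.0
            dest = pids[rng.choice(len(pids), p=w / w.sum())]
            a, b = ports[current], ports[dest]
            dist = great_circle_distance_km(a.lon, a.lat, b.lon, b.lat)
            sail = timedelta(seconds=round(dist / SHIP_SPEED_KMH * 3600.0))
            arrive = clock + sail
            volume = float(rng.lognormal(spec.ballast_mu, spec.ballast_sigma))
            if arrive > horizon:
                break
            voyages.append(Voyage(ship, current, dest, clock, arrive, volume))
            log.append(BallastRecord(ship, dest, arrive.date(), volume))
            clock = arrive + dwell
            current = dest
    return voyages, log


def _dwell_pings(ship: str, port: Port, start: datetime, end: datetime,
                 interval: timedelta) -> list[AISRecord]:
    times = []
    t = start
    while t < end:
        times.append(t)
        t += interval
    times.append(end)
    return [AISRecord(ship, t, 1, port.lon, port.lat) for t in times]


def generate_ais_stream(
    voyages: Iterable[Voyage],
    ports: Mapping[str, Port],
    spec: WorldSpec,
) -> list[AISRecord]:
    """AIS pings realising a voyage list, shuffled by seed.

    Each voyage contributes status-8 (under way) pings every
    ``ping_interval_hours`` along the great-circle track, strictly
    between departure and arrival; each port stay — the initial dwell,
    the 6 h dwell between voyages and a final 6 h dwell after the last
    arrival — contributes status-1 (anchored) pings at the port position,
    including pings exactly at the arrival and departure instants, so a
    noise-free ingest recovers the planted voyages exactly.  The record
    order is shuffled to exercise the ingest's internal sorting.
    """
    interval = timedelta(hours=spec.ping_interval_hours)
    dwell = timedelta(hours=DWELL_HOURS)
    by_ship: dict[str, list[Voyage]] = {}
    for v in voyages:
        by_ship.setdefault(v.ship_id, []).append(v)

    records: list[AISRecord] = []
    for ship in sorted(by_ship):
        seq = sorted(by_ship[ship], key=lambda v: v.depart)
        # initial dwell at the first source port
        first = seq[0]
        records += _dwell_pings(ship, ports[first.source_port],
                                first.depart - dwell, first.depart, interval)
        for k, v in enumerate(seq):
            src, dst = ports[v.source_port], ports[v.dest_port]
            span = (v.arrive - v.depart).total_seconds()
            times = []
            t = v.depart + interval
            while t < v.arrive:
                times.append(t)
                t += interval
            if times:
                fracs = np.array([(t - v.depart).total_seconds() / span
                                  for t in times])
                lons, lats = interpolate_great_circle(src.lon, src.lat,
                                                      dst.lon, dst.lat, fracs)
                records += [AISRecord(ship, t, 8, float(lo), float(la))
                            for t, lo, la in zip(times, lons, lats)]
            stay_end = seq[k + 1].depart if k + 1 < len(seq) else v.arrive + dwell
            records += _dwell_pings(ship, dst, v.arrive, stay_end, interval)

    rng = _rng(spec, _STAGE_SHUFFLE)
    order = rng.permutation(len(records))
    return [records[i] for i in order]
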