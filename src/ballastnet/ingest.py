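"""Turn AIS-style position reports into port calls, voyages and routes.

The ingest chain is::

    AIS pings ──detect_port_calls──▶ port calls ──build_voyages──▶ voyages
                                                        │
                               ballast discharge log ───┘ (volume join)

    voyages ──aggregate_routes──▶ one aggregate per ordered (source, dest)

A *port call* is a maximal run of consecutive pings of one ship whose
navigational status marks it as in port (anchored / not in operation by
default) and whose position lies within a fixed radius of a single port,
lasting at least a minimum dwell time.  Consecutive calls of one ship at
two distinct ports define a voyage; the ballast volume discharged on
arrival is joined from a discharge log keyed by ship, destination port
and calendar date.
"""

from __future__ import annotations

import csv
import io
import logging
from collections import defaultdict
from dataclasses import dataclass
from datetime import date, datetime, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geo import EARTH_RADIUS_KM, great_circle_distance_km, _unit_vectors

logger = logging.getLogger(__name__)

#: Navigational statuses counted as "in port": 1 = anchored, 2 = not in
#: operation.  Statuses 7 (fishing) and 8 (under way) and all other codes
#: are treated as not in port.
DEFAULT_IN_PORT_STATUSES = frozenset({1, 2})
DEFAULT_RADIUS_KM = 10.0
DEFAULT_MIN_DWELL_HOURS = 2.0
DEFAULT_VOLUME_M3 = 1000.0

__all__ = [
    "AISRecord", "Port", "PortCall", "Voyage", "RouteAggregate", "BallastRecord",
    "parse_ais_records", "detect_port_calls", "build_voyages", "aggregate_routes",
    "read_ports_csv", "write_ports_csv", "read_ballast_csv", "write_ballast_csv",
    "read_voyages_csv", "write_voyages_csv", "write_ais_csv",
    "DEFAULT_IN_PORT_STATUSES", "DEFAULT_RADIUS_KM", "DEFAULT_MIN_DWELL_HOURS",
    "DEFAULT_VOLUME_M3",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AISRecord:
    """One shipboard position report.

    ``ship_id`` is the vessel's official number (an opaque identifier),
    ``status`` the integer navigational status code in [0, 15].
    """

    ship_id: str
    timestamp: datetime
    status: int
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (0 <= self.status <= 15):
            raise ValueError(f"status {self.status} outside [0, 15]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} out of bounds")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} out of bounds")


@dataclass(frozen=True)
class Port:
    """A port with position and mean water-environment profile."""

    port_id: str
    name: str
    lon: float
    lat: float
    temperature_C: float
    salinity_PSU: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"port {self.port_id}: coordinates out of bounds")
        if not (-2.0 <= self.temperature_C <= 40.0):
            raise ValueError(f"port {self.port_id}: temperature {self.temperature_C} "
                             "outside [-2, 40] degC")
        if not (0.0 <= self.salinity_PSU <= 45.0):
            raise ValueError(f"port {self.port_id}: salinity {self.salinity_PSU} "
                             "outside [0, 45] PSU")


@dataclass(frozen=True)
class PortCall:
    ship_id: str
    port_id: str
    arrival: datetime
    departure: datetime

    def __post_init__(self) -> None:
        if self.arrival > self.departure:
            raise ValueError("port call arrival after departure")


@dataclass(frozen=True)
class Voyage:
    """One ship movement between two distinct ports.

    ``depart`` is when the ship left the source port (end of the previous
    call); ``arrive`` when it reached the destination (start of the next).
    ``ballast_volume_m3`` is the volume discharged at the destination.
    """

    ship_id: str
    source_port: str
    dest_port: str
    depart: datetime
    arrive: datetime
    ballast_volume_m3: float

    def __post_init__(self) -> None:
        if self.source_port == self.dest_port:
            raise ValueError("voyage source and destination must differ")
        if self.depart > self.arrive:
            raise ValueError("voyage departs after it arrives")
        if self.ballast_volume_m3 < 0:
            raise ValueError("negative ballast volume")

    @property
    def duration_hours(self) -> float:
        return (self.arrive - self.depart).total_seconds() / 3600.0


@dataclass(frozen=True)
class RouteAggregate:
    """All voyages over one ordered (source, dest) pair plus route length.

    ``distance_km`` defaults to the great-circle distance but may be
    overridden (e.g. with a routed sea distance) via ``replace``.
    :func:`aggregate_routes` only emits aggregates with at least one
    voyage; an empty aggregate is still constructible as the degenerate
    no-traffic input to the risk model (whose risk is exactly 0).
    """

    source_port: str
    dest_port: str
    voyages: tuple[Voyage, ...]
    distance_km: float

    def __post_init__(self) -> None:
        if self.distance_km <= 0:
            raise ValueError("route distance must be positive")
        for v in self.voyages:
            if (v.source_port, v.dest_port) != (self.source_port, self.dest_port):
                raise ValueError("voyage does not belong to this route")

    @property
    def n_voyages(self) -> int:
        return len(self.voyages)

    @property
    def total_volume_m3(self) -> float:
        return sum(v.ballast_volume_m3 for v in self.voyages)


@dataclass(frozen=True)
class BallastRecord:
    """One ballast discharge report: ship, receiving port, date, volume."""

    ship_id: str
    port_id: str
    date: date
    volume_m3: float

    def __post_init__(self) -> None:
        if self.volume_m3 < 0:
            raise ValueError("negative ballast volume in discharge log")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_timestamp(text: str) -> datetime:
    ts = datetime.fromisoformat(text.strip().replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def parse_ais_records(stream, strict: bool = False) -> list[AISRecord]:
    """Parse AIS CSV rows (``ship_id,timestamp,status,lon,lat``, header required).

    ``stream`` may be a path, an open text file, or an iterable of lines.
    Malformed rows (bad status, out-of-bounds coordinates, unparseable
    timestamps, missing fields) are skipped with a logged count, unless
    ``strict`` is set, in which case the first bad row raises
    :class:`ValueError` identifying its line number.
    """
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)  # inline CSV text
    elif isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        with open(stream, newline="") as fh:
            return parse_ais_records(fh, strict=strict)

    reader = csv.DictReader(stream)
    records: list[AISRecord] = []
    n_bad = 0
    # DictReader line numbers start after the header
    for row in reader:
        try:
            if row.get("lat") is None:
                raise ValueError("fewer than 5 fields")
            rec = AISRecord(
                ship_id=str(row["ship_id"]).strip(),
                timestamp=_parse_timestamp(row["timestamp"]),
                status=int(row["status"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            if strict:
                raise ValueError(
                    f"malformed AIS row at line {reader.line_num}: {exc}"
                ) from exc
            n_bad += 1
            continue
        records.append(rec)
    if n_bad:
        logger.warning("parse_ais_records: skipped %d malformed row(s)", n_bad)
    return records


def read_ports_csv(path) -> dict[str, Port]:
    """Read a port registry (port_id, name, lon, lat, temperature_C, salinity_PSU)."""
    ports: dict[str, Port] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            p = Port(
                port_id=str(row["port_id"]).strip(),
                name=str(row["name"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                temperature_C=float(row["temperature_C"]),
                salinity_PSU=float(row["salinity_PSU"]),
            )
            if p.port_id in ports:
                raise ValueError(f"duplicate port_id {p.port_id!r} in registry")
            ports[p.port_id] = p
    return ports


def write_ports_csv(ports: Mapping[str, Port] | Iterable[Port], path) -> None:
    if isinstance(ports, Mapping):
        ports = ports.values()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["port_id", "name", "lon", "lat", "temperature_C", "salinity_PSU"])
        for p in ports:
            w.writerow([p.port_id, p.name, repr(p.lon), repr(p.lat),
                        repr(p.temperature_C), repr(p.salinity_PSU)])


def read_ballast_csv(path) -> list[BallastRecord]:
    """Read a ballast discharge log (ship_id, port_id, date, volume_m3)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(BallastRecord(
                ship_id=str(row["ship_id"]).strip(),
                port_id=str(row["port_id"]).strip(),
                date=date.fromisoformat(str(row["date"]).strip()),
                volume_m3=float(row["volume_m3"]),
            ))
    return out


def write_ballast_csv(records: Iterable[BallastRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ship_id", "port_id", "date", "volume_m3"])
        for r in records:
            w.writerow([r.ship_id, r.port_id, r.date.isoformat(), repr(r.volume_m3)])


def write_ais_csv(records: Iterable[AISRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ship_id", "timestamp", "status", "lon", "lat"])
        for r in records:
            w.writerow([r.ship_id, r.timestamp.isoformat(), r.status,
                        repr(r.lon), repr(r.lat)])


def write_voyages_csv(voyages: Iterable[Voyage], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ship_id", "source_port", "dest_port", "depart", "arrive",
                    "ballast_volume_m3"])
        for v in voyages:
            w.writerow([v.ship_id, v.source_port, v.dest_port,
                        v.depart.isoformat(), v.arrive.isoformat(),
                        repr(v.ballast_volume_m3)])


def read_voyages_csv(path) -> list[Voyage]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(Voyage(
                ship_id=str(row["ship_id"]).strip(),
                source_port=str(row["source_port"]).strip(),
                dest_port=str(row["dest_port"]).strip(),
                depart=_parse_timestamp(row["depart"]),
                arrive=_parse_timestamp(row["arrive"]),
                ballast_volume_m3=float(row["ballast_volume_m3"]),
            ))
    return out


# ---------------------------------------------------------------------------
# port-call detection
# ---------------------------------------------------------------------------

class _PortIndex:
    """Nearest-port lookup on the unit sphere via a 3-D KD-tree.

    Great-circle distance is monotone in chord length, so a Euclidean
    nearest neighbour on unit vectors is also the great-circle nearest
    port, and a radius cut-off translates to a chord bound.
    """

    def __init__(self, ports: Sequence[Port]):
        self.ports = list(ports)
        xyz = _unit_vectors([p.lon for p in self.ports], [p.lat for p in self.ports])
        self.tree = cKDTree(np.atleast_2d(xyz))

    def nearest_within(self, lons, lats, radius_km: float) -> np.ndarray:
        """Index of the nearest port within ``radius_km``, else -1, per point."""
        chord = 2.0 * np.sin(min(radius_km / EARTH_RADIUS_KM, np.pi) / 2.0)
        xyz = _unit_vectors(lons, lats)
        dist, idx = self.tree.query(np.atleast_2d(xyz),
                                    distance_upper_bound=chord * (1 + 1e-12))
        idx = np.atleast_1d(idx)
        return np.where(np.isfinite(np.atleast_1d(dist)), idx, -1).astype(int)


def detect_port_calls(
    records: Iterable[AISRecord],
    ports: Mapping[str, Port] | Sequence[Port],
    radius_km: float = DEFAULT_RADIUS_KM,
    min_dwell_hours: float = DEFAULT_MIN_DWELL_HOURS,
    in_port_statuses: frozenset[int] = DEFAULT_IN_PORT_STATUSES,
) -> list[PortCall]:
    """Extract port calls from position reports.

    A call is a maximal run of consecutive pings of one ship (in time
    order; sorting is internal, so input order is irrelevant) whose status
    is in ``in_port_statuses`` and which all resolve to the same nearest
    port within ``radius_km``; the run must span at least
    ``min_dwell_hours``.  Arrival and departure are the run's first and
    last ping times.  An in-port-status ping outside every port's radius
    resolves to no port and therefore terminates any open run.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    port_list = list(ports.values()) if isinstance(ports, Mapping) else list(ports)
    if not port_list:
        return []
    index = _PortIndex(port_list)

    recs = sorted(records, key=lambda r: (r.ship_id, r.timestamp))
    if not recs:
        return []

    # resolve every ping to a port id (or None) in one vectorised query
    lons = np.array([r.lon for r in recs])
    lats = np.array([r.lat for r in recs])
    nearest = index.nearest_within(lons, lats, radius_km)
    assigned: list[str | None] = [
        port_list[i].port_id if (i >= 0 and r.status in in_port_statuses) else None
        for r, i in zip(recs, nearest)
    ]

    calls: list[PortCall] = []

    def _close(ship: str, port: str, first: datetime, last: datetime) -> None:
        if (last - first).total_seconds() / 3600.0 >= min_dwell_hours:
            calls.append(PortCall(ship, port, first, last))

    open_run: tuple[str, str, datetime, datetime] | None = None  # ship, port, first, last
    for rec, port_id in zip(recs, assigned):
        if open_run is not None and (port_id is None
                                     or rec.ship_id != open_run[0]
                                     or port_id != open_run[1]):
            _close(*open_run)
            open_run = None
        if port_id is not None:
            if open_run is None:
                open_run = (rec.ship_id, port_id, rec.timestamp, rec.timestamp)
            else:
                open_run = (open_run[0], open_run[1], open_run[2], rec.timestamp)
    if open_run is not None:
        _close(*open_run)
    return calls


# ---------------------------------------------------------------------------
# voyages & routes
# ---------------------------------------------------------------------------

def build_voyages(
    port_calls: Iterable[PortCall],
    ballast_log: Iterable[BallastRecord] = (),
    default_volume_m3: float = DEFAULT_VOLUME_M3,
) -> list[Voyage]:
    """Pair consecutive distinct-port calls of each ship into voyages.

    The voyage departs at the earlier call's departure and arrives at the
    later call's arrival.  Ballast volume is the sum of log entries for
    (ship, destination port) whose discharge date falls within the
    destination call's [arrival date, departure date] window (UTC); each
    log entry is consumed by at most one call (earliest call first), so
    back-to-back visits never double-count a discharge.  With no
    matching entry the voyage gets ``default_volume_m3`` — discharge
    logs (like the US NBIC archive) rarely cover every port worldwide.
    Consecutive calls at the same port produce no voyage.
    """
    if default_volume_m3 < 0:
        raise ValueError("default_volume_m3 must be non-negative")
    log_by_key: dict[tuple[str, str], list[list]] = defaultdict(list)
    for rec in ballast_log:
        # [record, consumed?] — entries are matched to at most one call
        log_by_key[(rec.ship_id, rec.port_id)].append([rec, False])

    by_ship: dict[str, list[PortCall]] = defaultdict(list)
    for call in port_calls:
        by_ship[call.ship_id].append(call)

    voyages: list[Voyage] = []
    n_same = 0
    for ship in sorted(by_ship):
        seq = sorted(by_ship[ship], key=lambda c: c.arrival)
        for prev, nxt in zip(seq, seq[1:]):
            if prev.port_id == nxt.port_id:
                n_same += 1
                continue
            entries = log_by_key.get((ship, nxt.port_id), ())
            window = (nxt.arrival.date(), nxt.departure.date())
            matched = []
            for slot in entries:
                rec, consumed = slot
                if not consumed and window[0] <= rec.date <= window[1]:
                    matched.append(rec.volume_m3)
                    slot[1] = True
            volume = sum(matched) if matched else default_volume_m3
            voyages.append(Voyage(ship, prev.port_id, nxt.port_id,
                                  prev.departure, nxt.arrival, volume))
    if n_same:
        logger.info("build_voyages: dropped %d same-port call pair(s)", n_same)
    return voyages


def aggregate_routes(
    voyages: Iterable[Voyage],
    ports: Mapping[str, Port],
) -> list[RouteAggregate]:
    """Group voyages by ordered (source, dest) pair and attach route length.

    Every voyage's ports must exist in the registry.  Aggregates are
    returned sorted by (source, dest) for reproducible downstream output.
    """
    groups: dict[tuple[str, str], list[Voyage]] = defaultdict(list)
    for v in voyages:
        for pid in (v.source_port, v.dest_port):
            if pid not in ports:
                raise KeyError(f"voyage references unregistered port {pid!r}")
        groups[(v.source_port, v.dest_port)].append(v)

    out = []
    for (src, dst) in sorted(groups):
        a, b = ports[src], ports[dst]
        out.append(RouteAggregate(
            source_port=src,
            dest_port=dst,
            voyages=tuple(groups[(src, dst)]),
            distance_km=great_circle_distance_km(a.lon, a.lat, b.lon, b.lat),
        ))
    return out
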