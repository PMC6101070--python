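"""Synthetic AIS traffic and its round trip through the ingest chain.

Generates a small world (12 ports, 6 ships, 40 days), renders the planted
voyages as a shuffled AIS ping stream, then recovers port calls and
voyages from the pings alone and compares against the planted truth.
"""

from ballastnet import (WorldSpec, build_voyages, detect_port_calls,
                        generate_ais_stream, generate_ports, generate_voyages)

spec = WorldSpec(n_ports=12, n_ships=6, duration_days=40, hub_ports=2,
                 hub_boost=5.0, seed=7)
ports = generate_ports(spec)
truth, ballast_log = generate_voyages(ports, spec)
stream = generate_ais_stream(truth, ports, spec)
print(f"world: {len(ports)} ports, {len(truth)} planted voyages, "
      f"{len(stream)} AIS pings")

calls = detect_port_calls(stream, ports, radius_km=10.0, min_dwell_hours=2.0)
voyages = build_voyages(calls, ballast_log)
print(f"ingest: {len(calls)} port calls -> {len(voyages)} voyages")


def as_set(vs):
    return {(v.ship_id, v.source_port, v.dest_port, v.depart, v.arrive,
             v.ballast_volume_m3) for v in vs}


print("recovered == planted:", as_set(voyages) == as_set(truth))
v = voyages[0]
print(f"\nexample voyage: {v.ship_id} {v.source_port}->{v.dest_port}, "
      f"{v.duration_hours:.1f} h at sea, {v.ballast_volume_m3:.0f} m3 discharged")
print("A port call is a run of anchored pings within 10 km of one port "
      "lasting >= 2 h; consecutive calls at distinct ports form a voyage.")
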