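"""Route-level invasion risk from first principles.

Builds two ports and a shipping route with three ballast discharges, then
walks through the three risk kernels and their aggregation to the route
and to the receiving port.
"""

from datetime import datetime, timedelta, timezone

from ballastnet import (Port, RiskKernelParams, RouteAggregate, Voyage,
                        great_circle_distance_km, p_alien, p_estab, p_intro,
                        port_invaded_risk, route_invasion_risk)

singapore_like = Port("SRC", "Source hub", 103.8, 1.3, 29.0, 33.0)
gulf_like = Port("DST", "Receiving port", 55.3, 25.3, 28.0, 38.0)

t0 = datetime(2014, 3, 1, tzinfo=timezone.utc)
voyages = tuple(
    Voyage("SHIP%d" % i, "SRC", "DST", t0 + timedelta(days=10 * i),
           t0 + timedelta(days=10 * i + 8), volume)
    for i, volume in enumerate([1200.0, 800.0, 2500.0])
)
distance = great_circle_distance_km(singapore_like.lon, singapore_like.lat,
                                    gulf_like.lon, gulf_like.lat)
route = RouteAggregate("SRC", "DST", voyages, distance)

params = RiskKernelParams()  # lambda_d=5000 km, mu=0.001 /m3, p_max=0.1
print(f"route distance: {distance:.0f} km")
print(f"P(Alien)  = {p_alien(distance, params):.4f}   "
      "(chance a source-native species is alien at the destination)")
print(f"P(Intro)  = {p_intro(1200.0, params):.4f}   (for a 1200 m3 discharge)")
print(f"P(Estab)  = {p_estab(singapore_like, gulf_like, params):.4f}   "
      "(1 degC and 5 PSU mismatch)")

rr = route_invasion_risk(route, singapore_like, gulf_like, params)
print(f"\nroute invasion risk over {route.n_voyages} arrivals: {rr.p_inv:.6f}")

# the port's invaded risk accumulates over all incoming routes
p_port = port_invaded_risk([rr.p_inv, 0.004948834])
print(f"invaded risk with a second incoming route of weight 0.004948834: "
      f"{p_port:.6f}")
print("\nEach arrival is an independent chance of a successful invasion; "
      "risks accumulate as 1 - prod(1 - p).")
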