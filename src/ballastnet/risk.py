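"""Route-level and port-level invasion risk.

The risk that shipping on a route from port *i* to port *j* causes an
invasion combines three per-arrival factors:

* ``P(Alien)`` — the chance a species native at the source is non-native
  at the destination, a function of route distance;
* ``P(Intro)`` — the chance organisms entrained in ballast tanks survive
  and are introduced, increasing with discharged volume;
* ``P(Estab)`` — the chance introduced organisms establish, governed by
  the temperature and salinity mismatch between the two ports.

Over all ship arrivals ``e`` on the route::

    P_ij(Inv) = 1 - prod_e [ 1 - P_ij(Alien) * P_e(Intro) * P_ij(Estab) ]

and a port's *invaded risk* accumulates over its incoming routes::

    P_j(Inv) = 1 - prod_i [ 1 - P_ij(Inv) ]

The three kernels are pluggable parametric forms (the literature offers
several calibrations); the defaults satisfy the qualitative constraints
above and keep every output a probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ingest import Port, RouteAggregate

#: Above this many arrivals per route the survival product is accumulated
#: in log space to avoid underflow.
_LOG_SPACE_THRESHOLD = 50

__all__ = [
    "RiskKernelParams", "RouteRisk",
    "p_alien", "p_intro", "p_estab",
    "route_invasion_risk", "port_invaded_risk",
]


@dataclass(frozen=True)
class RiskKernelParams:
    """Parameters of the three invasion-risk kernels.

    lambda_d : float
        Characteristic distance of the alienness kernel, km.
    mu : float
        Per-m3 introduction rate of the ballast survival kernel.
    p_max : float
        Establishment probability under a perfect environmental match.
    sigma_T, sigma_S : float
        Gaussian niche widths for temperature (degC) and salinity (PSU).
    alien_direction : str
        ``"increasing"`` (default): alienness grows with biogeographic
        separation, ``P(Alien) = 1 - exp(-d/lambda_d)``.
        ``"decreasing"``: ``P(Alien) = lambda_d / (lambda_d + d)``, the
        reading under which nearby ports share more alien species.
    survival_decay_per_hour : float
        Optional in-transit mortality rate; when positive, ``P(Intro)``
        is multiplied by ``exp(-delta * voyage hours)``.  Off by default.
    """

    lambda_d: float = 5000.0
    mu: float = 0.001
    p_max: float = 0.1
    sigma_T: float = 3.0
    sigma_S: float = 5.0
    alien_direction: str = "increasing"
    survival_decay_per_hour: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_d <= 0 or self.mu <= 0 or self.sigma_T <= 0 or self.sigma_S <= 0:
            raise ValueError("lambda_d, mu, sigma_T, sigma_S must be positive")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("p_max must be in (0, 1]")
        if self.alien_direction not in ("increasing", "decreasing"):
            raise ValueError("alien_direction must be 'increasing' or 'decreasing'")
        if self.survival_decay_per_hour < 0:
            raise ValueError("survival_decay_per_hour must be non-negative")


@dataclass(frozen=True)
class RouteRisk:
    """Invasion risk of one ordered route, with a per-arrival trace.

    ``components`` holds one ``(p_alien, p_intro, p_estab)`` triple per
    voyage, in input order, so the aggregation is auditable.
    """

    source_port: str
    dest_port: str
    p_inv: float
    components: tuple[tuple[float, float, float], ...] = field(default=())
    n_voyages: int = 0
    distance_km: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_inv <= 1.0):
            raise ValueError("p_inv must be a probability")


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def p_alien(distance_km: float, params: RiskKernelParams) -> float:
    """Probability that a source-native species is alien at the destination."""
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    if params.alien_direction == "increasing":
        return -math.expm1(-distance_km / params.lambda_d)
    return params.lambda_d / (params.lambda_d + distance_km)


def p_intro(volume_m3: float, params: RiskKernelParams) -> float:
    """Probability of introduction from discharging ``volume_m3`` of ballast."""
    if volume_m3 < 0:
        raise ValueError("volume must be non-negative")
    return -math.expm1(-params.mu * volume_m3)


def p_estab(env_source: Port, env_dest: Port, params: RiskKernelParams) -> float:
    """Establishment probability from the temperature/salinity mismatch.

    A separable Gaussian niche: maximal (``p_max``) when the two ports'
    mean temperature and salinity coincide, decaying with the squared
    differences scaled by the niche widths.
    """
    dT = env_dest.temperature_C - env_source.temperature_C
    dS = env_dest.salinity_PSU - env_source.salinity_PSU
    return params.p_max * math.exp(
        -dT * dT / (2.0 * params.sigma_T ** 2)
        - dS * dS / (2.0 * params.sigma_S ** 2)
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def route_invasion_risk(
    route: RouteAggregate,
    source: Port,
    dest: Port,
    params: RiskKernelParams = RiskKernelParams(),
) -> RouteRisk:
    """Invasion risk of one route over all its ship arrivals.

    ``P(Alien)`` and ``P(Estab)`` depend only on the route geometry and
    port environments and are computed once; ``P(Intro)`` varies per
    arrival with the discharged volume (and optionally decays with
    voyage duration).  The survival product is taken in log space when
    the route has many arrivals.
    """
    if (route.source_port, route.dest_port) != (source.port_id, dest.port_id):
        raise ValueError("route endpoints do not match the given ports")

    pa = p_alien(route.distance_km, params)
    pe = p_estab(source, dest, params)
    components = []
    per_arrival = []
    for v in route.voyages:
        pi = p_intro(v.ballast_volume_m3, params)
        if params.survival_decay_per_hour > 0:
            pi *= math.exp(-params.survival_decay_per_hour * v.duration_hours)
        components.append((pa, pi, pe))
        per_arrival.append(pa * pi * pe)

    if len(per_arrival) > _LOG_SPACE_THRESHOLD:
        log_surv = float(np.sum(np.log1p(-np.asarray(per_arrival))))
        p_inv = -math.expm1(log_surv)
    else:
        surv = 1.0
        for p in per_arrival:
            surv *= 1.0 - p
        p_inv = 1.0 - surv
    p_inv = min(max(p_inv, 0.0), 1.0)
    return RouteRisk(route.source_port, route.dest_port, p_inv,
                     tuple(components), len(per_arrival), route.distance_km)


def port_invaded_risk(incoming: Iterable[RouteRisk] | Sequence[float]) -> float:
    """Invaded risk of one port from its incoming route risks.

    Accepts :class:`RouteRisk` objects (which must all share one
    destination) or bare probabilities.  Accumulated in log space, so
    ``log(1 - P_j) = sum_i log(1 - P_ij)`` holds to round-off.
    """
    items = list(incoming)
    probs = []
    dests = set()
    for it in items:
        if isinstance(it, RouteRisk):
            dests.add(it.dest_port)
            probs.append(it.p_inv)
        else:
            probs.append(float(it))
    if len(dests) > 1:
        raise ValueError(f"mixed destination ports: {sorted(dests)}")
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise ValueError("route risks must be probabilities")
    if not probs:
        return 0.0
    if len(probs) == 1:
        return probs[0]
    if any(p == 1.0 for p in probs):
        return 1.0
    log_surv = float(np.sum(np.log1p(-np.asarray(probs, dtype=float))))
    return min(max(-math.expm1(log_surv), 0.0), 1.0)
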