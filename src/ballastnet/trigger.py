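"""Composite bioinvasion risk and the biosecurity trigger.

A port is risky in two distinct ways: it may *receive* invaders (its
invaded risk ``P_j(Inv)`` over incoming routes) and it may *relay* them
(its s-shell depth in the invasion network, the stepping-stone power).
Both are normalised to [0, 1] across the current port set and combined
linearly with a tradeoff weight theta::

    R(j) = theta * P~_j(Inv) + (1 - theta) * s~(j)

Biosecurity controls are triggered at ports with ``R(j) >= T``.
theta = 0.5 treats incoming and outgoing risk equally; smaller theta
emphasises stepping-stone spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import Port
from .score import ShellAssignment

__all__ = [
    "TriggerParams", "min_max_normalize", "bioinvasion_risk", "trigger_report",
]


@dataclass(frozen=True)
class TriggerParams:
    """``theta``: tradeoff weight between invaded risk and shell depth;
    ``T``: trigger threshold on the composite score.  Both in [0, 1]."""

    theta: float = 0.5
    T: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0) or not (0.0 <= self.T <= 1.0):
            raise ValueError("theta and T must lie in [0, 1]")


def min_max_normalize(values: Sequence[float]) -> np.ndarray:
    """Map values affinely onto [0, 1]; a constant collection maps to all
    zeros (the component then cannot influence any ranking)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty collection")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _rank_normalize(values: Sequence[float]) -> np.ndarray:
    """Average-rank normalisation onto [0, 1] (robust to outliers)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty collection")
    if x.size == 1 or np.all(x == x[0]):
        return np.zeros_like(x)
    r = stats.rankdata(x, method="average") - 1.0
    return r / (x.size - 1.0)


def bioinvasion_risk(p_tilde: float, s_tilde: float, theta: float) -> float:
    """Composite risk ``theta * p_tilde + (1 - theta) * s_tilde``."""
    for name, v in (("p_tilde", p_tilde), ("s_tilde", s_tilde), ("theta", theta)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return theta * p_tilde + (1.0 - theta) * s_tilde


def trigger_report(
    ports: Mapping[str, Port] | Sequence[str],
    invaded_risks: Mapping[str, float],
    shell_assignment: ShellAssignment | Mapping[str, int],
    params: TriggerParams = TriggerParams(),
    top_n: int = 100,
    normalization: str = "minmax",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank ports by composite bioinvasion risk and flag those over T.

    ``invaded_risks`` and the shell assignment must cover exactly the
    given port set.  Returns ``(report, ranked)``: the full report with
    one row per port (columns ``port_id, p_inv, shell_index, p_tilde,
    s_tilde, R, triggered``) sorted by R descending — ties by p_tilde
    descending, then port_id — and its ``top_n`` head.  Normalisation is
    min-max by default, or rank-based with ``normalization="rank"``.
    """
    port_ids = sorted(ports.keys() if isinstance(ports, Mapping) else ports)
    shells = (shell_assignment.shell_of if isinstance(shell_assignment, ShellAssignment)
              else dict(shell_assignment))
    if set(invaded_risks) != set(port_ids) or set(shells) != set(port_ids):
        raise ValueError("invaded risks and shell assignment must cover "
                         "exactly the given port set")
    if top_n < 0:
        raise ValueError("top_n must be non-negative")
    norm = {"minmax": min_max_normalize, "rank": _rank_normalize}.get(normalization)
    if norm is None:
        raise ValueError(f"unknown normalization {normalization!r}")

    p = np.array([invaded_risks[pid] for pid in port_ids], dtype=float)
    s = np.array([shells[pid] for pid in port_ids], dtype=float)
    p_t = norm(p)
    s_t = norm(s)
    R = params.theta * p_t + (1.0 - params.theta) * s_t

    report = pd.DataFrame({
        "port_id": port_ids,
        "p_inv": p,
        "shell_index": s.astype(int),
        "p_tilde": p_t,
        "s_tilde": s_t,
        "R": R,
        "triggered": R >= params.T,
    })
    report = report.sort_values(
        ["R", "p_tilde", "port_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    report.insert(0, "rank", np.arange(1, len(report) + 1))
    return report, report.head(top_n).copy()
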