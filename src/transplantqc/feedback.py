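"""Operational feedback: anomaly clustering, replant routes, twin messages,
and machine compensation signals.

After a run is assessed, the non-normal events feed three outputs:

* spatial clusters of anomalies (density-based, DBSCAN), so nearby problems
  can be replanted in one visit — isolated anomalies still form their own
  single-member clusters because every one must be replantable;
* an open replanting route over all anomaly points, built nearest-neighbour
  first and polished with 2-opt (route length is the optimality criterion);
* a stream of digital-twin JSON messages, one compact object per event with
  keys ``latitude``, ``longitude``, ``state``;
* windowed depth/spacing compensation signals for the transplanter: a high
  frequency of buried (exposed-root) seedlings in a sliding event window
  asks the depth actuator to raise (lower) the planting mechanism, and a
  sustained spacing drift asks for a planting-frequency adjustment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .assessment import TWIN_STATE, TransplantEvent, TransplantStatus
from .geodesy import PlanePoint, plane_distance

__all__ = [
    "AnomalyCluster",
    "ReplantRoute",
    "SignalKind",
    "CompensationSignal",
    "cluster_anomalies",
    "replant_route",
    "nearest_neighbor_route",
    "twin_messages",
    "twin_message_lines",
    "compensation_signals",
]


def anomalies(events: Sequence[TransplantEvent]) -> List[TransplantEvent]:
    return [e for e in events if e.status is not TransplantStatus.NORMAL]


@dataclass
class AnomalyCluster:
    members: List[TransplantEvent]
    centroid: PlanePoint
    radius: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")


def cluster_anomalies(
    events: Sequence[TransplantEvent],
    d_std: float = 0.5,
    eps_mult: float = 3.0,
    min_pts: int = 2,
) -> List[AnomalyCluster]:
    """Density-based clustering of anomaly events.

    Neighbourhood radius is ``eps_mult · d_std``.  DBSCAN noise points are
    kept as single-member clusters rather than discarded.
    """
    pts = anomalies(events)
    if not pts:
        return []
    X = np.array([[e.plane.x, e.plane.y] for e in pts])
    labels = DBSCAN(eps=eps_mult * d_std, min_samples=min_pts).fit_predict(X)
    clusters: List[AnomalyCluster] = []
    groups: Dict[int, List[int]] = {}
    singleton_order: List[List[int]] = []
    for i, lab in enumerate(labels):
        if lab == -1:
            singleton_order.append([i])
        else:
            groups.setdefault(int(lab), []).append(i)
    for idxs in list(groups.values()) + singleton_order:
        members = [pts[i] for i in idxs]
        cx = float(np.mean([m.plane.x for m in members]))
        cy = float(np.mean([m.plane.y for m in members]))
        centroid = PlanePoint(cx, cy)
        radius = max(plane_distance(centroid, m.plane) for m in members)
        clusters.append(AnomalyCluster(members=members, centroid=centroid, radius=radius))
    return clusters


@dataclass
class ReplantRoute:
    """An open visiting order over anomaly points, starting from ``start``."""

    start: PlanePoint
    stops: List[TransplantEvent]

    @property
    def total_length(self) -> float:
        if not self.stops:
            return 0.0
        length = plane_distance(self.start, self.stops[0].plane)
        for a, b in zip(self.stops, self.stops[1:]):
            length += plane_distance(a.plane, b.plane)
        return length


def nearest_neighbor_route(points: List[PlanePoint], start: PlanePoint) -> List[int]:
    """Visit order by repeatedly taking the closest unvisited point."""
    order: List[int] = []
    remaining = set(range(len(points)))
    cur = start
    while remaining:
        nxt = min(remaining, key=lambda i: plane_distance(cur, points[i]))
        order.append(nxt)
        remaining.remove(nxt)
        cur = points[nxt]
    return order


def _route_length(points: List[PlanePoint], order: List[int], start: PlanePoint) -> float:
    if not order:
        return 0.0
    length = plane_distance(start, points[order[0]])
    for a, b in zip(order, order[1:]):
        length += plane_distance(points[a], points[b])
    return length


def _two_opt(points: List[PlanePoint], order: List[int], start: PlanePoint) -> List[int]:
    # open-path 2-opt: reverse segments while any reversal shortens the route
    improved = True
    best = list(order)
    best_len = _route_length(points, best, start)
    while improved:
        improved = False
        n = len(best)
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = best[:i] + best[i : j + 1][::-1] + best[j + 1 :]
                cand_len = _route_length(points, cand, start)
                if cand_len < best_len - 1e-12:
                    best, best_len = cand, cand_len
                    improved = True
    return best


def replant_route(
    events: Sequence[TransplantEvent], start: PlanePoint
) -> ReplantRoute:
    """Open replanting path over all anomaly events: NN construction + 2-opt.

    Deterministic given event order and start; an anomaly-free run yields an
    empty route.
    """
    pts = anomalies(events)
    if not pts:
        return ReplantRoute(start=start, stops=[])
    coords = [e.plane for e in pts]
    order = nearest_neighbor_route(coords, start)
    order = _two_opt(coords, order, start)
    return ReplantRoute(start=start, stops=[pts[i] for i in order])


def twin_messages(events: Sequence[TransplantEvent]) -> List[dict]:
    """One twin message per event: latitude, longitude, state.

    States use the twin vocabulary
    {normal, missed, double, buried, exposed_root}.
    """
    return [
        {
            "latitude": e.geo.latitude,
            "longitude": e.geo.longitude,
            "state": TWIN_STATE[e.status],
        }
        for e in events
    ]


def twin_message_lines(events: Sequence[TransplantEvent], decimals: int = 5) -> List[str]:
    """Serialized JSONL twin messages, coordinates at fixed ≥5-decimal precision."""
    lines = []
    for e in events:
        lines.append(
            '{"latitude": %.*f, "longitude": %.*f, "state": "%s"}'
            % (decimals, e.geo.latitude, decimals, e.geo.longitude, TWIN_STATE[e.status])
        )
    return lines


class SignalKind(str, Enum):
    RAISE_DEPTH = "raise_depth"
    LOWER_DEPTH = "lower_depth"
    SPACING_ADJUST = "spacing_adjust"


@dataclass(frozen=True)
class CompensationSignal:
    kind: SignalKind
    magnitude: float  # fraction triggering a depth signal; relative spacing deviation otherwise
    window_start: int  # index of the first event in the triggering window
    window: int


def compensation_signals(
    events: Sequence[TransplantEvent],
    d_std: float = 0.5,
    window: int = 20,
    trigger_frac: float = 0.2,
    spacing_tol: float = 0.1,
) -> List[CompensationSignal]:
    """Sliding-window machine compensation signals.

    For each window of ``window`` consecutive events: a burial fraction
    above ``trigger_frac`` emits ``raise_depth``; an exposure fraction
    above it emits ``lower_depth``; a mean spacing deviating from
    ``d_std`` by more than ``spacing_tol`` (relative) emits
    ``spacing_adjust`` with the relative deviation as magnitude.  At most
    one signal per kind per window position.
    """
    signals: List[CompensationSignal] = []
    n = len(events)
    if n < window:
        return signals
    for start in range(0, n - window + 1):
        chunk = events[start : start + window]
        bury = sum(1 for e in chunk if e.status is TransplantStatus.SEEDLING_BURIAL)
        expose = sum(1 for e in chunk if e.status is TransplantStatus.ROOT_EXPOSURE)
        if bury / window > trigger_frac:
            signals.append(
                CompensationSignal(SignalKind.RAISE_DEPTH, bury / window, start, window)
            )
        if expose / window > trigger_frac:
            signals.append(
                CompensationSignal(SignalKind.LOWER_DEPTH, expose / window, start, window)
            )
        spacings = [e.spacing_before for e in chunk if e.spacing_before is not None]
        if spacings:
            deviation = (sum(spacings) / len(spacings) - d_std) / d_std
            if abs(deviation) > spacing_tol:
                signals.append(
                    CompensationSignal(SignalKind.SPACING_ADJUST, deviation, start, window)
                )
    return signals
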