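"""Five-status transplanting classification from counted plant sequences.

Each counted seedling (or gap between seedlings) is assigned one of five
statuses by combining in-row spacing with the visual detector class, in
strict descending priority:

1. **double planting** — a maximal chain of consecutive plants whose
   successive spacings are all below ``low_mult · d_std`` collapses into a
   single event at the chain centroid, overriding any visual class;
2. **missed planting** — a remaining gap above ``high_mult · d_std`` emits
   interpolated missed-point events inside the gap;
3. **seedling burial** / **root exposure** / **normal** — plants whose
   spacing sits in the normal band keep their visual class.

Spacing thresholds are inclusive: a spacing exactly equal to
``low_mult · d_std`` or ``high_mult · d_std`` is in the normal band.
The first plant of a ridge has no predecessor spacing and is classified on
its visual class alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence

from .fusion import FusedPlant, SeedlingClass
from .geodesy import GeoPoint, PlanePoint, plane_distance

__all__ = [
    "SpacingConfig",
    "TransplantStatus",
    "TransplantEvent",
    "split_ridges",
    "compute_spacings",
    "classify_ridge",
    "interpolate_missed",
    "assess_run",
]


@dataclass
class SpacingConfig:
    """Agronomic spacing thresholds.

    ``d_std`` is the standard in-row spacing (about 0.5 m for tobacco).
    Spacings below ``0.4 · d_std`` indicate double planting; above
    ``1.6 · d_std``, missed planting.  ``ridge_break_mult`` is the spacing
    multiple beyond which consecutive plants are treated as belonging to
    different ridges.
    """

    d_std: float = 0.5
    low_mult: float = 0.4
    high_mult: float = 1.6
    ridge_break_mult: float = 5.0
    #: a step deviating from the ridge's running heading by more than this
    #: angle starts a new ridge; 80° keeps an exactly-perpendicular headland
    #: step a deterministic break while in-row jitter stays far below it
    heading_break_deg: float = 80.0

    def __post_init__(self) -> None:
        if self.d_std <= 0:
            raise ValueError("d_std must be positive")
        if not 0 < self.low_mult < 1 < self.high_mult:
            raise ValueError("need 0 < low_mult < 1 < high_mult")


class TransplantStatus(str, Enum):
    """The five statuses, listed in descending decision priority."""

    DOUBLE_PLANTING = "double_planting"
    MISSED_PLANTING = "missed_planting"
    SEEDLING_BURIAL = "seedling_burial"
    ROOT_EXPOSURE = "root_exposure"
    NORMAL = "normal"


#: Status names used in digital-twin messages.
TWIN_STATE = {
    TransplantStatus.NORMAL: "normal",
    TransplantStatus.MISSED_PLANTING: "missed",
    TransplantStatus.DOUBLE_PLANTING: "double",
    TransplantStatus.SEEDLING_BURIAL: "buried",
    TransplantStatus.ROOT_EXPOSURE: "exposed_root",
}

_VISUAL_STATUS = {
    SeedlingClass.NORMAL: TransplantStatus.NORMAL,
    SeedlingClass.BURIED: TransplantStatus.SEEDLING_BURIAL,
    SeedlingClass.EXPOSED_ROOT: TransplantStatus.ROOT_EXPOSURE,
}


@dataclass(frozen=True)
class TransplantEvent:
    """One classified planting point.

    ``member_plant_ids`` holds the counted plants behind the event: at
    least two for a double-planting chain, none for an interpolated missed
    point, exactly one otherwise.  ``spacing_before`` is the distance to
    the previous event's location (``None`` for the first of a ridge).
    """

    status: TransplantStatus
    geo: GeoPoint
    plane: PlanePoint
    member_plant_ids: tuple = ()
    spacing_before: Optional[float] = None

    def __post_init__(self) -> None:
        n = len(self.member_plant_ids)
        if self.status is TransplantStatus.DOUBLE_PLANTING and n < 2:
            raise ValueError("double-planting event needs ≥ 2 members")
        if self.status is TransplantStatus.MISSED_PLANTING and n != 0:
            raise ValueError("missed-planting event carries no members")
        if (
            self.status
            not in (TransplantStatus.DOUBLE_PLANTING, TransplantStatus.MISSED_PLANTING)
            and n != 1
        ):
            raise ValueError(f"{self.status.value} event needs exactly 1 member")


def split_ridges(
    plants: Sequence[FusedPlant], cfg: SpacingConfig
) -> List[List[FusedPlant]]:
    """Partition a time-ordered plant sequence into ridges.

    A new ridge begins when consecutive spacing exceeds
    ``ridge_break_mult · d_std`` or the step direction deviates from the
    current ridge's running heading by more than ``heading_break_deg``
    (a serpentine headland turn).
    """
    if not plants:
        return []
    cos_break = math.cos(math.radians(cfg.heading_break_deg))
    ridges: List[List[FusedPlant]] = [[plants[0]]]
    heading = (0.0, 0.0)  # running displacement sum of the current ridge
    for prev, cur in zip(plants, plants[1:]):
        disp = (cur.plane.x - prev.plane.x, cur.plane.y - prev.plane.y)
        gap = math.hypot(*disp)
        h_norm = math.hypot(*heading)
        turned = False
        if h_norm > 0.0 and gap > 0.0:
            cos_angle = (heading[0] * disp[0] + heading[1] * disp[1]) / (h_norm * gap)
            turned = cos_angle < cos_break
        if gap > cfg.ridge_break_mult * cfg.d_std or turned:
            ridges.append([cur])
            heading = (0.0, 0.0)
        else:
            ridges[-1].append(cur)
            heading = (heading[0] + disp[0], heading[1] + disp[1])
    return ridges


def compute_spacings(ridge: Sequence[FusedPlant]) -> List[float]:
    """Planar Euclidean distances between consecutive plants (length n−1)."""
    return [
        plane_distance(a.plane, b.plane) for a, b in zip(ridge, ridge[1:])
    ]


def _lerp_geo(a: GeoPoint, b: GeoPoint, w: float) -> GeoPoint:
    # the spacing projection is linear in (lat, lon), so affine combinations
    # commute with it: interpolating in degrees equals interpolating in the plane
    return GeoPoint(
        latitude=a.latitude + w * (b.latitude - a.latitude),
        longitude=a.longitude + w * (b.longitude - a.longitude),
    )


def _missed_points(
    a_plane: PlanePoint,
    a_geo: GeoPoint,
    b_plane: PlanePoint,
    b_geo: GeoPoint,
    cfg: SpacingConfig,
) -> List[TransplantEvent]:
    d = plane_distance(a_plane, b_plane)
    if d <= cfg.high_mult * cfg.d_std:
        raise ValueError(
            f"gap {d:.3f} m does not exceed the missed-planting threshold "
            f"{cfg.high_mult * cfg.d_std:.3f} m"
        )
    # round() is round-half-to-even; affects only knife-edge gaps
    n_missed = max(1, round(d / cfg.d_std) - 1)
    events = []
    for k in range(1, n_missed + 1):
        w = k / (n_missed + 1)
        plane = PlanePoint(
            x=a_plane.x + w * (b_plane.x - a_plane.x),
            y=a_plane.y + w * (b_plane.y - a_plane.y),
        )
        events.append(
            TransplantEvent(
                status=TransplantStatus.MISSED_PLANTING,
                geo=_lerp_geo(a_geo, b_geo, w),
                plane=plane,
                member_plant_ids=(),
                spacing_before=d / (n_missed + 1),
            )
        )
    return events


def interpolate_missed(
    a: FusedPlant, b: FusedPlant, cfg: SpacingConfig
) -> List[TransplantEvent]:
    """Missed-planting points inside a wide gap between plants ``a`` and ``b``.

    The gap of length ``d`` yields ``max(1, round(d / d_std) − 1)`` points
    placed at equal fractions along the segment; geographic coordinates are
    recovered by the exact linearity of the spacing projection.
    """
    return _missed_points(a.plane, a.geo, b.plane, b.geo, cfg)


@dataclass
class _Element:
    """A collapsed ridge element: a single plant or a double-planting chain."""

    plane: PlanePoint
    geo: GeoPoint
    members: List[FusedPlant]

    @property
    def is_chain(self) -> bool:
        return len(self.members) > 1


def _collapse_chains(ridge: Sequence[FusedPlant], cfg: SpacingConfig) -> List[_Element]:
    spacings = compute_spacings(ridge)
    thresh = cfg.low_mult * cfg.d_std
    elements: List[_Element] = []
    i = 0
    n = len(ridge)
    while i < n:
        j = i
        while j < n - 1 and spacings[j] < thresh:
            j += 1
        members = list(ridge[i : j + 1])
        if len(members) == 1:
            p = members[0]
            elements.append(_Element(plane=p.plane, geo=p.geo, members=members))
        else:
            cx = sum(p.plane.x for p in members) / len(members)
            cy = sum(p.plane.y for p in members) / len(members)
            lat = sum(p.geo.latitude for p in members) / len(members)
            lon = sum(p.geo.longitude for p in members) / len(members)
            elements.append(
                _Element(
                    plane=PlanePoint(cx, cy),
                    geo=GeoPoint(lat, lon),
                    members=members,
                )
            )
        i = j + 1
    return elements


def classify_ridge(
    ridge: Sequence[FusedPlant], cfg: SpacingConfig
) -> List[TransplantEvent]:
    """Apply the spacing/vision decision rules to one ridge, in travel order.

    Double-planting chains are collapsed first (proximity overrides the
    visual class); spacings are then re-derived between the collapsed
    elements, wide gaps emit interpolated missed points, and remaining
    plants are classified by their visual class.
    """
    if not ridge:
        raise ValueError("ridge must be non-empty")
    elements = _collapse_chains(ridge, cfg)
    events: List[TransplantEvent] = []
    prev: Optional[_Element] = None
    for el in elements:
        spacing = plane_distance(prev.plane, el.plane) if prev is not None else None
        if spacing is not None and spacing > cfg.high_mult * cfg.d_std:
            events.extend(_missed_points(prev.plane, prev.geo, el.plane, el.geo, cfg))
        if el.is_chain:
            status = TransplantStatus.DOUBLE_PLANTING
        else:
            status = _VISUAL_STATUS[el.members[0].cls]
        events.append(
            TransplantEvent(
                status=status,
                geo=el.geo,
                plane=el.plane,
                member_plant_ids=tuple(p.plant_id for p in el.members),
                spacing_before=spacing,
            )
        )
        prev = el
    return events


def assess_run(
    plants: Sequence[FusedPlant], cfg: SpacingConfig
) -> List[TransplantEvent]:
    """Split a run into ridges and classify each, concatenated in travel order."""
    events: List[TransplantEvent] = []
    for ridge in split_ridges(plants, cfg):
        events.extend(classify_ridge(ridge, cfg))
    return events
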