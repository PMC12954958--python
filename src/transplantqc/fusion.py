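"""Fuse per-frame seedling detections with GNSS fixes into counted plants.

A downward-looking camera rides along the ridge centreline; each physical
seedling sweeps through the frame as the platform advances.  Counting works
by (1) linking per-frame detections into short tracks with greedy IoU
association, (2) recording one crossing event per track when the box centre
passes a configurable counting line, and (3) assigning each crossing the
GNSS position interpolated at the crossing timestamp.  A seedling is thus
counted exactly once, at the moment it sits under the camera, with the
platform's own position standing in for the plant's.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Sequence, Tuple

from .geodesy import GeoPoint, PlanePoint, ProjectionConfig, lonlat_to_plane

__all__ = [
    "SeedlingClass",
    "FixQuality",
    "DetectionRecord",
    "GnssFix",
    "FusedPlant",
    "CrossingConfig",
    "SynchronizationError",
    "link_tracks",
    "count_crossings",
    "interpolate_fix",
    "fuse_run",
]


class SeedlingClass(str, Enum):
    """Visual detector classes."""

    NORMAL = "normal"
    BURIED = "buried"
    EXPOSED_ROOT = "exposed_root"


class FixQuality(str, Enum):
    FIX = "fix"
    FLOAT = "float"
    SINGLE = "single"
    NONE = "none"


@dataclass(frozen=True)
class DetectionRecord:
    """One per-frame sighting of a seedling.

    ``bbox`` is ``(xmin, ymin, xmax, ymax)`` in pixels, 0-based,
    x-right / y-down.
    """

    frame_index: int
    timestamp: float
    cls: SeedlingClass
    bbox: Tuple[float, float, float, float]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmin < xmax and ymin < ymax):
            raise ValueError(f"degenerate bbox: {self.bbox}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {self.confidence}")

    @property
    def center(self) -> Tuple[float, float]:
        xmin, ymin, xmax, ymax = self.bbox
        return ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0)


@dataclass(frozen=True)
class GnssFix:
    timestamp: float
    position: GeoPoint
    quality: FixQuality = FixQuality.FIX


@dataclass(frozen=True)
class FusedPlant:
    """A counted seedling: crossing time, class, and fused position."""

    plant_id: int
    timestamp: float
    cls: SeedlingClass
    geo: GeoPoint
    plane: PlanePoint


class Axis(str, Enum):
    #: counting line is horizontal; the box centre's *y* coordinate crosses it
    HORIZONTAL_LINE = "horizontal_line"
    #: counting line is vertical; the box centre's *x* coordinate crosses it
    VERTICAL_LINE = "vertical_line"


class Direction(str, Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    ANY = "any"


@dataclass
class CrossingConfig:
    """Counting-line geometry and track association parameters."""

    axis: Axis = Axis.HORIZONTAL_LINE
    line_position: float = 540.0  # half of the default 1080-pixel image height
    direction: Direction = Direction.ANY
    iou_link_threshold: float = 0.3
    max_frame_gap: int = 2
    max_gnss_gap: float = 1.0
    image_size: Tuple[int, int] = (1920, 1080)  # (width, height)
    #: class at counting time: majority over the track, or the crossing frame
    track_majority_class: bool = True

    def __post_init__(self) -> None:
        extent = self.image_size[1] if self.axis is Axis.HORIZONTAL_LINE else self.image_size[0]
        if not 0 < self.line_position < extent:
            raise ValueError(
                f"line_position {self.line_position} outside image extent {extent}"
            )


class SynchronizationError(RuntimeError):
    """GNSS stream cannot supply a position for a requested timestamp."""


def _iou(a: Tuple[float, float, float, float], b: Tuple[float, float, float, float]) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def link_tracks(
    stream: Sequence[DetectionRecord], cfg: CrossingConfig
) -> List[List[DetectionRecord]]:
    """Greedy frame-to-frame IoU association of detections into tracks.

    Detections in consecutive (within ``max_frame_gap``) frames are linked
    to the open track whose last box overlaps most, provided IoU is at
    least ``iou_link_threshold``; unmatched detections start new tracks.
    """
    last_frame = None
    for det in stream:
        if last_frame is not None and det.frame_index < last_frame:
            raise ValueError("detection stream must be sorted by frame_index")
        last_frame = det.frame_index

    tracks: List[List[DetectionRecord]] = []
    open_tracks: List[List[DetectionRecord]] = []

    # group detections by frame
    by_frame: dict[int, List[DetectionRecord]] = {}
    for det in stream:
        by_frame.setdefault(det.frame_index, []).append(det)

    for frame in sorted(by_frame):
        dets = by_frame[frame]
        # retire stale tracks
        still_open = []
        for tr in open_tracks:
            if frame - tr[-1].frame_index <= cfg.max_frame_gap:
                still_open.append(tr)
        open_tracks = still_open

        # greedy matching by descending IoU
        candidates = []
        for ti, tr in enumerate(open_tracks):
            for di, det in enumerate(dets):
                iou = _iou(tr[-1].bbox, det.bbox)
                if iou >= cfg.iou_link_threshold:
                    candidates.append((iou, ti, di))
        candidates.sort(key=lambda c: -c[0])
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for iou, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            open_tracks[ti].append(dets[di])
            used_tracks.add(ti)
            used_dets.add(di)
        for di, det in enumerate(dets):
            if di not in used_dets:
                tr = [det]
                open_tracks.append(tr)
                tracks.append(tr)

    return tracks


def _center_coord(det: DetectionRecord, cfg: CrossingConfig) -> float:
    cx, cy = det.center
    return cy if cfg.axis is Axis.HORIZONTAL_LINE else cx


def count_crossings(
    tracks: Iterable[Sequence[DetectionRecord]], cfg: CrossingConfig
) -> List[Tuple[float, SeedlingClass]]:
    """Emit at most one (timestamp, class) counting event per track.

    The event fires at the first consecutive frame pair where the box
    centre moves from one side of the counting line to the other (in the
    configured direction); its timestamp is the later frame's.  Further
    oscillations of the same track are debounced — one plant, one count.
    """
    events: List[Tuple[float, SeedlingClass]] = []
    for track in tracks:
        crossing = None
        for prev, cur in zip(track, track[1:]):
            a = _center_coord(prev, cfg)
            b = _center_coord(cur, cfg)
            crossed_up = a < cfg.line_position <= b
            crossed_down = a >= cfg.line_position > b
            if cfg.direction is Direction.INCREASING:
                hit = crossed_up
            elif cfg.direction is Direction.DECREASING:
                hit = crossed_down
            else:
                hit = crossed_up or crossed_down
            if hit:
                crossing = cur
                break
        if crossing is None:
            continue
        if cfg.track_majority_class:
            counts = Counter(det.cls for det in track)
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                cls = crossing.cls  # tie → class of the crossing frame
            else:
                cls = top[0][0]
        else:
            cls = crossing.cls
        events.append((crossing.timestamp, cls))
    events.sort(key=lambda e: e[0])
    return events


def interpolate_fix(fixes: Sequence[GnssFix], t: float, max_gap: float = 1.0) -> GeoPoint:
    """Position at time ``t`` by linear interpolation between bracketing fixes.

    Outside the fix span, the nearest fix is used if within ``max_gap``
    seconds; otherwise a :class:`SynchronizationError` is raised.
    Interpolation is linear in degrees — adequate over short gaps at
    walking speeds.
    """
    if not fixes:
        raise SynchronizationError(f"no GNSS fixes available for t={t}")
    if t <= fixes[0].timestamp:
        if fixes[0].timestamp - t > max_gap:
            raise SynchronizationError(
                f"t={t} precedes first fix by more than {max_gap}s"
            )
        return fixes[0].position
    if t >= fixes[-1].timestamp:
        if t - fixes[-1].timestamp > max_gap:
            raise SynchronizationError(
                f"t={t} trails last fix by more than {max_gap}s"
            )
        return fixes[-1].position
    # binary search for the bracketing pair
    lo, hi = 0, len(fixes) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fixes[mid].timestamp <= t:
            lo = mid
        else:
            hi = mid
    a, b = fixes[lo], fixes[hi]
    if b.timestamp - a.timestamp > max_gap:
        raise SynchronizationError(
            f"bracketing GNSS gap {b.timestamp - a.timestamp:.3f}s exceeds {max_gap}s at t={t}"
        )
    if b.timestamp == a.timestamp:
        return a.position
    w = (t - a.timestamp) / (b.timestamp - a.timestamp)
    return GeoPoint(
        latitude=a.position.latitude + w * (b.position.latitude - a.position.latitude),
        longitude=a.position.longitude + w * (b.position.longitude - a.position.longitude),
    )


def fuse_run(
    detections: Sequence[DetectionRecord],
    fixes: Sequence[GnssFix],
    cfg: CrossingConfig,
    proj: ProjectionConfig,
) -> List[FusedPlant]:
    """Full fusion: tracks → counting events → geolocated plants.

    Returns one :class:`FusedPlant` per counted seedling, in crossing-time
    order with consecutive ``plant_id``.  An empty detection stream yields
    an empty list.
    """
    if not detections:
        return []
    tracks = link_tracks(detections, cfg)
    events = count_crossings(tracks, cfg)
    plants: List[FusedPlant] = []
    for pid, (t, cls) in enumerate(events):
        geo = interpolate_fix(fixes, t, cfg.max_gnss_gap)
        plants.append(
            FusedPlant(
                plant_id=pid,
                timestamp=t,
                cls=cls,
                geo=geo,
                plane=lonlat_to_plane(geo, proj),
            )
        )
    return plants
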