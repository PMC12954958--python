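"""Synthetic transplanting runs: layouts, anomalies, and sensor streams.

The simulator emulates an inspection platform driving along ridge
centrelines: plants sit at a nominal in-row spacing with small jitter,
per-point anomalies are injected (missed, double, buried, exposed-root),
GNSS fixes are emitted with Gaussian noise while a virtual camera produces
per-frame bounding-box detections whose boxes sweep through the frame as
the platform passes each plant.  Every pipeline stage downstream of a real
detector can thus be exercised without any image data.

Determinism: each run uses one integer seed; the layout and sensor stages
draw from independent substreams derived from it, so identical seeds give
identical streams byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .assessment import TransplantStatus
from .fusion import (
    CrossingConfig,
    DetectionRecord,
    FixQuality,
    GnssFix,
    SeedlingClass,
)
from .geodesy import DEFAULT_LAT_COEFF, GeoPoint, ProjectionConfig

__all__ = [
    "FieldSpec",
    "AnomalyRates",
    "SensorModel",
    "TruthPoint",
    "PhysicalPlant",
    "GroundTruth",
    "generate_layout",
    "render_streams",
    "simulate_run",
    "projection_for",
    "PRESETS",
]

_CLASS_INDEX = {
    SeedlingClass.NORMAL: 0,
    SeedlingClass.BURIED: 1,
    SeedlingClass.EXPOSED_ROOT: 2,
}
_INDEX_CLASS = {v: k for k, v in _CLASS_INDEX.items()}


@dataclass
class FieldSpec:
    """Geometry of a trial plot: ridges of plants at nominal spacing."""

    n_ridges: int = 10
    plants_per_ridge: int = 21
    d_std: float = 0.5
    ridge_gap: float = 1.2
    origin: GeoPoint = field(default_factory=lambda: GeoPoint(24.64190, 102.92841))
    azimuth_theta: float = 0.0
    serpentine: bool = True
    #: along-row position jitter, metres (σ); small relative to the normal band
    jitter_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.n_ridges < 1 or self.plants_per_ridge < 1:
            raise ValueError("counts must be ≥ 1")
        if self.d_std <= 0:
            raise ValueError("d_std must be positive")

    @property
    def n_points(self) -> int:
        return self.n_ridges * self.plants_per_ridge


@dataclass
class AnomalyRates:
    """Per-planting-point anomaly probabilities."""

    p_miss: float = 0.0
    p_double: float = 0.0
    p_bury: float = 0.0
    p_expose: float = 0.0

    def __post_init__(self) -> None:
        probs = (self.p_miss, self.p_double, self.p_bury, self.p_expose)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("rates must lie in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("anomaly rates must sum to ≤ 1")


def _identity_confusion() -> np.ndarray:
    return np.eye(3)


@dataclass
class SensorModel:
    """Sensor and detector error model.

    ``detect_prob`` is the probability that a physical plant is detected at
    all (a fully missed plant reproduces the missed-detection → missed-
    planting error path); ``frame_drop_prob`` drops individual detections
    within otherwise-detected tracks.  ``false_positive_rate`` injects, per
    planting point, a spurious detection track adjacent to a real plant
    (background mistaken for a seedling), reproducing the false-positive →
    double-planting error path.  ``confusion`` is a row-stochastic matrix
    over (normal, buried, exposed_root); the observed class of each plant
    is drawn from it once per plant and reported consistently across the
    plant's frames.
    """

    gnss_sigma: float = 0.01  # metres per axis; survey-grade RTK class
    gnss_rate: float = 10.0  # Hz
    frame_rate: float = 30.0  # Hz
    speed: float = 0.5  # m/s, typical transplanter speed
    detect_prob: float = 1.0
    frame_drop_prob: float = 0.0
    false_positive_rate: float = 0.0
    confusion: np.ndarray = field(default_factory=_identity_confusion)
    seed: int = 0
    #: pixels of image travel per metre of ground travel
    px_per_m: float = 2160.0
    box_w: float = 140.0
    box_h: float = 120.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.confusion.shape != (3, 3):
            raise ValueError("confusion must be 3×3")
        if not np.allclose(self.confusion.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("confusion rows must sum to 1")


@dataclass(frozen=True)
class TruthPoint:
    """Status and position of one theoretical planting point."""

    status: TransplantStatus
    geo: GeoPoint
    enu: Tuple[float, float]  # metres east/north of the field origin
    ridge: int
    index: int  # position along the ridge


@dataclass(frozen=True)
class PhysicalPlant:
    """One seedling actually present in the field."""

    geo: GeoPoint
    enu: Tuple[float, float]
    cls: SeedlingClass
    ridge: int
    s: float  # along-ridge coordinate, metres


@dataclass
class GroundTruth:
    field_spec: FieldSpec
    points: List[TruthPoint]
    plants: List[PhysicalPlant]


def projection_for(fs: FieldSpec, lat_coeff: float = DEFAULT_LAT_COEFF) -> ProjectionConfig:
    """Projection config consistent with a simulated field's origin."""
    return ProjectionConfig(
        ref_lat=fs.origin.latitude,
        lat_coeff=lat_coeff,
        origin=fs.origin,
        azimuth_theta=fs.azimuth_theta,
    )


def _enu_to_geo(east: float, north: float, fs: FieldSpec) -> GeoPoint:
    m_per_deg_lon = DEFAULT_LAT_COEFF * math.cos(math.radians(fs.origin.latitude))
    return GeoPoint(
        latitude=fs.origin.latitude + north / DEFAULT_LAT_COEFF,
        longitude=fs.origin.longitude + east / m_per_deg_lon,
    )


def _ridge_frame(fs: FieldSpec) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Unit vectors (east, north): along-ridge and across-ridge (to the right)."""
    th = math.radians(fs.azimuth_theta)
    along = (math.sin(th), math.cos(th))
    across = (math.cos(th), -math.sin(th))
    return along, across


def generate_layout(fs: FieldSpec, rates: AnomalyRates, seed: int = 0) -> GroundTruth:
    """Place plants along ridges and inject per-point anomalies.

    A missed point removes its plant; a double point adds a second plant at
    an along-row offset drawn uniformly from (0.1, 0.35)·d_std — strictly
    inside the double-planting band; burial/exposure change the plant's
    visual class only.
    """
    rng = np.random.default_rng([seed, 0])
    along, across = _ridge_frame(fs)
    points: List[TruthPoint] = []
    plants: List[PhysicalPlant] = []
    cum = np.cumsum([rates.p_miss, rates.p_double, rates.p_bury, rates.p_expose])
    for r in range(fs.n_ridges):
        off = r * fs.ridge_gap
        for k in range(fs.plants_per_ridge):
            s = k * fs.d_std + rng.normal(0.0, fs.jitter_sigma)
            east = along[0] * s + across[0] * off
            north = along[1] * s + across[1] * off
            geo = _enu_to_geo(east, north, fs)
            u = rng.uniform()
            if u < cum[0]:
                status = TransplantStatus.MISSED_PLANTING
            elif u < cum[1]:
                status = TransplantStatus.DOUBLE_PLANTING
            elif u < cum[2]:
                status = TransplantStatus.SEEDLING_BURIAL
            elif u < cum[3]:
                status = TransplantStatus.ROOT_EXPOSURE
            else:
                status = TransplantStatus.NORMAL
            points.append(TruthPoint(status=status, geo=geo, enu=(east, north), ridge=r, index=k))
            if status is TransplantStatus.MISSED_PLANTING:
                continue
            cls = {
                TransplantStatus.SEEDLING_BURIAL: SeedlingClass.BURIED,
                TransplantStatus.ROOT_EXPOSURE: SeedlingClass.EXPOSED_ROOT,
            }.get(status, SeedlingClass.NORMAL)
            plants.append(PhysicalPlant(geo=geo, enu=(east, north), cls=cls, ridge=r, s=s))
            if status is TransplantStatus.DOUBLE_PLANTING:
                ds = rng.uniform(0.1, 0.35) * fs.d_std
                s2 = s + ds
                e2 = along[0] * s2 + across[0] * off
                n2 = along[1] * s2 + across[1] * off
                plants.append(
                    PhysicalPlant(
                        geo=_enu_to_geo(e2, n2, fs),
                        enu=(e2, n2),
                        cls=SeedlingClass.NORMAL,
                        ridge=r,
                        s=s2,
                    )
                )
    return GroundTruth(field_spec=fs, points=points, plants=plants)


@dataclass
class _Segment:
    """A straight piece of the vehicle path."""

    t_start: float
    t_end: float
    p_start: Tuple[float, float]
    p_end: Tuple[float, float]
    ridge: int | None  # None for headland transit

    def position(self, t: float) -> Tuple[float, float]:
        if self.t_end == self.t_start:
            return self.p_start
        w = (t - self.t_start) / (self.t_end - self.t_start)
        return (
            self.p_start[0] + w * (self.p_end[0] - self.p_start[0]),
            self.p_start[1] + w * (self.p_end[1] - self.p_start[1]),
        )


def _vehicle_path(fs: FieldSpec, speed: float, t0: float, lead: float = 1.0) -> List[_Segment]:
    along, across = _ridge_frame(fs)
    length = (fs.plants_per_ridge - 1) * fs.d_std

    def enu(s: float, r: int) -> Tuple[float, float]:
        off = r * fs.ridge_gap
        return (along[0] * s + across[0] * off, along[1] * s + across[1] * off)

    segments: List[_Segment] = []
    t = t0
    prev_end: Tuple[float, float] | None = None
    for r in range(fs.n_ridges):
        reverse = fs.serpentine and (r % 2 == 1)
        s_a, s_b = (length + lead, -lead) if reverse else (-lead, length + lead)
        p_a, p_b = enu(s_a, r), enu(s_b, r)
        if prev_end is not None:
            d = math.dist(prev_end, p_a)
            segments.append(_Segment(t, t + d / speed, prev_end, p_a, ridge=None))
            t += d / speed
        d = math.dist(p_a, p_b)
        segments.append(_Segment(t, t + d / speed, p_a, p_b, ridge=r))
        t += d / speed
        prev_end = p_b
    return segments


def render_streams(
    gt: GroundTruth,
    sensors: SensorModel,
    crossing_cfg: CrossingConfig | None = None,
) -> Tuple[List[DetectionRecord], List[GnssFix]]:
    """Simulate the camera and GNSS streams for a ground-truth layout.

    Each detected plant yields a track of bounding boxes whose centres
    sweep through the counting line exactly when the platform passes the
    plant, so crossing-time GNSS interpolation recovers the plant position.
    """
    cfg = crossing_cfg or CrossingConfig()
    fs = gt.field_spec
    rng = np.random.default_rng([sensors.seed, 1])
    segments = _vehicle_path(fs, sensors.speed, sensors.t0)
    t_end = segments[-1].t_end

    # ---- GNSS fixes over the whole path
    fixes: List[GnssFix] = []
    n_fix = int(math.floor((t_end - sensors.t0) * sensors.gnss_rate)) + 1
    seg_i = 0
    for i in range(n_fix):
        t = sensors.t0 + i / sensors.gnss_rate
        while seg_i < len(segments) - 1 and t > segments[seg_i].t_end:
            seg_i += 1
        e, n = segments[seg_i].position(t)
        e += rng.normal(0.0, sensors.gnss_sigma)
        n += rng.normal(0.0, sensors.gnss_sigma)
        fixes.append(
            GnssFix(timestamp=t, position=_enu_to_geo(e, n, fs), quality=FixQuality.FIX)
        )

    # ---- plant crossing times, in traversal order
    img_w, img_h = cfg.image_size
    line = cfg.line_position
    # boxes are emitted only while fully inside the frame
    extent = img_h if cfg.axis.value == "horizontal_line" else img_w
    span_px = min(line, extent - line) - sensors.box_h / 2.0
    vis_half_m = max(span_px, sensors.box_h) / sensors.px_per_m
    vis_half_t = vis_half_m / sensors.speed

    @dataclass
    class _TrackPlan:
        t_cross: float
        cls: SeedlingClass
        cx: float

    plans: List[_TrackPlan] = []
    for seg in segments:
        if seg.ridge is None:
            continue
        seg_len = math.dist(seg.p_start, seg.p_end)
        ridge_plants = [p for p in gt.plants if p.ridge == seg.ridge]
        for p in ridge_plants:
            # distance of the plant from the segment start, along travel
            d_along = (
                (p.enu[0] - seg.p_start[0]) * (seg.p_end[0] - seg.p_start[0])
                + (p.enu[1] - seg.p_start[1]) * (seg.p_end[1] - seg.p_start[1])
            ) / seg_len
            t_cross = seg.t_start + d_along / sensors.speed
            detected = rng.uniform() < sensors.detect_prob
            obs_idx = rng.choice(3, p=sensors.confusion[_CLASS_INDEX[p.cls]])
            cx = 960.0 + rng.uniform(-50.0, 50.0)
            if detected:
                plans.append(_TrackPlan(t_cross, _INDEX_CLASS[int(obs_idx)], cx))
            if rng.uniform() < sensors.false_positive_rate:
                # background mistaken for a seedling right next to a real plant
                dt = rng.uniform(0.15, 0.35) * fs.d_std / sensors.speed
                plans.append(
                    _TrackPlan(t_cross + dt, SeedlingClass.NORMAL, 960.0 + rng.uniform(-50.0, 50.0))
                )

    # ---- detections per plan, by global frame clock
    detections: List[DetectionRecord] = []
    for plan in plans:
        f_lo = int(math.ceil((plan.t_cross - vis_half_t - sensors.t0) * sensors.frame_rate))
        f_hi = int(math.floor((plan.t_cross + vis_half_t - sensors.t0) * sensors.frame_rate))
        for f in range(max(f_lo, 0), f_hi + 1):
            t = sensors.t0 + f / sensors.frame_rate
            if sensors.frame_drop_prob > 0.0 and rng.uniform() < sensors.frame_drop_prob:
                continue
            c_line = line + sensors.px_per_m * (t - plan.t_cross) * sensors.speed
            if cfg.axis.value == "horizontal_line":
                cx, cy = plan.cx, c_line
            else:
                cx, cy = c_line, 540.0
            xmin, xmax = cx - sensors.box_w / 2.0, cx + sensors.box_w / 2.0
            ymin, ymax = cy - sensors.box_h / 2.0, cy + sensors.box_h / 2.0
            if xmin < 0 or ymin < 0 or xmax > img_w or ymax > img_h:
                continue
            detections.append(
                DetectionRecord(
                    frame_index=f,
                    timestamp=t,
                    cls=plan.cls,
                    bbox=(xmin, ymin, xmax, ymax),
                    confidence=float(np.clip(rng.normal(0.85, 0.05), 0.3, 1.0)),
                )
            )
    detections.sort(key=lambda d: (d.frame_index, d.bbox[0], d.bbox[1]))
    return detections, fixes


def simulate_run(
    fs: FieldSpec,
    rates: AnomalyRates | None = None,
    sensors: SensorModel | None = None,
    crossing_cfg: CrossingConfig | None = None,
    seed: int = 0,
) -> Tuple[GroundTruth, List[DetectionRecord], List[GnssFix]]:
    """Convenience wrapper: layout + streams with one seed."""
    rates = rates or AnomalyRates()
    sensors = sensors or SensorModel()
    sensors.seed = seed
    gt = generate_layout(fs, rates, seed=seed)
    detections, fixes = render_streams(gt, sensors, crossing_cfg)
    return gt, detections, fixes


#: Trial-plot shapes matching the two validation fields: a 10-ridge plot of
#: 21 plants each (210 points) and an 8-ridge plot of 48 plants each (384).
PRESETS = {
    "chengjiang-like": FieldSpec(n_ridges=10, plants_per_ridge=21),
    "mile-like": FieldSpec(n_ridges=8, plants_per_ridge=48),
}
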