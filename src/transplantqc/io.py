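"""Readers and writers for the stream formats shared across modules.

Canonical on-disk formats:

* detections — JSONL (keys ``frame``, ``t``, ``cls``, ``bbox``, ``conf``)
  or CSV with the same fields;
* GNSS fixes — CSV (``t``, ``lat``, ``lon``, ``quality``) or a minimal
  NMEA-RMC subset (timestamp, lat/lon with hemisphere, status A/V);
* fused plants, events, ground truth, summaries — CSV; events and routes
  also as GeoJSON; twin messages as JSONL.

Readers validate each record and reject malformed input with the line
number rather than silently coercing it.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import yaml

from .assessment import TWIN_STATE, TransplantEvent, TransplantStatus
from .fusion import (
    DetectionRecord,
    FixQuality,
    FusedPlant,
    GnssFix,
    SeedlingClass,
)
from .geodesy import GeoPoint
from .reporting import STATUS_ORDER, StatusSummary
from .simulator import GroundTruth

__all__ = [
    "ParseError",
    "write_detections_jsonl",
    "read_detections_jsonl",
    "write_detections_csv",
    "read_detections_csv",
    "write_fixes_csv",
    "read_fixes_csv",
    "read_nmea_rmc",
    "write_nmea_rmc",
    "write_fused_csv",
    "write_events_csv",
    "read_events_csv",
    "events_to_geojson",
    "write_events_geojson",
    "write_ground_truth_csv",
    "read_truth_points_csv",
    "route_to_geojson",
    "write_summary_json",
    "write_summary_csv",
    "load_config",
]


class ParseError(ValueError):
    """Malformed input record; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


# --------------------------------------------------------------------------
# detections


def write_detections_jsonl(path, detections: Sequence[DetectionRecord]) -> None:
    with open(path, "w") as fh:
        for d in detections:
            fh.write(
                json.dumps(
                    {
                        "frame": d.frame_index,
                        "t": round(d.timestamp, 6),
                        "cls": d.cls.value,
                        "bbox": [round(v, 3) for v in d.bbox],
                        "conf": round(d.confidence, 4),
                    }
                )
                + "\n"
            )


def read_detections_jsonl(path) -> List[DetectionRecord]:
    out: List[DetectionRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                out.append(
                    DetectionRecord(
                        frame_index=int(obj["frame"]),
                        timestamp=float(obj["t"]),
                        cls=SeedlingClass(obj["cls"]),
                        bbox=tuple(float(v) for v in obj["bbox"]),
                        confidence=float(obj["conf"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(path, line_no, f"bad detection record: {exc}") from exc
    return out


_DET_FIELDS = ["frame", "t", "cls", "xmin", "ymin", "xmax", "ymax", "conf"]


def write_detections_csv(path, detections: Sequence[DetectionRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_DET_FIELDS)
        for d in detections:
            w.writerow(
                [d.frame_index, f"{d.timestamp:.6f}", d.cls.value]
                + [f"{v:.3f}" for v in d.bbox]
                + [f"{d.confidence:.4f}"]
            )


def read_detections_csv(path) -> List[DetectionRecord]:
    out: List[DetectionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            try:
                out.append(
                    DetectionRecord(
                        frame_index=int(row["frame"]),
                        timestamp=float(row["t"]),
                        cls=SeedlingClass(row["cls"]),
                        bbox=(
                            float(row["xmin"]),
                            float(row["ymin"]),
                            float(row["xmax"]),
                            float(row["ymax"]),
                        ),
                        confidence=float(row["conf"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(path, line_no, f"bad detection row: {exc}") from exc
    return out


# --------------------------------------------------------------------------
# GNSS fixes


def write_fixes_csv(path, fixes: Sequence[GnssFix]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "lat", "lon", "quality"])
        for f in fixes:
            w.writerow(
                [
                    f"{f.timestamp:.6f}",
                    f"{f.position.latitude:.9f}",
                    f"{f.position.longitude:.9f}",
                    f.quality.value,
                ]
            )


def read_fixes_csv(path) -> List[GnssFix]:
    out: List[GnssFix] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            try:
                out.append(
                    GnssFix(
                        timestamp=float(row["t"]),
                        position=GeoPoint(float(row["lat"]), float(row["lon"])),
                        quality=FixQuality(row["quality"]),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(path, line_no, f"bad fix row: {exc}") from exc
    return out


def _dm_to_deg(dm: str, hemi: str, is_lat: bool) -> float:
    # NMEA packs degrees and minutes together: ddmm.mmmm / dddmm.mmmm
    width = 2 if is_lat else 3
    if len(dm.split(".")[0]) < width + 2:
        raise ValueError(f"coordinate field too short: {dm!r}")
    deg = float(dm[:width])
    minutes = float(dm[width:])
    val = deg + minutes / 60.0
    if hemi in ("S", "W"):
        val = -val
    elif hemi not in ("N", "E"):
        raise ValueError(f"bad hemisphere {hemi!r}")
    return val


def read_nmea_rmc(path) -> List[GnssFix]:
    """Minimal NMEA-RMC reader: UTC timestamp, position, status A/V."""
    out: List[GnssFix] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if not line.startswith("$") or "RMC" not in line.split(",")[0]:
                raise ParseError(path, line_no, f"not an RMC sentence: {line[:20]!r}")
            body = line[1:].split("*")[0]
            fields = body.split(",")
            try:
                if len(fields) < 10:
                    raise ValueError("too few fields")
                hhmmss, status = fields[1], fields[2]
                lat = _dm_to_deg(fields[3], fields[4], is_lat=True)
                lon = _dm_to_deg(fields[5], fields[6], is_lat=False)
                ddmmyy = fields[9]
                dt = datetime.strptime(
                    f"{ddmmyy} {hhmmss.split('.')[0]}", "%d%m%y %H%M%S"
                ).replace(tzinfo=timezone.utc)
                frac = float("0." + hhmmss.split(".")[1]) if "." in hhmmss else 0.0
                t = dt.timestamp() + frac
                quality = FixQuality.FIX if status == "A" else FixQuality.NONE
                out.append(GnssFix(timestamp=t, position=GeoPoint(lat, lon), quality=quality))
            except (ValueError, IndexError) as exc:
                raise ParseError(path, line_no, f"bad RMC sentence: {exc}") from exc
    return out


def _deg_to_dm(value: float, is_lat: bool) -> Tuple[str, str]:
    hemi = ("N" if value >= 0 else "S") if is_lat else ("E" if value >= 0 else "W")
    v = abs(value)
    deg = int(v)
    minutes = (v - deg) * 60.0
    width = 2 if is_lat else 3
    return f"{deg:0{width}d}{minutes:07.4f}", hemi


def write_nmea_rmc(path, fixes: Sequence[GnssFix]) -> None:
    with open(path, "w") as fh:
        for f in fixes:
            dt = datetime.fromtimestamp(f.timestamp, tz=timezone.utc)
            frac = f.timestamp - int(f.timestamp)
            hhmmss = dt.strftime("%H%M%S") + f".{int(round(frac * 100)):02d}"
            lat, ns = _deg_to_dm(f.position.latitude, True)
            lon, ew = _deg_to_dm(f.position.longitude, False)
            status = "A" if f.quality is not FixQuality.NONE else "V"
            body = f"GPRMC,{hhmmss},{status},{lat},{ns},{lon},{ew},0.0,0.0,{dt.strftime('%d%m%y')},,"
            cs = 0
            for ch in body:
                cs ^= ord(ch)
            fh.write(f"${body}*{cs:02X}\n")


# --------------------------------------------------------------------------
# fused plants, events, ground truth


def write_fused_csv(path, plants: Sequence[FusedPlant]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plant_id", "t", "cls", "lat", "lon", "x", "y"])
        for p in plants:
            w.writerow(
                [
                    p.plant_id,
                    f"{p.timestamp:.6f}",
                    p.cls.value,
                    f"{p.geo.latitude:.9f}",
                    f"{p.geo.longitude:.9f}",
                    f"{p.plane.x:.4f}",
                    f"{p.plane.y:.4f}",
                ]
            )


def write_events_csv(path, events: Sequence[TransplantEvent]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["status", "lat", "lon", "x", "y", "spacing_before", "member_ids"])
        for e in events:
            w.writerow(
                [
                    e.status.value,
                    f"{e.geo.latitude:.9f}",
                    f"{e.geo.longitude:.9f}",
                    f"{e.plane.x:.4f}",
                    f"{e.plane.y:.4f}",
                    "" if e.spacing_before is None else f"{e.spacing_before:.4f}",
                    ";".join(str(i) for i in e.member_plant_ids),
                ]
            )


def read_events_csv(path) -> List[TransplantEvent]:
    from .geodesy import PlanePoint

    out: List[TransplantEvent] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            try:
                members = tuple(
                    int(i) for i in row["member_ids"].split(";") if i != ""
                )
                spacing = row["spacing_before"]
                out.append(
                    TransplantEvent(
                        status=TransplantStatus(row["status"]),
                        geo=GeoPoint(float(row["lat"]), float(row["lon"])),
                        plane=PlanePoint(float(row["x"]), float(row["y"])),
                        member_plant_ids=members,
                        spacing_before=None if spacing == "" else float(spacing),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(path, line_no, f"bad event row: {exc}") from exc
    return out


def events_to_geojson(events: Sequence[TransplantEvent]) -> dict:
    features = []
    for e in events:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [e.geo.longitude, e.geo.latitude],
                },
                "properties": {
                    "state": TWIN_STATE[e.status],
                    "members": list(e.member_plant_ids),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_events_geojson(path, events: Sequence[TransplantEvent]) -> None:
    with open(path, "w") as fh:
        json.dump(events_to_geojson(events), fh, indent=1)


def write_ground_truth_csv(path, gt: GroundTruth) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ridge", "index", "status", "lat", "lon", "east", "north"])
        for p in gt.points:
            w.writerow(
                [
                    p.ridge,
                    p.index,
                    p.status.value,
                    f"{p.geo.latitude:.9f}",
                    f"{p.geo.longitude:.9f}",
                    f"{p.enu[0]:.4f}",
                    f"{p.enu[1]:.4f}",
                ]
            )


def read_truth_points_csv(path) -> List[Tuple[TransplantStatus, GeoPoint]]:
    out: List[Tuple[TransplantStatus, GeoPoint]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            try:
                out.append(
                    (
                        TransplantStatus(row["status"]),
                        GeoPoint(float(row["lat"]), float(row["lon"])),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(path, line_no, f"bad truth row: {exc}") from exc
    return out


# --------------------------------------------------------------------------
# routes and summaries


def route_to_geojson(route) -> dict:
    coords = [[e.geo.longitude, e.geo.latitude] for e in route.stops]
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "total_length_m": route.total_length,
                    "n_stops": len(route.stops),
                },
            }
        ],
    }


def write_summary_json(path, summary: StatusSummary, inference=None, abnormality=None) -> None:
    payload: dict = {"summary": summary.as_dict()}
    if inference is not None:
        payload["inference"] = inference.as_dict()
    if abnormality is not None:
        payload["abnormality_rate_pct"] = abnormality
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_summary_csv(path, summary: StatusSummary) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["status", "ground_truth", "assessed", "correct", "accuracy_pct"])
        for status in STATUS_ORDER:
            r = summary.rows[status]
            w.writerow([status.value, r.ground_truth, r.assessed, r.correct, r.accuracy])
        t = summary.total
        w.writerow(["total", t.ground_truth, t.assessed, t.correct, t.accuracy])


# --------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "origin_lat",
    "origin_lon",
    "azimuth_theta_deg",
    "ref_lat",
    "x_off",
    "z_off",
    "lat_coeff",
    "d_std",
    "low_mult",
    "high_mult",
    "ridge_break_mult",
    "line_position",
    "iou_link_threshold",
    "max_frame_gap",
    "max_gnss_gap",
    "seed",
}


def load_config(path) -> Dict[str, float]:
    """Load a YAML key–value run config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(path, 1, "config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ParseError(path, 1, f"unknown config keys: {sorted(unknown)}")
    return data
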