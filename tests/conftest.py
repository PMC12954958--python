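"""Shared fixtures: synthetic plant sequences and simulated runs."""

from __future__ import annotations

from typing import List, Optional, Sequence

import pytest

from transplantqc import (
    AnomalyRates,
    CrossingConfig,
    FieldSpec,
    FusedPlant,
    GeoPoint,
    ProjectionConfig,
    SeedlingClass,
    SensorModel,
    SpacingConfig,
    simulate_run,
)
from transplantqc.geodesy import PlanePoint, plane_to_lonlat
from transplantqc.simulator import projection_for


@pytest.fixture
def proj() -> ProjectionConfig:
    return ProjectionConfig(ref_lat=24.6, origin=GeoPoint(24.6, 102.9))


def make_plants(
    spacings: Sequence[float],
    classes: Optional[Sequence[SeedlingClass]] = None,
    d_std: float = 0.5,
    proj: Optional[ProjectionConfig] = None,
) -> List[FusedPlant]:
    """Plants along the x axis with the given consecutive spacings (in units
    of d_std); classes default to all normal."""
    proj = proj or ProjectionConfig(ref_lat=24.6, origin=GeoPoint(24.6, 102.9))
    n = len(spacings) + 1
    classes = list(classes) if classes else [SeedlingClass.NORMAL] * n
    assert len(classes) == n
    xs = [0.0]
    for s in spacings:
        xs.append(xs[-1] + s * d_std)
    plants = []
    for i, (x, cls) in enumerate(zip(xs, classes)):
        plane = PlanePoint(x, 0.0)
        plants.append(
            FusedPlant(
                plant_id=i,
                timestamp=float(i),
                cls=cls,
                geo=plane_to_lonlat(plane, proj),
                plane=plane,
            )
        )
    return plants


@pytest.fixture
def small_clean_run():
    """3 ridges × 15 plants, mixed anomalies, noise-free sensors."""
    fs = FieldSpec(n_ridges=3, plants_per_ridge=15)
    rates = AnomalyRates(p_miss=0.05, p_double=0.05, p_bury=0.05, p_expose=0.05)
    gt, dets, fixes = simulate_run(fs, rates, SensorModel(gnss_sigma=0.0), seed=7)
    return fs, gt, dets, fixes, projection_for(fs)


@pytest.fixture
def spacing_cfg() -> SpacingConfig:
    return SpacingConfig(d_std=0.5)
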