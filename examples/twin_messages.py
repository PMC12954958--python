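"""Digital-twin messages and scene-frame mapping.

Assesses a small simulated run, emits one JSON message per planting event
(the wire format consumed by the twin renderer), and maps event coordinates
into the ridge-aligned scene frame.
"""

from transplantqc import (
    AnomalyRates,
    CrossingConfig,
    FieldSpec,
    GeoPoint,
    ProjectionConfig,
    SpacingConfig,
    assess_run,
    fuse_run,
    geo_to_scene,
    simulate_run,
    twin_message_lines,
)
from transplantqc.simulator import projection_for

fs = FieldSpec(n_ridges=2, plants_per_ridge=10, azimuth_theta=30.0)
gt, dets, fixes = simulate_run(fs, AnomalyRates(p_bury=0.15), seed=9)
proj = projection_for(fs)
events = assess_run(fuse_run(dets, fixes, CrossingConfig(), proj), SpacingConfig())

print("twin message stream (first 5):")
for line in twin_message_lines(events)[:5]:
    print(" ", line)

scene_cfg = ProjectionConfig(origin=fs.origin, azimuth_theta=fs.azimuth_theta)
print("\nscene coordinates (ridge-aligned frame, metres):")
for e in events[:5]:
    s = geo_to_scene(e.geo, scene_cfg)
    print(f"  {e.status.value:>16}  X={s.X:7.2f}  Z={s.Z:7.2f}")
# With the scene rotated by the ridge azimuth, plants of one ridge share
# (nearly) constant X and advance along Z — the twin renders ridges upright.
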