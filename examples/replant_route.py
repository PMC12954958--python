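"""Cluster anomalies and plan a replanting route.

Simulates a run with a high miss rate, clusters the anomaly points with
DBSCAN, builds an open replanting path (nearest-neighbour + 2-opt), and
prints windowed machine compensation signals.
"""

from transplantqc import (
    AnomalyRates,
    CrossingConfig,
    FieldSpec,
    SpacingConfig,
    assess_run,
    cluster_anomalies,
    compensation_signals,
    fuse_run,
    replant_route,
    simulate_run,
)
from transplantqc.geodesy import PlanePoint
from transplantqc.simulator import projection_for

fs = FieldSpec(n_ridges=4, plants_per_ridge=30)
rates = AnomalyRates(p_miss=0.10, p_bury=0.08)
gt, dets, fixes = simulate_run(fs, rates, seed=5)
proj = projection_for(fs)
events = assess_run(fuse_run(dets, fixes, CrossingConfig(), proj), SpacingConfig())

clusters = cluster_anomalies(events, d_std=fs.d_std)
print(f"{sum(len(c.members) for c in clusters)} anomalies in {len(clusters)} clusters")
for i, c in enumerate(clusters):
    print(f"  cluster {i}: {len(c.members)} events, radius {c.radius:.2f} m")

start = PlanePoint(events[0].plane.x, events[0].plane.y)  # field entrance
route = replant_route(events, start)
print(f"replant route: {len(route.stops)} stops, {route.total_length:.1f} m walk")

signals = compensation_signals(events, d_std=fs.d_std, window=20)
kinds = {s.kind.value for s in signals}
print(f"compensation signals fired: {sorted(kinds) or 'none'}")
# raise_depth fires when >20 % of a 20-event window is buried seedlings —
# the planting mechanism is running too deep and should be raised.
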