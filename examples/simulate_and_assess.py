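"""Simulate a transplanting run and assess it end to end.

Generates a 10-ridge × 21-plant plot (the shape of a real validation
trial), injects anomalies at known rates, renders detection and GNSS
streams, fuses them into counted plants, classifies the five statuses, and
scores the result against the known ground truth.
"""

from collections import Counter

from transplantqc import (
    AnomalyRates,
    CrossingConfig,
    SensorModel,
    SpacingConfig,
    assess_run,
    evaluate_run,
    fuse_run,
    simulate_run,
    summary_accuracy,
    abnormality_rate,
)
from transplantqc.simulator import PRESETS, projection_for

fs = PRESETS["chengjiang-like"]  # 10 ridges × 21 plants = 210 points
rates = AnomalyRates(p_miss=0.06, p_double=0.03, p_bury=0.04, p_expose=0.04)
gt, detections, fixes = simulate_run(fs, rates, SensorModel(), seed=42)
print(f"{fs.n_points} theoretical points, {len(gt.plants)} physical plants")
print(f"{len(detections)} per-frame detections, {len(fixes)} GNSS fixes")

proj = projection_for(fs)
plants = fuse_run(detections, fixes, CrossingConfig(), proj)
events = assess_run(plants, SpacingConfig(d_std=fs.d_std))
print(f"{len(plants)} plants counted → {len(events)} classified events")
print("event statuses:", dict(Counter(e.status.value for e in events)))

summary = evaluate_run(events, gt, proj)
acc = summary_accuracy(summary)
print(f"overall accuracy vs ground truth: {acc['overall']} %")
print(f"abnormality rate: {abnormality_rate(summary):.2f} % of assessed events")
# Accuracy is the fraction of ground-truth points whose assessed status
# matches; the abnormality rate is the share of non-normal assessed events.
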