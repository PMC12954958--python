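# Methods

## Problem and model

A transplanting run is inspected by a platform moving along ridge
centrelines with a downward camera (1920×1080 px, 30 fps) and an RTK-GNSS
receiver (±1 cm horizontal class). A visual detector emits per-frame
bounding boxes labelled normal / buried / exposed-root. The package turns
those two streams into one classified event per planting point.

**Counting and fusion.** Detections are associated frame-to-frame by
greedy IoU (threshold 0.3, max frame gap 2). "Passing the centre of the
frame" is operationalized as the box centre crossing a single configurable
counting line (default: horizontal line at half image height, direction
agnostic); each track counts at most once (debounce), at the timestamp of
the later frame of the first crossing pair. The event class is the
majority class over the track, ties broken by the crossing frame — a
single-frame decision is available by config. GNSS position at the
crossing time is linearly interpolated in degrees between bracketing fixes
(error ≪ 1 cm over ≤ 1 s gaps at ≤ 1 m/s); since the camera sits over the
ridge line, the platform position at crossing time stands in for the plant
position.

**Projections.** Two flat-earth maps are kept deliberately distinct.
Spacing uses x = λ·111000·cos(ref_lat), y = φ·111000 (metres per degree
fixed at 111 000); the twin scene uses the equirectangular local tangent
plane with R = 6 378 137 m (≈ 111 319.49 m/°) rotated clockwise by the
ridge azimuth θ. The two constants differ by 0.29 %; both are exposed in
config, and each subsystem uses its own constant. Both maps are valid over
~1 km working areas only; no ellipsoidal corrections. ref_lat defaults to
the latitude of the first GNSS fix of the run. θ is configured in degrees
and converted internally.

**Decision rules.** Statuses are assigned in strict priority:
double planting, missed planting, burial, exposure, normal.

1. Maximal chains of consecutive plants whose successive spacings are all
   < 0.4·d_std collapse into one double-planting event at the arithmetic
   centroid of the members (proximity overrides the visual class; a buried
   plant inside a chain is not additionally reported). Spacings are then
   re-derived between collapsed elements, which prevents a chain from
   spuriously triggering a missed-planting gap.
2. A remaining gap d > 1.6·d_std emits n = max(1, round(d/d_std) − 1)
   missed-planting events at equal fractions along the gap. `round` is
   round-half-to-even and affects only knife-edge gaps. Geographic
   coordinates of interpolated points come from the same affine
   interpolation — exact, because the spacing projection is linear in
   (φ, λ).
3. Everything else keeps its visual class. Thresholds are inclusive:
   d = 0.4·d_std and d = 1.6·d_std are in the normal band. The first plant
   of a ridge has no predecessor spacing and is classified visually.

**Ridge segmentation.** A new ridge starts when consecutive spacing
exceeds 5·d_std or the step direction deviates from the current ridge's
running heading by more than 80°. The deviation form (rather than a
literal ">90° turn" between consecutive steps) is deliberate: in a
serpentine pass the headland step between ridge ends is *exactly*
perpendicular to travel, so a >90° rule sits on the boundary and resolves
by floating-point accident. At 80° the perpendicular step is a
deterministic break while in-row jitter (≲ 6° at the default noise) never
is.

**Validation statistics.** Events are matched to ground-truth points
greedily by distance within 0.3·d_std (the alignment rule for field truth
is this package's own choice). Per-status accuracy is
100·correct/ground_truth, presented half-up at 2 decimals; the abnormality
rate is the non-normal share of assessed events. Overall accuracy k/n gets
a Wilson 95 % score interval (z = 1.959964) and one-sided upper-tail tests
against a baseline p₀ = 0.85: a z test without continuity correction and
an exact binomial tail P(X ≥ k). One-sided is the appropriate direction
for "accuracy exceeds baseline". For the reference two-plot trial tally
(539/594) these give [88.14 %, 92.82 %], p_z = 4.46e-05,
p_binom = 2.16e-05 — the table arithmetic supports an overall accuracy of
90.74 %, which is what the reporting module targets.

**Feedback.** Clustering, routing and compensation are operationalizations
of qualitative requirements ("spatial clustering", "optimal replanting
path", "high frequency"), so the knobs are explicit config: DBSCAN with
eps = 3·d_std and min_samples = 2, noise kept as singleton clusters (every
anomaly must be replantable); an open route (no return to start) built
nearest-neighbour and improved by 2-opt until no reversal shortens it,
with route length the optimality criterion; compensation over a sliding
window of 20 events firing when the burial (exposure) fraction exceeds
0.2 — raise (lower) the planting depth — or when mean spacing drifts more
than 10 % from d_std.

**Detector operators.** Dynamic convolution: Y = Σᵢ αᵢ (Wᵢ ∗ X) with
α = softmax(MLP(GlobalAvgPool(X))); the MLP is two layers, hidden width
max(1, c_in/4), ReLU, temperature 1 (widths are unspecified upstream — a
standard gating choice). The mixed-kernel form conv(X, Σ αᵢWᵢ) is
algebraically identical and both are provided; tests pin their agreement
at 1e-6. Pinwheel-shaped convolution: four branches pad the input
asymmetrically — P(1,0,0,3), P(0,3,0,1), P(0,1,3,0), P(3,0,1,0) as
(left, right, top, bottom) — and convolve with 3-extent directional
kernels, then BN, SiLU, channel concatenation and a 2×2 fusion
convolution. The kernel orientation per branch is the one disambiguation
this package applies: each 3-extent kernel must lie along the axis its
padding extends by 3 px ((3,1),(1,3),(3,1),(1,3) for the paddings above),
otherwise the four branch outputs do not share a spatial shape. With that
pairing, shapes agree for any stride and the measured union receptive
field of one fused output is 25 input positions (9 for a plain 3×3).
Branch stride defaults to 2 (the block replaces downsampling convolutions
in the detector backbone; the equations print no stride) with stride 1
used for receptive-field analysis; the fusion conv is stride 1. No bias
terms (absorbed by BN); BN defaults to identity statistics so the forward
pass is analyzable as a linear map. Receptive fields are measured by
impulse response with all-ones weights and identity activations.

## Simulator

The generator emulates the validation-trial geometry: ridges of
plants_per_ridge points at nominal spacing d_std = 0.5 m, ridge gap 1.2 m,
serpentine traversal at 0.5 m/s, 30 fps camera, 10 Hz GNSS with σ = 1 cm
per axis. Bundled presets reproduce the two trial shapes (10×21 = 210 and
8×48 = 384 points). Defaults chosen where no upstream value exists:
along-row jitter σ = 0.02 m (well inside the normal band); double-planting
offset uniform in (0.1, 0.35)·d_std (strictly inside the double band);
pixel scale 2160 px/m so a plant's track crosses the frame in ~1 s at the
default speed (the camera is abstract — no optics model).

Per-point anomalies are sampled independently: miss removes the plant,
double adds a second plant at the offset above, bury/expose relabel the
visual class. The detector error model has three independent knobs:
`detect_prob` — the probability a plant is detected *at all* (a per-plant
track dropout, chosen so the missed-detection → missed-planting error path
of real systems is reproducible; with per-frame dropout a ~25-frame track
would effectively never vanish); `frame_drop_prob` — per-frame dropout
within surviving tracks; `false_positive_rate` — per point, a spurious
track injected adjacent to a real plant at (0.15, 0.35)·d_std (background
mistaken for a seedling), which the assessment correctly calls double
planting. The per-class confusion matrix is sampled once per plant, not
per frame, so configured per-class correctness proportions survive the
track-majority vote.

One integer seed drives a run; layout and sensor stages draw from
substreams `[seed, 0]` and `[seed, 1]`, so identical seeds give
byte-identical streams.

**What passing tests do and do not show.** The simulator has straight
ridges, a plant-centred camera, independent per-point anomalies, Gaussian
GNSS noise and no occlusion, motion blur, terrain, or correlated detector
failures. Perfect scores under identity sensors validate the *logic*
(counting, fusion, rules, statistics), not field performance; detector
accuracy itself is outside this package's scope and enters only as the
configurable error model. Two physical limits are modelled honestly: a
miss at the first or last point of a ridge produces no spacing gap and is
undetectable, and a false positive more than 0.4·d_std from any plant
would not be called double.

## Numerical choices and problem sizes

Percentages are rounded half-up to 2 decimals for presentation; all
geometry is double precision. Test and acceptance runs use fields of up to
10×100 points and 20 replicates for rate-recovery checks — sizes at which
binomial standard errors are small enough to make the checks sharp while a
full run stays under a second. The brute-force classifier oracle is
checked on randomized ridges of ≤ 8 plants, where exhaustive chain
enumeration is tractable.

## Known limitations

- Single camera, single row per pass; no cross-ridge spacing analysis.
- GNSS interpolation is linear in degrees; fine at walking speeds and
  ≤ 1 s gaps, wrong for fast platforms or sparse fixes.
- The replanting route is a 2-opt local optimum, not a proven shortest
  path.
- The NMEA reader covers the RMC subset only (time, position, status).
- No training or gradients in the convolution operators; they are forward
  semantics and receptive-field analysis only.
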