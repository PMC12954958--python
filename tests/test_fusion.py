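"""Track linking, counting-line crossings, and GNSS fusion."""

import random

import pytest

from transplantqc import (
    CrossingConfig,
    DetectionRecord,
    GeoPoint,
    GnssFix,
    SeedlingClass,
    SensorModel,
    count_crossings,
    fuse_run,
    interpolate_fix,
    link_tracks,
    simulate_run,
)
from transplantqc.fusion import SynchronizationError
from transplantqc.simulator import FieldSpec, AnomalyRates, projection_for


def det(frame, cy, cx=960.0, cls=SeedlingClass.NORMAL, w=100.0, h=100.0, t=None):
    t = frame / 30.0 if t is None else t
    return DetectionRecord(
        frame_index=frame,
        timestamp=t,
        cls=cls,
        bbox=(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
    )


class TestLinkTracks:
    def test_drifting_box_forms_one_track(self):
        stream = [det(f, 500 + 10 * f) for f in range(5)]
        tracks = link_tracks(stream, CrossingConfig())
        assert len(tracks) == 1
        assert len(tracks[0]) == 5

    def test_distant_boxes_form_two_tracks(self):
        stream = []
        for f in range(3):
            stream.append(det(f, 200.0))
            stream.append(det(f, 800.0))
        tracks = link_tracks(stream, CrossingConfig())
        assert len(tracks) == 2
        assert all(len(t) == 3 for t in tracks)

    def test_gap_beyond_max_frame_gap_splits_track(self):
        # same box at frames 0,1 then 5,6: gap of 4 > max_frame_gap 2
        stream = [det(0, 400), det(1, 400), det(5, 400), det(6, 400)]
        tracks = link_tracks(stream, CrossingConfig(max_frame_gap=2))
        assert len(tracks) == 2
        # but a gap within the allowance keeps one track
        stream2 = [det(0, 400), det(1, 400), det(3, 400)]
        assert len(link_tracks(stream2, CrossingConfig(max_frame_gap=2))) == 1

    def test_unsorted_stream_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            link_tracks([det(3, 400), det(1, 400)], CrossingConfig())

    def test_each_detection_in_exactly_one_track(self):
        rng = random.Random(5)
        stream = []
        for f in range(20):
            for base in (150.0, 520.0, 900.0):
                stream.append(det(f, base + rng.uniform(-5, 5)))
        tracks = link_tracks(stream, CrossingConfig())
        ids = [id(d) for tr in tracks for d in tr]
        assert len(ids) == len(stream)
        assert len(set(ids)) == len(stream)


class TestCountCrossings:
    def cfg(self, direction="increasing"):
        from transplantqc.fusion import Direction

        return CrossingConfig(direction=Direction(direction))

    def test_single_crossing_timestamped_at_later_frame(self):
        track = [det(0, 500), det(1, 530), det(2, 560)]
        events = count_crossings([track], self.cfg("increasing"))
        assert len(events) == 1
        t, cls = events[0]
        assert t == pytest.approx(2 / 30.0)

    def test_track_on_one_side_never_counts(self):
        track = [det(f, 100 + f) for f in range(5)]
        assert count_crossings([track], self.cfg("any")) == []

    def test_oscillating_track_counts_once(self):
        track = [det(0, 540), det(1, 560), det(2, 520), det(3, 560)]
        events = count_crossings([track], self.cfg("any"))
        assert len(events) == 1

    def test_majority_class_with_crossing_frame_tiebreak(self):
        track = [
            det(0, 500, cls=SeedlingClass.BURIED),
            det(1, 530, cls=SeedlingClass.BURIED),
            det(2, 560, cls=SeedlingClass.NORMAL),
        ]
        events = count_crossings([track], self.cfg("increasing"))
        assert events[0][1] is SeedlingClass.BURIED
        tied = [det(0, 500, cls=SeedlingClass.BURIED), det(1, 560, cls=SeedlingClass.NORMAL)]
        events = count_crossings([tied], self.cfg("increasing"))
        assert events[0][1] is SeedlingClass.NORMAL  # crossing frame breaks the tie

    def test_in_frame_permutation_does_not_change_events(self):
        stream = []
        for f in range(6):
            stream.append(det(f, 450 + 30 * f, cx=700))
            stream.append(det(f, 430 + 30 * f, cx=1200))
        cfg = CrossingConfig()
        ev_a = count_crossings(link_tracks(stream, cfg), cfg)
        shuffled = []
        for f in range(6):
            pair = [d for d in stream if d.frame_index == f]
            shuffled.extend(pair[::-1])
        ev_b = count_crossings(link_tracks(shuffled, cfg), cfg)
        assert sorted(ev_a) == sorted(ev_b)


class TestInterpolateFix:
    def fixes(self):
        return [
            GnssFix(0.0, GeoPoint(24.0, 102.0)),
            GnssFix(1.0, GeoPoint(24.00002, 102.0)),
        ]

    def test_midpoint(self):
        p = interpolate_fix(self.fixes(), 0.5)
        assert p.latitude == pytest.approx(24.00001, abs=1e-12)

    def test_exact_fix_time(self):
        p = interpolate_fix(self.fixes(), 1.0)
        assert p.latitude == 24.00002

    def test_query_beyond_max_gap_raises(self):
        with pytest.raises(SynchronizationError):
            interpolate_fix(self.fixes(), 6.0, max_gap=1.0)
        with pytest.raises(SynchronizationError):
            interpolate_fix([], 0.0)

    def test_nearest_fix_within_gap_tolerance(self):
        p = interpolate_fix(self.fixes(), 1.5, max_gap=1.0)
        assert p.latitude == 24.00002


class TestFuseRun:
    def test_lossless_round_trip_recovers_classes(self, small_clean_run):
        fs, gt, dets, fixes, proj = small_clean_run
        plants = fuse_run(dets, fixes, CrossingConfig(), proj)
        assert len(plants) == len(gt.plants)
        truth_classes = sorted(p.cls.value for p in gt.plants)
        fused_classes = sorted(p.cls.value for p in plants)
        assert fused_classes == truth_classes

    def test_empty_detections_yield_empty_output(self, small_clean_run):
        _, _, _, fixes, proj = small_clean_run
        assert fuse_run([], fixes, CrossingConfig(), proj) == []

    def test_zero_detection_probability_yields_empty_output(self):
        fs = FieldSpec(n_ridges=1, plants_per_ridge=10)
        _, dets, fixes = simulate_run(fs, sensors=SensorModel(detect_prob=0.0), seed=3)
        assert dets == []
        assert fuse_run(dets, fixes, CrossingConfig(), projection_for(fs)) == []

    def test_dropout_preserves_order_of_survivors(self):
        fs = FieldSpec(n_ridges=1, plants_per_ridge=10, serpentine=False)
        sensors = SensorModel(gnss_sigma=0.0, detect_prob=0.9, seed=11)
        gt, dets, fixes = simulate_run(fs, AnomalyRates(), sensors, seed=11)
        plants = fuse_run(dets, fixes, CrossingConfig(), projection_for(fs))
        assert 0 < len(plants) <= 10
        ts = [p.timestamp for p in plants]
        assert ts == sorted(ts)
        ids = [p.plant_id for p in plants]
        assert ids == list(range(len(plants)))
        # travel advances monotonically along the ridge (azimuth 0 → north)
        ys = [p.plane.y for p in plants]
        assert all(b > a for a, b in zip(ys, ys[1:]))
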