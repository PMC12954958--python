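"""Anomaly clustering, replant routes, twin messages, compensation signals."""

import itertools
import json
import math

import pytest

from transplantqc import (
    GeoPoint,
    SeedlingClass,
    TransplantStatus,
    cluster_anomalies,
    compensation_signals,
    replant_route,
    twin_message_lines,
    twin_messages,
)
from transplantqc.assessment import TransplantEvent
from transplantqc.feedback import SignalKind, nearest_neighbor_route
from transplantqc.geodesy import PlanePoint, plane_distance

N = TransplantStatus.NORMAL
B = TransplantStatus.SEEDLING_BURIAL
E = TransplantStatus.ROOT_EXPOSURE
M = TransplantStatus.MISSED_PLANTING


def event(status, x, y, lat=24.6, lon=102.9, spacing=None):
    members = ()
    if status not in (TransplantStatus.MISSED_PLANTING,):
        members = (0, 1) if status is TransplantStatus.DOUBLE_PLANTING else (0,)
    return TransplantEvent(
        status=status,
        geo=GeoPoint(lat, lon),
        plane=PlanePoint(x, y),
        member_plant_ids=members,
        spacing_before=spacing,
    )


class TestClusterAnomalies:
    def test_no_anomalies_no_clusters(self):
        events = [event(N, i * 0.5, 0) for i in range(5)]
        assert cluster_anomalies(events) == []

    def test_near_group_plus_outlier(self):
        events = [
            event(B, 0.0, 0.0),
            event(B, 0.5, 0.0),
            event(E, 1.0, 0.0),
            event(M, 20 * 0.5, 0.0),  # 20·d_std away
        ]
        clusters = cluster_anomalies(events, d_std=0.5, eps_mult=3.0, min_pts=2)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 3]

    def test_dense_grid_chains_into_one_cluster(self):
        events = [
            event(M, i * 0.5, j * 0.5) for i in range(5) for j in range(5)
        ]
        clusters = cluster_anomalies(events, d_std=0.5)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 25

    def test_members_within_radius_and_exhaustive(self):
        events = [event(B, i * 0.4, (i % 3) * 0.2) for i in range(12)]
        clusters = cluster_anomalies(events, d_std=0.5)
        total = sum(len(c.members) for c in clusters)
        assert total == 12
        for c in clusters:
            for m in c.members:
                assert plane_distance(c.centroid, m.plane) <= c.radius + 1e-12


class TestReplantRoute:
    def test_single_point_route(self):
        ev = [event(M, 3.0, 4.0)]
        r = replant_route(ev, PlanePoint(0, 0))
        assert len(r.stops) == 1
        assert r.total_length == pytest.approx(5.0)

    def test_empty_route_for_clean_run(self):
        r = replant_route([event(N, 0, 0)], PlanePoint(0, 0))
        assert r.stops == []
        assert r.total_length == 0.0

    def test_collinear_points_visited_in_spatial_order(self):
        xs = [4.0, 1.0, 3.0, 2.0, 5.0]
        ev = [event(M, x, 0.0) for x in xs]
        r = replant_route(ev, PlanePoint(0, 0))
        assert [s.plane.x for s in r.stops] == sorted(xs)

    def test_square_route_matches_exhaustive_optimum(self):
        corners = [(0, 1), (1, 1), (1, 0), (0.0, 0.0)]
        ev = [event(M, x, y) for x, y in corners[:3]]
        start = PlanePoint(0.0, 0.0)
        r = replant_route(ev, start)
        # brute force over all open tours from the start corner
        pts = [PlanePoint(x, y) for x, y in corners[:3]]

        def length(order):
            tot = plane_distance(start, pts[order[0]])
            for a, b in zip(order, order[1:]):
                tot += plane_distance(pts[a], pts[b])
            return tot

        best = min(length(list(p)) for p in itertools.permutations(range(3)))
        assert r.total_length == pytest.approx(best)
        assert r.total_length == pytest.approx(3.0)  # three unit sides

    def test_two_opt_never_worse_than_nearest_neighbor(self):
        import numpy as np

        rng = np.random.default_rng(8)
        ev = [event(M, x, y) for x, y in rng.uniform(0, 10, size=(15, 2))]
        start = PlanePoint(0, 0)
        r = replant_route(ev, start)
        pts = [e.plane for e in ev]
        nn_order = nearest_neighbor_route(pts, start)
        nn_len = plane_distance(start, pts[nn_order[0]]) + sum(
            plane_distance(pts[a], pts[b]) for a, b in zip(nn_order, nn_order[1:])
        )
        assert r.total_length <= nn_len + 1e-9
        # every anomaly appears exactly once
        assert sorted(id(s) for s in r.stops) == sorted(id(e) for e in ev)


class TestTwinMessages:
    def test_burial_message_matches_wire_format(self):
        ev = [event(B, 0, 0, lat=24.64190, lon=102.92841)]
        (line,) = twin_message_lines(ev)
        assert line == '{"latitude": 24.64190, "longitude": 102.92841, "state": "buried"}'
        obj = json.loads(line)
        assert list(obj) == ["latitude", "longitude", "state"]

    def test_empty_events_empty_stream(self):
        assert twin_messages([]) == []
        assert twin_message_lines([]) == []

    def test_round_trip_recovers_position_and_state(self):
        states = {
            N: "normal",
            M: "missed",
            TransplantStatus.DOUBLE_PLANTING: "double",
            B: "buried",
            E: "exposed_root",
        }
        events = [event(s, 0, 0, lat=24.6 + i * 1e-4) for i, s in enumerate(states)]
        lines = twin_message_lines(events)
        assert len(lines) == len(events)
        for line, ev_in in zip(lines, events):
            obj = json.loads(line)
            assert obj["state"] == states[ev_in.status]
            assert obj["latitude"] == pytest.approx(ev_in.geo.latitude, abs=1e-5)


class TestCompensationSignals:
    def test_all_normal_run_emits_nothing(self):
        events = [event(N, i * 0.5, 0, spacing=0.5) for i in range(40)]
        assert compensation_signals(events, d_std=0.5) == []

    def test_frequent_burials_raise_depth(self):
        events = [
            event(B if i < 5 else N, i * 0.5, 0, spacing=0.5) for i in range(20)
        ]
        signals = compensation_signals(events, d_std=0.5, window=20)
        kinds = {s.kind for s in signals}
        assert kinds == {SignalKind.RAISE_DEPTH}
        assert signals[0].magnitude == pytest.approx(0.25)

    def test_alternating_bury_expose_fires_both_depth_signals(self):
        events = [
            event(B if i % 2 == 0 else E, i * 0.5, 0, spacing=0.5) for i in range(20)
        ]
        kinds = {s.kind for s in compensation_signals(events, d_std=0.5)}
        assert kinds == {SignalKind.RAISE_DEPTH, SignalKind.LOWER_DEPTH}

    def test_spacing_drift_triggers_adjustment(self):
        events = [event(N, i * 0.6, 0, spacing=0.6) for i in range(20)]
        signals = compensation_signals(events, d_std=0.5, window=20)
        assert [s.kind for s in signals] == [SignalKind.SPACING_ADJUST]
        assert signals[0].magnitude == pytest.approx(0.2)

    def test_signals_are_shift_equivariant(self):
        burst = [event(B, i * 0.5, 0, spacing=0.5) for i in range(10)]
        tail = [event(N, (10 + i) * 0.5, 0, spacing=0.5) for i in range(15)]
        base = compensation_signals(burst + tail, d_std=0.5, window=20)
        prefix = [event(N, -(i + 1) * 0.5, 0, spacing=0.5) for i in range(7)]
        shifted = compensation_signals(prefix + burst + tail, d_std=0.5, window=20)
        # windows past the prefix reproduce the base pattern, delayed by 7
        base_pattern = [(s.kind, round(s.magnitude, 9), s.window_start) for s in base]
        shifted_pattern = [
            (s.kind, round(s.magnitude, 9), s.window_start - 7)
            for s in shifted
            if s.window_start >= 7
        ]
        assert shifted_pattern == base_pattern
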