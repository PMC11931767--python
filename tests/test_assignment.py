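import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from microconc.assignment import (
    LocationMode,
    OutOfRangeError,
    UnknownLocationError,
    UnresolvableLocationError,
    assign_to_microplace,
    build_case_series,
    parse_location,
)
from microconc.network import Kind, Microplace, MicroplaceNetwork


class TestParseLocation:
    def test_cross_streets(self):
        loc = parse_location(
            {"cross_street_a": "South St.", "cross_street_b": "Main St."}
        )
        assert loc.mode is LocationMode.CROSS_STREETS
        assert loc.payload == ("South St.", "Main St.")

    def test_preassigned_passthrough(self):
        loc = parse_location({"microplace_id": "seg-17"})
        assert loc.mode is LocationMode.PREASSIGNED
        assert loc.payload == "seg-17"

    def test_coordinates(self):
        loc = parse_location({"x": 1.5, "y": -2.0})
        assert loc.mode is LocationMode.COORDINATES
        assert loc.payload == (1.5, -2.0)

    def test_precedence_cross_streets_first(self):
        loc = parse_location(
            {
                "cross_street_a": "A St",
                "cross_street_b": "B St",
                "address_ref": "A St block 1",
                "x": 0.0,
                "y": 0.0,
                "microplace_id": "seg-0",
            }
        )
        assert loc.mode is LocationMode.CROSS_STREETS

    def test_address_before_coordinates(self):
        loc = parse_location({"address_ref": "A St block 1", "x": 0.0, "y": 0.0})
        assert loc.mode is LocationMode.ADDRESS_REF

    def test_unknown_location_names_event(self):
        with pytest.raises(UnknownLocationError, match="ev-99"):
            parse_location({"event_id": "ev-99", "x": np.nan})


class TestAssign:
    def test_point_on_segment_distance_zero(self, small_network):
        seg = small_network.microplaces[0]
        mid = seg.geometry.interpolate(0.5, normalized=True)
        loc = parse_location({"x": mid.x, "y": mid.y})
        mp, dist = assign_to_microplace(loc, small_network)
        assert mp == seg.id
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_cross_street_assignment(self, small_network):
        inter = next(
            m for m in small_network.microplaces if m.kind is Kind.INTERSECTION
        )
        a, b = [s.strip() for s in inter.label.split("&")]
        loc = parse_location({"cross_street_a": b, "cross_street_b": a})
        assert assign_to_microplace(loc, small_network) == (inter.id, 0.0)

    def test_address_assignment(self, small_network):
        seg = small_network.microplaces[0]
        loc = parse_location({"address_ref": seg.label})
        assert assign_to_microplace(loc, small_network) == (seg.id, 0.0)

    def test_unresolvable_label(self, small_network):
        loc = parse_location({"address_ref": "no such street"})
        with pytest.raises(UnresolvableLocationError):
            assign_to_microplace(loc, small_network)

    def test_out_of_range_point(self, small_network):
        loc = parse_location({"x": 1e7, "y": 1e7})
        with pytest.raises(OutOfRangeError):
            assign_to_microplace(loc, small_network, snap_threshold=10.0)

    def test_tie_break_smallest_id(self):
        net = MicroplaceNetwork(
            [
                Microplace("b-2", Kind.INTERSECTION, Point(0.0, 0.0)),
                Microplace("a-1", Kind.INTERSECTION, Point(2.0, 0.0)),
            ]
        )
        loc = parse_location({"x": 1.0, "y": 0.0})
        mp, _ = assign_to_microplace(loc, net, snap_threshold=5.0)
        assert mp == "a-1"

    def test_nearest_agrees_with_exhaustive_scan(self, small_network):
        rng = np.random.default_rng(0)
        xs = rng.uniform(-50, 450, 100)
        ys = rng.uniform(-50, 450, 100)
        pts = [Point(x, y) for x, y in zip(xs, ys)]
        for pt in pts:
            # brute-force oracle: scan every microplace, tie-break by id
            best = min(
                small_network.microplaces,
                key=lambda m: (m.geometry.distance(pt), m.id),
            )
            loc = parse_location({"x": pt.x, "y": pt.y})
            mp, dist = assign_to_microplace(loc, small_network, snap_threshold=1e9)
            assert mp == best.id
            assert dist == pytest.approx(best.geometry.distance(pt))


class TestBuildCaseSeries:
    def test_completeness_and_exclusion_log(self, small_network):
        seg = small_network.microplaces[0]
        events = pd.DataFrame(
            {
                "event_id": [f"e{i}" for i in range(5)],
                "date": ["2008-01-01"] * 5,
                "microplace_id": [seg.id, seg.id, None, None, None],
                "address_ref": [None, None, seg.label, None, None],
                "x": [None, None, None, 1e7, None],
                "y": [None, None, None, 1e7, None],
            }
        )
        series, log = build_case_series(events, small_network, snap_threshold=10.0)
        assert len(series) + len(log) == 5
        assert len(series) == 3
        assert set(log["event_id"]) == {"e3", "e4"}
        reasons = dict(zip(log["event_id"], log["reason"]))
        assert "snap threshold" in reasons["e3"]
        assert "no location" in reasons["e4"]

    def test_all_preassigned_identity_and_idempotence(self, small_network):
        ids = [m.id for m in small_network.microplaces[:4]]
        events = pd.DataFrame(
            {
                "event_id": [f"e{i}" for i in range(4)],
                "date": [f"2009-0{i + 1}-01" for i in range(4)],
                "microplace_id": ids,
            }
        )
        series, log = build_case_series(events, small_network)
        assert log.empty
        assert list(series.data["microplace_id"]) == ids
        # re-assigning the already-assigned series changes nothing
        again, log2 = build_case_series(series.data, small_network)
        assert log2.empty
        pd.testing.assert_frame_equal(
            again.data[["event_id", "microplace_id"]],
            series.data[["event_id", "microplace_id"]],
        )

    def test_empty_input_gives_empty_series(self, small_network):
        events = pd.DataFrame(columns=["event_id", "date", "microplace_id"])
        series, log = build_case_series(events, small_network)
        assert len(series) == 0 and log.empty

    def test_output_ordered_by_date_then_id(self, small_network):
        ids = [small_network.microplaces[0].id] * 3
        events = pd.DataFrame(
            {
                "event_id": ["b", "a", "c"],
                "date": ["2009-02-01", "2009-02-01", "2009-01-01"],
                "microplace_id": ids,
            }
        )
        series, _ = build_case_series(events, small_network)
        assert list(series.data["event_id"]) == ["c", "a", "b"]
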