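"""Route scheduling, modulators and detour classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navtopo.network import NetworkError, build_dual_graph, centrality_table
from navtopo.routes import (
    Route,
    TimingConfig,
    classify_detours,
    compute_modulator,
    decision_point_modulators,
    read_route_json,
    schedule_route,
    schedules_to_frame,
    write_route_json,
)

from conftest import make_chain, make_grid


def chain_route(n, goal=None, condition="navigation"):
    return Route(
        id="r0",
        ordered_segment_ids=tuple(f"S{i}" for i in range(n)),
        goal_changes=((0, goal or f"S{n - 1}"),),
        condition=condition,
    )


MIDPOINT = TimingConfig(dp_entry_jitter=(6.0, 6.0), start_jitter=(9.0, 9.0))


class TestScheduling:
    def test_hand_computed_onsets_two_segments(self):
        # lengths 48 and 32 m at 1.6 m/s -> 30 s and 20 s of walking;
        # jitters pinned to their midpoints (start 9 s, DP->entry 6 s)
        net = make_chain(2, lengths=[48.0, 32.0])
        g = build_dual_graph(net)
        sched = schedule_route(chain_route(2), g, MIDPOINT, np.random.default_rng(0))
        got = [(e.type, e.onset) for e in sched.events]
        assert got == [
            ("new_goal", 9.0),        # after the 9-s start image
            ("travel_period", 33.0),  # midpoint of the 18..48 walking gap
            ("decision_point", 48.0),  # 18 + 30 s walking
            ("street_entry", 59.0),   # DP end (53) + 6-s jitter
            ("travel_period", 69.0),  # midpoint of 59..79
        ]
        assert sched.total_duration == pytest.approx(79.0)

    def test_event_durations_follow_the_design(self, chain5):
        g = build_dual_graph(chain5)
        sched = schedule_route(chain_route(5), g, TimingConfig(), np.random.default_rng(1))
        durs = {e.type: e.duration for e in sched.events}
        assert durs["new_goal"] == 9.0
        assert durs["decision_point"] == 5.0
        assert durs["street_entry"] == 0.0
        assert durs["travel_period"] == 0.0

    def test_dp_entry_jitter_bounds_over_many_draws(self, chain5):
        g = build_dual_graph(chain5)
        rng = np.random.default_rng(2)
        timing = TimingConfig()
        gaps = []
        for _ in range(250):  # 4 DP->entry pairs each -> 1000 gaps
            sched = schedule_route(chain_route(5), g, timing, rng)
            dps = sched.of_type("decision_point")
            ses = sched.of_type("street_entry")
            gaps += [se.onset - (dp.onset + dp.duration) for dp, se in zip(dps, ses)]
        assert len(gaps) == 1000
        assert min(gaps) >= 3.0 and max(gaps) <= 9.0

    def test_start_jitter_bounds(self, chain5):
        g = build_dual_graph(chain5)
        rng = np.random.default_rng(3)
        onsets = [schedule_route(chain_route(5), g, TimingConfig(), rng).events[0].onset
                  for _ in range(300)]
        assert min(onsets) >= 5.0 and max(onsets) <= 13.0

    def test_counts_one_dp_and_entry_per_junction(self, chain5):
        g = build_dual_graph(chain5)
        sched = schedule_route(chain_route(5), g, TimingConfig(), np.random.default_rng(4))
        assert len(sched.of_type("decision_point")) == 4
        assert len(sched.of_type("street_entry")) == 4
        assert len(sched.of_type("new_goal")) == 1
        onsets = [e.onset for e in sched.events]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_zero_and_single_segment_routes_error(self, chain5):
        g = build_dual_graph(chain5)
        with pytest.raises(ValueError):
            Route(id="r", ordered_segment_ids=(), goal_changes=((0, "S0"),))
        with pytest.raises(ValueError, match="at least 2"):
            schedule_route(
                Route(id="r", ordered_segment_ids=("S0",), goal_changes=((0, "S0"),)),
                g, TimingConfig(), np.random.default_rng(0),
            )

    def test_nonadjacent_sequence_errors_naming_break(self, chain5):
        g = build_dual_graph(chain5)
        bad = Route(id="r", ordered_segment_ids=("S0", "S2"), goal_changes=((0, "S2"),))
        with pytest.raises(NetworkError, match="S0.*S2"):
            schedule_route(bad, g, TimingConfig(), np.random.default_rng(0))

    def test_reproducible_under_seed(self, chain5):
        g = build_dual_graph(chain5)
        a = schedule_route(chain_route(5), g, TimingConfig(), np.random.default_rng(9))
        b = schedule_route(chain_route(5), g, TimingConfig(), np.random.default_rng(9))
        assert [(e.type, e.onset) for e in a.events] == [(e.type, e.onset) for e in b.events]


class TestModulators:
    def test_degree_deltas_along_chain(self, chain5):
        # degrees along the chain are 1,2,2,2,1
        g = build_dual_graph(chain5)
        table = centrality_table(g)
        sched = schedule_route(chain_route(5), g, MIDPOINT, np.random.default_rng(0))
        series = compute_modulator(sched, table, "degree")
        assert series.raw == [2.0, 2.0, 2.0, 1.0]
        assert series.delta == [1.0, 0.0, 0.0, -1.0]
        assert series.categorical == [1, 0, 0, -1]

    def test_categorical_is_sign_of_delta(self, grid44):
        g = build_dual_graph(grid44)
        table = centrality_table(g)
        route = Route(id="r", ordered_segment_ids=("h0_0", "v1_0", "h1_1", "v2_1"),
                      goal_changes=((0, "v2_1"),))
        sched = schedule_route(route, g, MIDPOINT, np.random.default_rng(0))
        for param in ("degree", "closeness", "betweenness"):
            series = compute_modulator(sched, table, param)
            assert series.categorical == [int(np.sign(d)) for d in series.delta]

    def test_translation_invariance_of_delta(self, grid44):
        g = build_dual_graph(grid44)
        table = centrality_table(g)
        route = Route(id="r", ordered_segment_ids=("h0_0", "v1_0", "h1_1"),
                      goal_changes=((0, "h1_1"),))
        sched = schedule_route(route, g, MIDPOINT, np.random.default_rng(0))
        base = compute_modulator(sched, table, "degree")
        shifted = table.copy()
        shifted["degree"] = shifted["degree"] + 17.5
        moved = compute_modulator(sched, shifted, "degree")
        assert moved.delta == base.delta
        assert moved.categorical == base.categorical

    def test_missing_covariate_errors_listing_segments(self, chain5):
        g = build_dual_graph(chain5)
        table = centrality_table(g)
        sched = schedule_route(chain_route(5), g, MIDPOINT, np.random.default_rng(0))
        with pytest.raises(KeyError, match="line_of_sight"):
            compute_modulator(sched, table, "line_of_sight_m")

    def test_goal_referenced_parameters(self, chain5):
        g = build_dual_graph(chain5)
        table = centrality_table(g)
        sched = schedule_route(chain_route(5), g, MIDPOINT, np.random.default_rng(0))
        depth = compute_modulator(sched, table, "step_depth_to_goal", g=g)
        # walking straight at the goal: depth falls 3,2,1,0 -> delta -1 each
        assert depth.raw == [3.0, 2.0, 1.0, 0.0]
        assert depth.categorical == [-1, -1, -1, -1]
        metric = compute_modulator(sched, table, "path_distance_to_goal", g=g)
        assert all(d < 0 for d in metric.delta)

    def test_decision_point_past_and_future(self, chain5):
        g = build_dual_graph(chain5)
        table = centrality_table(g)
        sched = schedule_route(chain_route(5), g, MIDPOINT, np.random.default_rng(0))
        past = decision_point_modulators(sched, table, "degree", reference="past")
        future = decision_point_modulators(sched, table, "degree", reference="future")
        # first DP (on S0) has no previous segment -> skipped for 'past'
        assert len(past) == 3
        assert past.delta == [1.0, 0.0, 0.0]
        # future: degree of next minus current along 1,2,2,2,1
        assert len(future) == 4
        assert future.delta == [1.0, 0.0, 0.0, -1.0]


class TestDetours:
    def test_straight_route_has_no_detours(self, chain5):
        g = build_dual_graph(chain5)
        sched = classify_detours(
            schedule_route(chain_route(5), g, MIDPOINT, np.random.default_rng(0)), g
        )
        assert [e.is_detour for e in sched.of_type("street_entry")] == [False] * 4

    def test_sideways_and_backward_moves_are_detours(self, grid44):
        g = build_dual_graph(grid44)
        # goal h0_2: moving h0_0 -> v1_0 is sideways (depth 2 -> 2): a detour;
        # then v1_0 -> h0_1 improves (depth 2 -> 1)
        route = Route(id="r", ordered_segment_ids=("h0_0", "v1_0", "h0_1", "h0_2"),
                      goal_changes=((0, "h0_2"),))
        sched = classify_detours(
            schedule_route(route, g, MIDPOINT, np.random.default_rng(0)), g
        )
        assert [e.is_detour for e in sched.of_type("street_entry")] == [True, False, False]

    def test_metric_variant_can_differ(self, chain3):
        g = build_dual_graph(chain3)
        route = Route(id="r", ordered_segment_ids=("S0", "S1", "S2"),
                      goal_changes=((0, "S2"),))
        topo = classify_detours(
            schedule_route(route, g, MIDPOINT, np.random.default_rng(0)), g
        )
        metric = classify_detours(
            schedule_route(route, g, MIDPOINT, np.random.default_rng(0)), g, metric=True
        )
        assert [e.is_detour for e in topo.of_type("street_entry")] == [False, False]
        assert [e.is_detour for e in metric.of_type("street_entry")] == [False, False]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(shift=st.floats(-100, 100, allow_nan=False))
def test_delta_series_invariant_under_constant_shift(shift):
    """Adding any constant to all segment values never changes delta/categorical."""
    net = make_chain(5)
    g = build_dual_graph(net)
    table = centrality_table(g)
    sched = schedule_route(chain_route(5), g, MIDPOINT, np.random.default_rng(0))
    base = compute_modulator(sched, table, "degree")
    shifted = table.copy()
    shifted["degree"] = shifted["degree"] + shift
    moved = compute_modulator(sched, shifted, "degree")
    assert np.allclose(moved.delta, base.delta)
    assert moved.categorical == base.categorical


class TestRouteIO:
    def test_route_json_roundtrip(self, tmp_path):
        routes = [chain_route(4), chain_route(3, condition="control")]
        routes[1] = Route(id="r1", ordered_segment_ids=routes[1].ordered_segment_ids,
                          goal_changes=((0, "S2"), (2, "S0")), condition="control")
        path = tmp_path / "routes.json"
        write_route_json(routes, path)
        back = read_route_json(path)
        assert [r.id for r in back] == ["r0", "r1"]
        assert back[1].goal_changes == ((0, "S2"), (2, "S0"))
        assert back[1].condition == "control"

    def test_schedule_frame_layout(self, chain5):
        g = build_dual_graph(chain5)
        sched = classify_detours(
            schedule_route(chain_route(5), g, MIDPOINT, np.random.default_rng(0)), g
        )
        frame = schedules_to_frame([sched])
        assert list(frame.columns) == [
            "route_id", "event_type", "onset_s", "duration_s", "segment_id",
            "prev_segment_id", "goal_id", "is_detour",
        ]
        assert (frame.onset_s.diff().dropna() > 0).all()
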