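"""Routes, timed event schedules, detour classification and event modulators.

A route is an ordered walk over street segments.  Its video realisation
contains four event families:

* ``new_goal`` (NGE, 9 s) — a new destination is presented;
* ``decision_point`` (DP, 5 s) — pause before a junction where the upcoming
  turn is indicated;
* ``street_entry`` (SE, duration 0) — the instant the traveller crosses into
  a new segment; locus of the change-in-centrality modulators;
* ``travel_period`` (duration 0) — control time points equidistant between
  the other events, sampled only in gaps longer than a configurable minimum.

DP precedes its street entry by a jitter drawn from [3, 9] s (measured from
the end of the 5-s pause) and the start image is shown for a jitter of
[5, 13] s; a street entry whose turn does not strictly reduce the
topological distance to the active goal is flagged as a forced detour.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DualGraph, NetworkError, metric_path_distance, step_depth

log = logging.getLogger(__name__)

__all__ = [
    "Route",
    "TimingConfig",
    "Event",
    "RouteEventSchedule",
    "ModulatorSeries",
    "schedule_route",
    "compute_modulator",
    "classify_detours",
    "decision_point_modulators",
    "schedules_to_frame",
]

GOAL_PARAMETERS = ("step_depth_to_goal", "path_distance_to_goal")


@dataclass(frozen=True)
class Route:
    """An ordered segment walk with the goals active along it."""

    id: str
    ordered_segment_ids: tuple[str, ...]
    goal_changes: tuple[tuple[int, str], ...]  # (position index, goal segment id)
    condition: str = "navigation"  # navigation | control

    def __post_init__(self) -> None:
        if self.condition not in ("navigation", "control"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.ordered_segment_ids:
            raise ValueError(f"route {self.id!r} has no segments")
        if not self.goal_changes or self.goal_changes[0][0] != 0:
            raise ValueError(f"route {self.id!r} must define a goal at position 0")

    def goal_at(self, position: int) -> str:
        """Goal active while traversing the segment at *position*."""
        goal = self.goal_changes[0][1]
        for idx, gid in self.goal_changes:
            if idx <= position:
                goal = gid
        return goal


@dataclass(frozen=True)
class TimingConfig:
    """Timing parameters of the route videos (seconds, meters/second)."""

    walking_speed: float = 1.6
    nge_duration: float = 9.0
    dp_duration: float = 5.0
    dp_entry_jitter: tuple[float, float] = (3.0, 9.0)
    start_jitter: tuple[float, float] = (5.0, 13.0)
    street_text_duration: float = 3.0  # location text after a turn; offsets mid-route NGEs
    travel_event_min_gap: float = 6.0


@dataclass
class Event:
    type: str  # new_goal | decision_point | street_entry | travel_period
    onset: float
    duration: float
    segment_id: str
    prev_segment_id: str | None = None
    next_segment_id: str | None = None  # decision points only
    goal_id: str | None = None
    position: int | None = None  # index of segment_id along the route
    is_detour: bool | None = None  # street_entry only, set by classify_detours


@dataclass
class RouteEventSchedule:
    route: Route
    events: list[Event]
    total_duration: float

    def of_type(self, event_type: str) -> list[Event]:
        return [e for e in self.events if e.type == event_type]

    def validate(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(f"route {self.route.id!r}: event onsets not strictly increasing")


@dataclass
class ModulatorSeries:
    """Per-event raw / delta / categorical values of one parameter.

    ``categorical`` is the sign of ``delta`` (-1, 0, +1).  Events without a
    predecessor segment carry no delta and are omitted.
    """

    parameter: str
    events: list[Event] = field(default_factory=list)
    raw: list[float] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    categorical: list[int] = field(default_factory=list)

    def append(self, event: Event, raw: float, delta: float) -> None:
        self.events.append(event)
        self.raw.append(float(raw))
        self.delta.append(float(delta))
        self.categorical.append(int(np.sign(delta)))

    def __len__(self) -> int:
        return len(self.events)


def schedule_route(
    route: Route,
    g: DualGraph,
    timing: TimingConfig = TimingConfig(),
    rng: np.random.Generator | None = None,
) -> RouteEventSchedule:
    """Lay the route out in time and emit its event schedule.

    Timeline: start-image jitter -> initial NGE -> per traversed junction a
    DP, a jitter, then the street entry (followed by an NGE when the goal
    changed on entry) -> travel-period events at the midpoints of all gaps
    longer than ``travel_event_min_gap``.  Reproducible under a seeded rng.
    """
    rng = rng if rng is not None else np.random.default_rng()
    segs = route.ordered_segment_ids
    if len(segs) < 2:
        raise ValueError(f"route {route.id!r}: needs at least 2 segments to traverse")
    for a, b in zip(segs, segs[1:]):
        if b not in g.neighbors(a):
            raise NetworkError(
                f"route {route.id!r}: segments {a!r} -> {b!r} are not adjacent in the dual graph"
            )
    lengths = {s: g.primal.segments[s].length for s in segs}
    speed = timing.walking_speed

    events: list[Event] = []
    t = float(rng.uniform(*timing.start_jitter))
    events.append(
        Event("new_goal", onset=t, duration=timing.nge_duration,
              segment_id=segs[0], goal_id=route.goal_at(0), position=0)
    )
    t += timing.nge_duration
    goal_change_positions = {idx: gid for idx, gid in route.goal_changes if idx > 0}
    for i in range(len(segs) - 1):
        cur, nxt = segs[i], segs[i + 1]
        dp_onset = t + lengths[cur] / speed
        events.append(
            Event("decision_point", onset=dp_onset, duration=timing.dp_duration,
                  segment_id=cur, prev_segment_id=segs[i - 1] if i > 0 else None,
                  next_segment_id=nxt, goal_id=route.goal_at(i), position=i)
        )
        jitter = float(rng.uniform(*timing.dp_entry_jitter))
        se_onset = dp_onset + timing.dp_duration + jitter
        events.append(
            Event("street_entry", onset=se_onset, duration=0.0,
                  segment_id=nxt, prev_segment_id=cur,
                  goal_id=route.goal_at(i), position=i + 1)
        )
        t = se_onset
        if i + 1 in goal_change_positions:
            nge_onset = se_onset + timing.street_text_duration
            events.append(
                Event("new_goal", onset=nge_onset, duration=timing.nge_duration,
                      segment_id=nxt, prev_segment_id=cur,
                      goal_id=goal_change_positions[i + 1], position=i + 1)
            )
            t = nge_onset + timing.nge_duration
    total = t + lengths[segs[-1]] / speed

    _insert_travel_periods(events, total, timing.travel_event_min_gap)
    events.sort(key=lambda e: e.onset)
    sched = RouteEventSchedule(route=route, events=events, total_duration=total)
    sched.validate()
    return sched


def _insert_travel_periods(events: list[Event], total: float, min_gap: float) -> None:
    """One duration-0 event at the midpoint of every inter-event gap > min_gap."""
    main = sorted(events, key=lambda e: e.onset)
    extras: list[Event] = []
    for a, b in zip(main, main[1:]):
        gap_start, gap_end = a.onset + a.duration, b.onset
        if gap_end - gap_start > min_gap:
            seg = a.segment_id
            extras.append(
                Event("travel_period", onset=(gap_start + gap_end) / 2, duration=0.0,
                      segment_id=seg, prev_segment_id=a.prev_segment_id,
                      goal_id=a.goal_id, position=a.position)
            )
    last = main[-1]
    if total - (last.onset + last.duration) > min_gap:
        extras.append(
            Event("travel_period", onset=(last.onset + last.duration + total) / 2,
                  duration=0.0, segment_id=last.segment_id,
                  prev_segment_id=last.prev_segment_id, goal_id=last.goal_id,
                  position=last.position)
        )
    events.extend(extras)


def _event_value(
    event: Event, segment_id: str, table: pd.DataFrame, parameter: str,
    g: DualGraph | None,
) -> float:
    if parameter in GOAL_PARAMETERS:
        if g is None:
            raise ValueError(f"parameter {parameter!r} needs the dual graph")
        if event.goal_id is None:
            raise ValueError("event has no active goal")
        if parameter == "step_depth_to_goal":
            return float(step_depth(g, segment_id, event.goal_id))
        return metric_path_distance(g.primal, g, segment_id, event.goal_id)
    return float(table.at[segment_id, parameter])


def compute_modulator(
    schedule: RouteEventSchedule,
    table: pd.DataFrame,
    parameter: str,
    g: DualGraph | None = None,
    event_type: str = "street_entry",
) -> ModulatorSeries:
    """Raw, delta and categorical modulator values at each event of a family.

    raw = value at the entered (current) segment, delta = current minus
    previous, categorical = sign(delta).  Goal-referenced parameters
    (step depth / metric path distance to the active goal) require the dual
    graph.  Events without a previous segment are omitted.
    """
    if parameter not in GOAL_PARAMETERS:
        if parameter not in table.columns:
            raise KeyError(f"parameter {parameter!r} not in centrality table")
        missing = [
            e.segment_id
            for e in schedule.of_type(event_type)
            if e.segment_id not in table.index
            or (e.prev_segment_id is not None and e.prev_segment_id not in table.index)
        ]
        if missing:
            raise KeyError(f"segments missing {parameter!r} values: {sorted(set(missing))}")
    series = ModulatorSeries(parameter=parameter)
    for e in schedule.of_type(event_type):
        if e.prev_segment_id is None:
            continue
        cur = _event_value(e, e.segment_id, table, parameter, g)
        prev = _event_value(e, e.prev_segment_id, table, parameter, g)
        series.append(e, raw=cur, delta=cur - prev)
    return series


def classify_detours(
    schedule: RouteEventSchedule, g: DualGraph, metric: bool = False
) -> RouteEventSchedule:
    """Flag each street entry as a forced detour or not (in place; returns schedule).

    A street entry is a detour iff the traversed turn does not *strictly*
    reduce the distance to the active goal, i.e. d(current, goal) >=
    d(previous, goal).  Distance is topological step depth by default; the
    metric variant uses meters of shortest dual path.
    """
    for e in schedule.of_type("street_entry"):
        if e.goal_id is None:
            raise ValueError(f"street entry at {e.onset:.1f}s has no active goal")
        if metric:
            d_cur = metric_path_distance(g.primal, g, e.segment_id, e.goal_id)
            d_prev = metric_path_distance(g.primal, g, e.prev_segment_id, e.goal_id)
        else:
            d_cur = step_depth(g, e.segment_id, e.goal_id)
            d_prev = step_depth(g, e.prev_segment_id, e.goal_id)
        e.is_detour = d_cur >= d_prev
    return schedule


def decision_point_modulators(
    schedule: RouteEventSchedule,
    table: pd.DataFrame,
    parameter: str,
    reference: str = "past",
    g: DualGraph | None = None,
) -> ModulatorSeries:
    """Change-in-parameter modulators at decision points.

    ``reference='past'``: current segment minus the previous one (the change
    the traveller has just experienced); ``'future'``: the segment beyond the
    junction minus the current one (the change the indicated turn will
    produce).  Decision points lacking the needed neighbour are skipped with
    a log notice.
    """
    if reference not in ("past", "future"):
        raise ValueError("reference must be 'past' or 'future'")
    series = ModulatorSeries(parameter=parameter)
    for e in schedule.of_type("decision_point"):
        if reference == "past":
            if e.prev_segment_id is None:
                log.info("route %s: DP at %.1fs has no previous segment; skipped",
                         schedule.route.id, e.onset)
                continue
            cur = _event_value(e, e.segment_id, table, parameter, g)
            prev = _event_value(e, e.prev_segment_id, table, parameter, g)
            series.append(e, raw=cur, delta=cur - prev)
        else:
            if e.next_segment_id is None:
                log.info("route %s: DP at %.1fs has unknown future segment; skipped",
                         schedule.route.id, e.onset)
                continue
            fut = _event_value(e, e.next_segment_id, table, parameter, g)
            cur = _event_value(e, e.segment_id, table, parameter, g)
            series.append(e, raw=fut, delta=fut - cur)
    return series


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def schedules_to_frame(schedules: list[RouteEventSchedule]) -> pd.DataFrame:
    """Flatten schedules to the exported TSV layout."""
    rows = []
    for sched in schedules:
        for e in sched.events:
            rows.append(
                {
                    "route_id": sched.route.id,
                    "event_type": e.type,
                    "onset_s": e.onset,
                    "duration_s": e.duration,
                    "segment_id": e.segment_id,
                    "prev_segment_id": e.prev_segment_id or "",
                    "goal_id": e.goal_id or "",
                    "is_detour": "" if e.is_detour is None else int(e.is_detour),
                }
            )
    return pd.DataFrame(rows)


def read_route_json(path_or_obj) -> list[Route]:
    """Route file: a single object or a list of
    ``{"id","condition","segments":[...],"goals":[{"at_index","goal_segment"}]}``."""
    if isinstance(path_or_obj, (dict, list)):
        obj = path_or_obj
    else:
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    if isinstance(obj, dict):
        obj = [obj]
    return [
        Route(
            id=str(r["id"]),
            ordered_segment_ids=tuple(r["segments"]),
            goal_changes=tuple((int(gc["at_index"]), gc["goal_segment"]) for gc in r["goals"]),
            condition=r.get("condition", "navigation"),
        )
        for r in obj
    ]


def write_route_json(routes: list[Route], path) -> None:
    obj = [
        {
            "id": r.id,
            "condition": r.condition,
            "segments": list(r.ordered_segment_ids),
            "goals": [{"at_index": i, "goal_segment": gid} for i, gid in r.goal_changes],
        }
        for r in routes
    ]
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
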