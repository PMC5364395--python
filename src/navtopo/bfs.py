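"""Breadth-first-search planning demand at detours.

When a forced detour invalidates the planned route, re-planning is modelled
as a breadth-first search over the street network seen as a decision tree:
level 1 covers every segment reachable at the junction immediately ahead,
level 2 additionally covers the segments at the next junction along the
optimal (shortest step-depth) path to the goal.  The demand score is the sum
of a chosen centrality (degree by default; closeness or betweenness as
variants) over the segments in the searched layer(s).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .network import DualGraph, NetworkError
from .routes import RouteEventSchedule

log = logging.getLogger(__name__)

__all__ = ["bfs_demand_level1", "bfs_demand_level2", "demand_series"]

CENTRALITY_KINDS = ("degree", "closeness", "betweenness")


def _layer_sum(
    g: DualGraph, junction: str, exclude: str, table: pd.DataFrame, kind: str
) -> float:
    options = sorted(g.junction_segments(junction) - {exclude})
    return float(sum(table.at[s, kind] for s in options))


def bfs_demand_level1(
    g: DualGraph,
    current: str,
    came_from: str | None,
    table: pd.DataFrame,
    kind: str = "degree",
    include_current: bool = False,
) -> float:
    """Level-1 demand: summed centrality of the segments at the junction ahead.

    The currently occupied segment is excluded by default (the traveller does
    not re-plan the street they stand on); ``include_current=True`` adds it.
    A dead end ahead (no other incident segment) is an error.
    """
    if kind not in CENTRALITY_KINDS:
        raise ValueError(f"kind must be one of {CENTRALITY_KINDS}")
    ahead = g.ahead_junction(current, came_from)
    options = g.junction_segments(ahead) - {current}
    if not options:
        raise NetworkError(f"segment {current!r} dead-ends at junction {ahead!r}")
    value = _layer_sum(g, ahead, current, table, kind)
    if include_current:
        value += float(table.at[current, kind])
    return value


def bfs_demand_level2(
    g: DualGraph,
    current: str,
    came_from: str | None,
    goal: str,
    table: pd.DataFrame,
    kind: str = "degree",
    include_current: bool = False,
) -> float:
    """Level-1 plus the layer at the next junction on the optimal path to the goal.

    The optimal path is the shortest dual path from *current* to *goal*, ties
    broken lexicographically by segment id.  When the goal is the immediate
    next segment there is no subsequent junction and the value equals the
    level-1 demand.
    """
    level1 = bfs_demand_level1(g, current, came_from, table, kind, include_current)
    if goal not in g:
        raise NetworkError(f"unknown goal segment {goal!r}")
    path = _lexicographic_shortest_path(g, current, goal)
    if len(path) < 2:
        return level1  # already at the goal
    nxt = path[1]
    if nxt == goal:
        return level1  # goal adjacent: no subsequent junction to search
    ahead = g.ahead_junction(current, came_from)
    far = g.ahead_junction(nxt, came_from=current) if ahead in g.endpoint_junctions(nxt) else None
    if far is None:
        # nxt does not hang off the immediate junction (possible when the
        # optimal first move is behind us); use its far end w.r.t. current
        far = g.ahead_junction(nxt, came_from=current)
    return level1 + _layer_sum(g, far, nxt, table, kind)


def _lexicographic_shortest_path(g: DualGraph, source: str, target: str) -> list[str]:
    """Shortest path choosing, at equal depth, the lexicographically smallest
    predecessor chain; deterministic among tied geodesics."""
    if source == target:
        return [source]
    dist = nx.single_source_shortest_path_length(g.nx_graph, target)
    if source not in dist:
        raise NetworkError(f"goal {target!r} unreachable from {source!r}")
    path = [source]
    node = source
    while node != target:
        nxt = min(n for n in g.neighbors(node) if dist[n] == dist[node] - 1)
        path.append(nxt)
        node = nxt
    return path


def demand_series(
    schedule: RouteEventSchedule,
    g: DualGraph,
    table: pd.DataFrame,
    kind: str = "degree",
    level: str = "one",
) -> tuple[list, list[float]]:
    """Per-detour demand values, aligned to the detour street-entry events.

    ``level`` is ``'one'`` or ``'one_plus_two'``.  The schedule must already
    carry detour flags (see :func:`navtopo.routes.classify_detours`).
    Returns ``(events, values)``.
    """
    if level not in ("one", "one_plus_two"):
        raise ValueError("level must be 'one' or 'one_plus_two'")
    events, values = [], []
    for e in schedule.of_type("street_entry"):
        if e.is_detour is None:
            raise ValueError("schedule not classified for detours")
        if not e.is_detour:
            continue
        if level == "one":
            v = bfs_demand_level1(g, e.segment_id, e.prev_segment_id, table, kind)
        else:
            v = bfs_demand_level2(g, e.segment_id, e.prev_segment_id, e.goal_id, table, kind)
        events.append(e)
        values.append(v)
    return events, values


def demand_frame(
    schedules: list[RouteEventSchedule],
    g: DualGraph,
    table: pd.DataFrame,
    kinds: tuple[str, ...] = CENTRALITY_KINDS,
    levels: tuple[str, ...] = ("one", "one_plus_two"),
) -> pd.DataFrame:
    """Long-format demand table for export (route, onset, level, kind, demand)."""
    rows = []
    for sched in schedules:
        for kind in kinds:
            for level in levels:
                events, values = demand_series(sched, g, table, kind, level)
                for e, v in zip(events, values):
                    rows.append(
                        {
                            "route_id": sched.route.id,
                            "event_onset_s": e.onset,
                            "level": level,
                            "centrality_kind": kind,
                            "demand": v,
                        }
                    )
    return pd.DataFrame(rows)
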