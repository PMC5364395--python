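"""Street networks, dual (segment) graphs and space-syntax centrality.

A street network is held in two forms.  The *primal* form mirrors the map:
junctions are nodes and street segments run between them.  Space-syntax
analysis works on the *dual* form: each street segment becomes a node and
two segments are linked iff they share a junction.  All centrality measures
(degree, closeness, betweenness) and step depths are computed on the dual
graph with unit-weight (topological) steps; metric distance in meters is a
separate operation used only for path-distance covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Junction",
    "StreetSegment",
    "PrimalNetwork",
    "DualGraph",
    "CentralityTable",
    "build_dual_graph",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "step_depth",
    "step_depth_to_boundary",
    "metric_path_distance",
    "centrality_table",
    "read_network_json",
    "write_network_json",
    "read_geojson_linestrings",
]


class NetworkError(ValueError):
    """Structural problem in a street network (bad reference, disconnection)."""


@dataclass(frozen=True)
class Junction:
    """A street intersection; node of the primal graph."""

    id: str
    incident_segment_ids: frozenset[str] = frozenset()
    x: float | None = None
    y: float | None = None


@dataclass(frozen=True)
class StreetSegment:
    """A stretch of a named street between two junctions; node of the dual graph."""

    id: str
    name: str
    endpoint_junctions: tuple[str, str]
    length: float
    width: float | None = None
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NetworkError(f"segment {self.id!r}: length must be > 0, got {self.length}")
        if self.width is not None and self.width < 0:
            raise NetworkError(f"segment {self.id!r}: width must be >= 0")


@dataclass
class PrimalNetwork:
    """Junction-node street network plus the set of study-boundary segments."""

    junctions: dict[str, Junction]
    segments: dict[str, StreetSegment]
    boundary_segment_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.boundary_segment_ids = frozenset(self.boundary_segment_ids)
        self.validate()

    def validate(self) -> None:
        for seg in self.segments.values():
            for j in seg.endpoint_junctions:
                if j not in self.junctions:
                    raise NetworkError(
                        f"segment {seg.id!r} references unknown junction {j!r}"
                    )
        for jn in self.junctions.values():
            for s in jn.incident_segment_ids:
                if s not in self.segments:
                    raise NetworkError(
                        f"junction {jn.id!r} references unknown segment {s!r}"
                    )
        for b in self.boundary_segment_ids:
            if b not in self.segments:
                raise NetworkError(f"boundary segment {b!r} not in network")

    @classmethod
    def from_segments(
        cls,
        segments: Iterable[StreetSegment],
        boundary_segment_ids: Iterable[str] = (),
        junction_coords: Mapping[str, tuple[float, float]] | None = None,
    ) -> "PrimalNetwork":
        """Build the network, deriving junction incidence from segment endpoints."""
        segs = {s.id: s for s in segments}
        incident: dict[str, set[str]] = {}
        for s in segs.values():
            for j in s.endpoint_junctions:
                incident.setdefault(j, set()).add(s.id)
        coords = junction_coords or {}
        junctions = {
            j: Junction(
                j,
                frozenset(ids),
                x=coords.get(j, (None, None))[0],
                y=coords.get(j, (None, None))[1],
            )
            for j, ids in incident.items()
        }
        return cls(junctions, segs, frozenset(boundary_segment_ids))


class DualGraph:
    """Segment-node graph: nodes are segment ids, edges join segments sharing a junction.

    Retains the primal incidence (segment -> endpoint junctions,
    junction -> incident segments) so junction-local queries such as
    breadth-first-search planning demand remain possible.
    """

    def __init__(self, graph: nx.Graph, net: PrimalNetwork):
        self._g = graph
        self._net = net

    @property
    def nx_graph(self) -> nx.Graph:
        return self._g

    @property
    def primal(self) -> PrimalNetwork:
        return self._net

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def neighbors(self, segment_id: str) -> list[str]:
        self._check(segment_id)
        return list(self._g.neighbors(segment_id))

    def endpoint_junctions(self, segment_id: str) -> tuple[str, str]:
        self._check(segment_id)
        return self._net.segments[segment_id].endpoint_junctions

    def junction_segments(self, junction_id: str) -> frozenset[str]:
        return self._net.junctions[junction_id].incident_segment_ids

    def shared_junctions(self, a: str, b: str) -> set[str]:
        return set(self.endpoint_junctions(a)) & set(self.endpoint_junctions(b))

    def ahead_junction(self, current: str, came_from: str | None) -> str:
        """Junction at the far end of *current*, given the segment arrived from.

        With no predecessor the junction of higher incident count is returned
        (arbitrary but deterministic is not needed there; callers in the route
        pipeline always have a predecessor).
        """
        j1, j2 = self.endpoint_junctions(current)
        if came_from is None:
            return j2
        shared = self.shared_junctions(current, came_from)
        if not shared:
            raise NetworkError(f"segments {current!r} and {came_from!r} share no junction")
        behind = min(shared)  # deterministic if a pair shares two junctions
        if j1 == behind and j2 != behind:
            return j2
        if j2 == behind and j1 != behind:
            return j1
        # current is a loop or both endpoints shared; fall back to the other one
        return j2 if j1 == behind else j1

    def _check(self, segment_id: str) -> None:
        if segment_id not in self._g:
            raise NetworkError(f"unknown segment id {segment_id!r}")


def build_dual_graph(net: PrimalNetwork) -> DualGraph:
    """Dual-graph construction: one node per segment, one edge per co-incident pair.

    Multiple shared junctions between the same two segments still yield a
    single edge; self-edges never arise.  Raises if the result is not one
    connected component (centralities would be undefined).
    """
    net.validate()
    g = nx.Graph()
    g.add_nodes_from(net.segments)
    for jn in net.junctions.values():
        ids = sorted(jn.incident_segment_ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                g.add_edge(a, b)
    if g.number_of_nodes() and not nx.is_connected(g):
        smallest = min(nx.connected_components(g), key=lambda c: (len(c), min(c)))
        raise NetworkError(
            f"street network is disconnected; smallest component: {sorted(smallest)}"
        )
    return DualGraph(g, net)


def degree_centrality(g: DualGraph, segment_id: str) -> int:
    """Number of street segments connected to *segment_id* in the dual graph."""
    g._check(segment_id)
    return g.nx_graph.degree(segment_id)


def closeness_centrality(g: DualGraph, segment_id: str, normalized: bool = False) -> float:
    """Reciprocal of the summed topological distance to all other segments.

    With ``normalized=True`` the conventional (n-1)/sum(d) form is returned
    instead of the raw 1/sum(d); both induce the same ranking and the same
    sign of any change, which is all the downstream regressors use.
    """
    g._check(segment_id)
    dists = nx.single_source_shortest_path_length(g.nx_graph, segment_id)
    if len(dists) != len(g):
        raise NetworkError("dual graph is disconnected: closeness undefined")
    total = sum(dists.values())
    if total == 0:
        raise NetworkError("closeness undefined for a single-segment network")
    return (len(g) - 1) / total if normalized else 1.0 / total


def betweenness_centrality(g: DualGraph, segment_id: str) -> float:
    """Freeman betweenness: sum over unordered pairs of the geodesic fraction through the node.

    Endpoints are excluded (the segment must lie strictly inside the path) and
    each unordered pair is counted once.
    """
    g._check(segment_id)
    return _betweenness_all(g)[segment_id]


def _betweenness_all(g: DualGraph) -> dict[str, float]:
    return nx.betweenness_centrality(g.nx_graph, normalized=False)


def step_depth(g: DualGraph, from_id: str, to_id: str) -> int:
    """Topological distance: number of junction crossings on the shortest dual path."""
    g._check(from_id)
    g._check(to_id)
    try:
        return nx.shortest_path_length(g.nx_graph, from_id, to_id)
    except nx.NetworkXNoPath as exc:  # pragma: no cover - connectivity enforced at build
        raise NetworkError(f"no path between {from_id!r} and {to_id!r}") from exc


def step_depth_to_boundary(
    g: DualGraph, segment_id: str, boundary: Iterable[str] | None = None
) -> int:
    """Minimum step depth from *segment_id* to any study-boundary segment."""
    boundary = frozenset(boundary if boundary is not None else g.primal.boundary_segment_ids)
    if not boundary:
        raise NetworkError("boundary segment set is empty")
    g._check(segment_id)
    if segment_id in boundary:
        return 0
    # single multi-source BFS from the boundary
    dists = nx.multi_source_dijkstra_path_length(g.nx_graph, set(boundary), weight=None)
    if segment_id not in dists:
        raise NetworkError(f"segment {segment_id!r} cannot reach the boundary")
    return int(dists[segment_id])


def metric_path_distance(net: PrimalNetwork, g: DualGraph, from_id: str, to_id: str) -> float:
    """Metric length in meters of the shortest dual path, weighting each
    traversed segment by its length; the origin segment is not counted, the
    destination is.  Returns 0.0 for identical segments."""
    g._check(from_id)
    g._check(to_id)
    if from_id == to_id:
        return 0.0
    dg = nx.DiGraph()
    for a, b in g.nx_graph.edges:
        dg.add_edge(a, b, weight=net.segments[b].length)
        dg.add_edge(b, a, weight=net.segments[a].length)
    try:
        return float(nx.dijkstra_path_length(dg, from_id, to_id))
    except nx.NetworkXNoPath as exc:  # pragma: no cover
        raise NetworkError(f"no path between {from_id!r} and {to_id!r}") from exc


def centrality_table(g: DualGraph, normalized_closeness: bool = False) -> pd.DataFrame:
    """Per-segment centrality table (CentralityTable).

    Columns: degree, closeness, betweenness, step_depth_to_boundary (the last
    only when the network declares boundary segments), plus every segment
    covariate present on the primal segments.  Indexed by segment id.
    """
    gx = g.nx_graph
    n = len(g)
    closeness = {}
    for s in gx.nodes:
        dists = nx.single_source_shortest_path_length(gx, s)
        total = sum(dists.values())
        closeness[s] = ((n - 1) / total) if normalized_closeness else (1.0 / total)
    between = _betweenness_all(g)
    rows = {
        s: {
            "degree": gx.degree(s),
            "closeness": closeness[s],
            "betweenness": between[s],
        }
        for s in gx.nodes
    }
    boundary = g.primal.boundary_segment_ids
    if boundary:
        bdists = nx.multi_source_dijkstra_path_length(gx, set(boundary), weight=None)
        for s in rows:
            rows[s]["step_depth_to_boundary"] = int(bdists[s])
    for s, seg in g.primal.segments.items():
        if seg.width is not None:
            rows[s]["street_width"] = seg.width
        rows[s]["street_length"] = seg.length
        for k, v in seg.covariates.items():
            rows[s][k] = v
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "segment_id"
    return table


def write_centrality_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# I/O: documented network JSON schema and the optional GeoJSON reader
# ---------------------------------------------------------------------------

def read_network_json(path_or_obj) -> PrimalNetwork:
    """Read the network JSON schema.

    Schema::

        {"junctions":  [{"id", "x", "y"}, ...],            # x/y optional
         "segments":   [{"id", "name", "junctions": [j1, j2],
                         "length_m", "width_m", "covariates": {...}}, ...],
         "boundary_segments": [...]}
    """
    if isinstance(path_or_obj, dict):
        obj = path_or_obj
    else:
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    coords = {
        j["id"]: (j.get("x"), j.get("y")) for j in obj.get("junctions", [])
    }
    segments = [
        StreetSegment(
            id=s["id"],
            name=s.get("name", s["id"]),
            endpoint_junctions=(s["junctions"][0], s["junctions"][1]),
            length=float(s["length_m"]),
            width=float(s["width_m"]) if s.get("width_m") is not None else None,
            covariates=dict(s.get("covariates", {})),
        )
        for s in obj["segments"]
    ]
    net = PrimalNetwork.from_segments(
        segments, obj.get("boundary_segments", ()), junction_coords=coords
    )
    # declared junctions may add coordinates for junctions already derived
    return net


def write_network_json(net: PrimalNetwork, path) -> None:
    obj = {
        "junctions": [
            {"id": j.id, **({"x": j.x, "y": j.y} if j.x is not None else {})}
            for j in sorted(net.junctions.values(), key=lambda j: j.id)
        ],
        "segments": [
            {
                "id": s.id,
                "name": s.name,
                "junctions": list(s.endpoint_junctions),
                "length_m": s.length,
                **({"width_m": s.width} if s.width is not None else {}),
                **({"covariates": dict(s.covariates)} if s.covariates else {}),
            }
            for s in sorted(net.segments.values(), key=lambda s: s.id)
        ],
        "boundary_segments": sorted(net.boundary_segment_ids),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_geojson_linestrings(path_or_obj, tolerance: float = 1e-6) -> PrimalNetwork:
    """Build a network from a GeoJSON FeatureCollection of LineStrings.

    Each feature becomes one segment; endpoints within *tolerance* of one
    another are snapped to a common junction.  Lengths are planar unless a
    ``length_m`` property is given.
    """
    import math

    if isinstance(path_or_obj, dict):
        obj = path_or_obj
    else:
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    snapped: list[tuple[float, float]] = []

    def snap(pt: tuple[float, float]) -> int:
        for i, q in enumerate(snapped):
            if abs(q[0] - pt[0]) <= tolerance and abs(q[1] - pt[1]) <= tolerance:
                return i
        snapped.append(pt)
        return len(snapped) - 1

    segments = []
    coords: dict[str, tuple[float, float]] = {}
    for k, feat in enumerate(obj["features"]):
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            continue
        pts = geom["coordinates"]
        j1 = snap((pts[0][0], pts[0][1]))
        j2 = snap((pts[-1][0], pts[-1][1]))
        props = feat.get("properties") or {}
        length = props.get("length_m")
        if length is None:
            length = sum(
                math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1)
            )
        sid = str(props.get("id", f"seg{k}"))
        segments.append(
            StreetSegment(
                id=sid,
                name=str(props.get("name", sid)),
                endpoint_junctions=(f"j{j1}", f"j{j2}"),
                length=float(length),
                covariates={
                    k2: float(v)
                    for k2, v in props.items()
                    if isinstance(v, (int, float)) and k2 not in ("length_m",)
                },
            )
        )
        coords[f"j{j1}"] = snapped[j1]
        coords[f"j{j2}"] = snapped[j2]
    return PrimalNetwork.from_segments(segments, junction_coords=coords)
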