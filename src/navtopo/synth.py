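"""Synthetic street networks, routes and ROI BOLD with known ground truth.

The generator emulates the study conditions of a dense-urban navigation
experiment: a dense historic district of ~26 named streets subdivided into
segments, 10 routes (half navigation, half control) traversed at walking
speed 1.6 m/s lasting 198-325 s each, roughly half of all street entries
being forced detours, and per-subject ROI BOLD time series built as
design x beta plus AR(1) noise.  Every generator is a pure function of its
spec and seed, so any pipeline stage can be tested bit-reproducibly without
external data.

The street network is a perturbed Manhattan-like lattice, not a replica of
any real map: half the streets run one way, half the other, junctions at
every crossing, a fraction of inter-junction segments deleted and a few
diagonals added.  This produces the qualitative features the analysis
needs - dual-degree variance spanning roughly 2..6+ and a closeness gradient
from boundary to center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import glm as glm_mod
from .bfs import demand_frame
from .network import (
    DualGraph,
    PrimalNetwork,
    StreetSegment,
    build_dual_graph,
    centrality_table,
    write_network_json,
)
from .routes import (
    Route,
    RouteEventSchedule,
    TimingConfig,
    classify_detours,
    compute_modulator,
    schedule_route,
    schedules_to_frame,
    write_route_json,
)

__all__ = [
    "NetworkSpec",
    "SimulationSpec",
    "SyntheticDataset",
    "generate_network",
    "generate_routes",
    "generate_bold",
    "generate_dataset",
    "simulate_observer",
    "chance_level_accuracy",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the perturbed-grid street network generator.

    The lattice is densified toward its center: segment deletions become
    more likely toward the study-area edge and multi-way star junctions
    (plaza-style intersections where 6-8 streets meet) are seeded
    preferentially in the core.  This reproduces the qualitative signature
    of a dense historic district - high degree variance, a closeness and
    betweenness gradient toward the center, and hub junctions - rather than
    a homogeneous Manhattan grid.
    """

    n_streets: int = 26
    deletion_p_center: float = 0.02
    deletion_p_edge: float = 0.12
    star_p_center: float = 0.45  # per interior junction at the exact center
    star_p_edge: float = 0.0
    star_spoke_p: float = 0.8  # each of the 4 diagonal spokes of a star
    n_courts: int = 3  # cul-de-sac courts: short dead-end chains off a junction
    court_length: int = 3  # segments per court (the middle ones have dual degree 2)
    segment_length_mean: float = 52.0  # meters; dense urban block scale
    segment_length_sd: float = 15.0
    segment_length_bounds: tuple[float, float] = (25.0, 110.0)
    seed: int = 0


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions of the simulated experiment."""

    n_subjects: int = 24
    n_routes: int = 10  # alternating navigation / control
    tr: float = 2.897  # seconds per scan
    walking_speed: float = 1.6  # m/s
    duration_range: tuple[float, float] = (198.0, 325.0)
    detour_fraction: float = 0.5
    goal_depth_range: tuple[int, int] = (4, 8)
    fixation_s: float = 12.0
    cue_s: float = 5.0
    rho: float = 0.3  # AR(1) coefficient of the BOLD noise
    sigma: float = 1.0  # marginal noise standard deviation
    effect_size: float = 1.0  # group-level d of injected modulator effects
    between_subject_sd: float = 0.5  # sd of true subject betas
    rois: tuple[str, ...] = (
        "right_posterior_hippocampus",
        "lateral_pfc",
        "parietal_control",
    )
    # roi -> design column -> (mean_beta, sd_beta); None -> built from
    # effect_size/between_subject_sd defaults at dataset generation time
    effects: dict | None = None
    base_betas: dict = field(
        default_factory=lambda: {
            "task": 0.5,
            "street_entry": 0.3,
            "new_goal": 0.5,
            "decision_point": 0.3,
            "travel_period": 0.0,
        }
    )

    def default_effects(self) -> dict[str, dict[str, tuple[float, float]]]:
        """Ground-truth effect map: the hippocampal ROI carries the
        navigation street-entry degree-change effect, the prefrontal ROI the
        navigation BFS planning-demand effect, the third ROI nothing."""
        if self.effects is not None:
            return self.effects
        mu = self.effect_size * self.between_subject_sd
        sd = self.between_subject_sd
        return {
            "right_posterior_hippocampus": {
                "navigation_street_entry_x_degree_cat": (mu, sd)
            },
            "lateral_pfc": {"navigation_street_entry_x_bfs_degree_raw": (mu, sd)},
            "parietal_control": {},
        }


# ---------------------------------------------------------------------------
# street network
# ---------------------------------------------------------------------------

def generate_network(spec: NetworkSpec) -> PrimalNetwork:
    """Perturbed-grid street network; deterministic per spec (incl. seed)."""
    if spec.n_streets < 4:
        raise ValueError(f"need at least 4 streets for a grid, got {spec.n_streets}")
    rng = np.random.default_rng(spec.seed)
    n_h = spec.n_streets // 2
    n_v = spec.n_streets - n_h
    lo, hi = spec.segment_length_bounds

    def draw_length() -> float:
        return float(
            np.clip(rng.normal(spec.segment_length_mean, spec.segment_length_sd), lo, hi)
        )

    segs: dict[str, StreetSegment] = {}

    def add(sid: str, name: str, j1: str, j2: str) -> None:
        segs[sid] = StreetSegment(
            id=sid, name=name, endpoint_junctions=(j1, j2), length=draw_length()
        )

    def radial(r: float, c: float) -> float:
        """0 at the lattice center, 1 at its corners (Chebyshev)."""
        cr, cc = (n_h - 1) / 2.0, (n_v - 1) / 2.0
        return max(abs(r - cr) / max(cr, 1), abs(c - cc) / max(cc, 1))

    for r in range(n_h):
        for c in range(n_v - 1):
            add(f"h{r}_{c}", f"East Street {r}", f"j{r}_{c}", f"j{r}_{c + 1}")
    for c in range(n_v):
        for r in range(n_h - 1):
            add(f"v{c}_{r}", f"North Street {c}", f"j{r}_{c}", f"j{r + 1}_{c}")

    # position-dependent deletions that keep the segment (dual) graph connected
    def seg_graph(current: dict[str, StreetSegment]) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(current)
        by_junction: dict[str, list[str]] = {}
        for s in current.values():
            for j in s.endpoint_junctions:
                by_junction.setdefault(j, []).append(s.id)
        for ids in by_junction.values():
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    g.add_edge(a, b)
        return g

    def seg_radial(seg: StreetSegment) -> float:
        coords = [tuple(int(x) for x in j[1:].split("_")) for j in seg.endpoint_junctions]
        return sum(radial(r, c) for r, c in coords) / 2.0

    p0, p1 = spec.deletion_p_center, spec.deletion_p_edge
    for sid in sorted(segs):
        if rng.random() < p0 + (p1 - p0) * seg_radial(segs[sid]):
            trial = dict(segs)
            del trial[sid]
            g = seg_graph(trial)
            if g.number_of_nodes() and nx.is_connected(g):
                segs = trial

    # star junctions: diagonal spokes turn a crossing into a 6-8 way plaza
    n_spoke = 0
    s0, s1 = spec.star_p_center, spec.star_p_edge
    for r in range(1, n_h - 1):
        for c in range(1, n_v - 1):
            if rng.random() < s0 + (s1 - s0) * radial(r, c):
                for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
                    if rng.random() < spec.star_spoke_p:
                        add(f"s{n_spoke}", f"Star Court {n_spoke}",
                            f"j{r}_{c}", f"j{r + dr}_{c + dc}")
                        n_spoke += 1

    # cul-de-sac courts: a short chain hanging off a grid junction gives the
    # network its low-degree tail (the final segment has dual degree 1, the
    # middle ones 2), like the yards and courts of a dense historic district
    grid_junctions = sorted({j for s in segs.values() for j in s.endpoint_junctions})
    coords = {f"j{r}_{c}": (float(c), float(r)) for r in range(n_h) for c in range(n_v)}
    court_dirs = ((0.22, 0.28), (-0.25, 0.22), (0.24, -0.24), (-0.22, -0.27))
    for q in range(spec.n_courts):
        host = grid_junctions[int(rng.integers(len(grid_junctions)))]
        dx, dy = court_dirs[q % len(court_dirs)]
        hx, hy = coords[host]
        prev = host
        for step in range(spec.court_length):
            nxt = f"court{q}_{step}"
            add(f"c{q}_{step}", f"Yard {q}", prev, nxt)
            coords[nxt] = (hx + dx * (step + 1), hy + dy * (step + 1))
            prev = nxt

    boundary = {
        s.id
        for s in segs.values()
        if any(_is_perimeter(j, n_h, n_v) for j in s.endpoint_junctions)
    }
    net = PrimalNetwork.from_segments(
        segs.values(),
        boundary_segment_ids=boundary,
        junction_coords=coords,
    )
    build_dual_graph(net)  # raises if somehow disconnected
    return net


def _is_perimeter(junction_id: str, n_h: int, n_v: int) -> bool:
    if not junction_id.startswith("j"):
        return False  # court junctions are never on the study perimeter
    r, c = (int(x) for x in junction_id[1:].split("_"))
    return r in (0, n_h - 1) or c in (0, n_v - 1)


# ---------------------------------------------------------------------------
# routes
# ---------------------------------------------------------------------------

def generate_routes(
    g: DualGraph,
    sim: SimulationSpec,
    rng: np.random.Generator,
    timing: TimingConfig | None = None,
) -> list[Route]:
    """Sample routes that generally follow the optimal path but take forced
    detours at a controlled rate.

    Detour decisions use error-diffusion dithering so the realized fraction
    of non-improving street entries stays within ~2 events of the target
    across the whole route set.  Expected durations (at jitter midpoints)
    are kept well inside the stated range so the realized, jittered
    schedules respect it.
    """
    timing = timing or TimingConfig(walking_speed=sim.walking_speed)
    segments = g.primal.segments
    ids = sorted(segments)
    gx = g.nx_graph
    dist_cache: dict[str, dict[str, int]] = {}

    def dist_to(goal: str) -> dict[str, int]:
        if goal not in dist_cache:
            dist_cache[goal] = nx.single_source_shortest_path_length(gx, goal)
        return dist_cache[goal]

    lo_d, hi_d = sim.duration_range
    jit_mid = sum(timing.dp_entry_jitter) / 2
    start_mid = sum(timing.start_jitter) / 2
    margin = 20.0  # keep expected duration this far inside the stated range
    routes: list[Route] = []
    detours_done = 0
    entries_done = 0
    for k in range(sim.n_routes):
        for _attempt in range(200):
            r = _sample_route_walk(
                g, ids, sim, rng, timing, dist_to,
                target_duration=float(rng.uniform(lo_d + margin + 10, hi_d - margin)),
                jit_mid=jit_mid, start_mid=start_mid,
                detour_state=[detours_done, entries_done],
            )
            if r is not None:
                walk, goals, d_count, e_count = r
                # accept only if the running detour fraction stays on target
                # (tolerance tightens as entries accumulate)
                cum_e = entries_done + e_count
                cum_d = detours_done + d_count
                tol = max(0.025, 0.6 / cum_e)
                if abs(cum_d / cum_e - sim.detour_fraction) > tol:
                    continue
                detours_done += d_count
                entries_done += e_count
                routes.append(
                    Route(
                        id=f"route{k:02d}",
                        ordered_segment_ids=tuple(walk),
                        goal_changes=tuple(goals),
                        condition="navigation" if k % 2 == 0 else "control",
                    )
                )
                break
        else:
            raise RuntimeError(f"could not sample route {k} after 200 attempts")
    return routes


def _sample_route_walk(g, ids, sim, rng, timing, dist_to, target_duration,
                       jit_mid, start_mid, detour_state):
    """One candidate walk; returns (segments, goal_changes, n_detours, n_entries)."""
    segments = g.primal.segments
    speed = timing.walking_speed
    lo_depth, hi_depth = sim.goal_depth_range
    start = ids[rng.integers(len(ids))]
    goal = _draw_goal(g, start, rng, lo_depth, hi_depth, dist_to)
    if goal is None:
        return None
    # head in a direction from which the goal can be approached
    d0 = dist_to(goal)
    j1, j2 = segments[start].endpoint_junctions
    headings = [j1, j2] if rng.random() < 0.5 else [j2, j1]
    behind = headings[0]
    for b in headings:
        ahead0 = j2 if b == j1 else j1
        opts = g.junction_segments(ahead0) - {start}
        if any(d0[c] < d0[start] for c in opts):
            behind = b
            break
    walk = [start]
    goals = [(0, goal)]
    est = start_mid + timing.nge_duration
    detours, entries = detour_state
    d_new = e_new = 0
    cur = start
    while est < target_duration:
        ahead = next(
            (j for j in segments[cur].endpoint_junctions if j != behind),
            segments[cur].endpoint_junctions[1],
        )
        cands = sorted(g.junction_segments(ahead) - {cur})
        # never walk into a dead end (its far junction offers no options and
        # no planning-demand layer), except to finish at the goal
        cands = [
            c for c in cands
            if c == goal or len(
                g.junction_segments(_far_junction(g, c, ahead)) - {c}
            ) > 0
        ]
        if not cands:
            return None  # dead end; resample the route
        d = dist_to(goal)
        improving = [c for c in cands if d[c] < d[cur]]
        worsening = [c for c in cands if d[c] >= d[cur]]
        err = sim.detour_fraction * (entries + e_new + 1) - (detours + d_new)
        want_detour = rng.random() < np.clip(err, 0.0, 1.0)
        if want_detour and worsening:
            # prefer sideways moves (equal depth): the walk recovers quickly
            sideways = [c for c in worsening if d[c] == d[cur]]
            pool = sideways if sideways else worsening
            nxt = pool[int(rng.integers(len(pool)))]
        elif improving:
            nxt = improving[int(rng.integers(len(improving)))]
        else:
            # no improving option ahead: take the least-worsening one
            best = min(d[c] for c in worsening)
            pool = [c for c in worsening if d[c] == best]
            nxt = pool[int(rng.integers(len(pool)))]
        e_new += 1
        if d[nxt] >= d[cur]:
            d_new += 1
        est += segments[cur].length / speed + timing.dp_duration + jit_mid
        walk.append(nxt)
        behind = ahead
        cur = nxt
        if cur == goal:
            goal = _draw_goal(g, cur, rng, lo_depth, hi_depth, dist_to,
                              behind=behind)
            if goal is None:
                return None
            goals.append((len(walk) - 1, goal))
            est += timing.street_text_duration + timing.nge_duration
    est += segments[cur].length / speed
    lo_d, hi_d = sim.duration_range
    if len(walk) < 3 or not (lo_d + 15 <= est <= hi_d - 15):
        return None
    return walk, goals, d_new, e_new


def _far_junction(g, segment, near_junction):
    j1, j2 = g.primal.segments[segment].endpoint_junctions
    return j2 if near_junction == j1 else j1


def _draw_goal(g, from_segment, rng, lo_depth, hi_depth, dist_to, behind=None):
    d = dist_to(from_segment)
    cands = sorted(s for s, dd in d.items() if lo_depth <= dd <= hi_depth)
    if not cands:
        return None
    if behind is not None:
        # prefer goals that can be approached without turning around
        segs = g.primal.segments
        j1, j2 = segs[from_segment].endpoint_junctions
        ahead = j2 if behind == j1 else j1
        opts = g.junction_segments(ahead) - {from_segment}
        forward = [
            c for c in cands
            if any(dist_to(c)[o] < dist_to(c)[from_segment] for o in opts)
        ]
        if forward:
            cands = forward
    return cands[int(rng.integers(len(cands)))]


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

def generate_bold(
    design: glm_mod.DesignMatrix,
    beta,
    rho: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """y = X beta + AR(1) noise with marginal standard deviation *sigma*.

    *beta* may be a vector (one series) or a (n_columns, n_rois) matrix.
    The noise process is stationary: x_0 ~ N(0, sigma^2),
    x_t = rho x_{t-1} + sqrt(1-rho^2) sigma e_t.
    """
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    beta = np.asarray(beta, dtype=float)
    squeeze = beta.ndim == 1
    if squeeze:
        beta = beta[:, None]
    X = design.values()
    if beta.shape[0] != X.shape[1]:
        raise ValueError(f"beta has {beta.shape[0]} rows, design has {X.shape[1]} columns")
    n, r = X.shape[0], beta.shape[1]
    e = rng.standard_normal((n, r))
    noise = np.empty((n, r))
    noise[0] = sigma * e[0]
    scale = sigma * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        noise[t] = rho * noise[t - 1] + scale * e[t]
    y = X @ beta + noise
    return y[:, 0] if squeeze else y


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one simulated experiment produced, plus its ground truth."""

    net: PrimalNetwork
    dual: DualGraph
    table: pd.DataFrame
    routes: list[Route]
    schedules: list[RouteEventSchedule]
    session: glm_mod.Session
    design: glm_mod.DesignMatrix  # the generating (superset) design
    bold: list[pd.DataFrame]  # one (scans x rois) frame per subject
    truth: pd.DataFrame  # subject, roi, column, beta
    network_spec: NetworkSpec
    sim_spec: SimulationSpec
    seed: int

    def write_all(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_network_json(self.net, out / "network.json")
        write_route_json(self.routes, out / "routes.json")
        self.table.to_csv(out / "centrality.tsv", sep="\t")
        schedules_to_frame(self.schedules).to_csv(out / "schedules.tsv", sep="\t", index=False)
        demand_frame(self.schedules, self.dual, self.table).to_csv(
            out / "bfs_demand.tsv", sep="\t", index=False
        )
        self.design.to_tsv(out / "design.tsv")
        for i, y in enumerate(self.bold):
            y.to_csv(out / f"bold_sub{i:02d}.tsv", sep="\t", index_label="scan")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def generate_dataset(
    network_spec: NetworkSpec | None = None,
    sim_spec: SimulationSpec | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Run the full forward model: network -> centrality -> routes ->
    schedules -> session design -> per-subject BOLD."""
    sim = sim_spec or SimulationSpec()
    nspec = network_spec or NetworkSpec(seed=seed)
    if network_spec is None:
        nspec = NetworkSpec(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    net = generate_network(nspec)
    dual = build_dual_graph(net)
    table = centrality_table(dual)
    timing = TimingConfig(walking_speed=sim.walking_speed)
    lo_d, hi_d = sim.duration_range
    for _ in range(50):
        routes = generate_routes(dual, sim, rng, timing)
        schedules = [classify_detours(schedule_route(r, dual, timing, rng), dual)
                     for r in routes]
        if all(lo_d <= s.total_duration <= hi_d for s in schedules):
            break
    else:  # pragma: no cover - margins make this unreachable in practice
        raise RuntimeError("could not realize route durations inside the stated range")

    session = assemble_session(schedules, sim)
    design = glm_mod.build_model_design(session, table, dual, "recovery")
    effects = sim.default_effects()
    base = {}
    for name in design.names:
        for cond in ("navigation", "control"):
            for family, b in sim.base_betas.items():
                if name == f"{cond}_{family}":
                    base[name] = b
    truth_rows = []
    bold = []
    for s in range(sim.n_subjects):
        beta = np.zeros((len(design.names), len(sim.rois)))
        for j, roi in enumerate(sim.rois):
            for name, b in base.items():
                beta[design.names.index(name), j] = b
            for col, (mu, sd) in effects.get(roi, {}).items():
                if col not in design.names:
                    continue
                b = float(rng.normal(mu, sd))
                beta[design.names.index(col), j] = b
                truth_rows.append({"subject": s, "roi": roi, "column": col, "beta": b})
        y = generate_bold(design, beta, sim.rho, sim.sigma, rng)
        bold.append(pd.DataFrame(y, columns=list(sim.rois)))
    truth = pd.DataFrame(truth_rows, columns=["subject", "roi", "column", "beta"])
    return SyntheticDataset(
        net=net, dual=dual, table=table, routes=routes, schedules=schedules,
        session=session, design=design, bold=bold, truth=truth,
        network_spec=nspec, sim_spec=sim, seed=seed,
    )


def assemble_session(
    schedules: list[RouteEventSchedule], sim: SimulationSpec
) -> glm_mod.Session:
    """Concatenate route videos on the scanner clock with fixation + cue gaps."""
    onsets = []
    t = 0.0
    for sched in schedules:
        t += sim.fixation_s + sim.cue_s
        onsets.append(t)
        t += sched.total_duration
    n_scans = int(np.ceil((t + 20.0) / sim.tr))
    return glm_mod.Session(schedules=schedules, route_onsets=onsets,
                           tr=sim.tr, n_scans=n_scans)


# ---------------------------------------------------------------------------
# behavioural observer
# ---------------------------------------------------------------------------

def simulate_observer(
    schedules: list[RouteEventSchedule],
    table: pd.DataFrame,
    knowledge: str = "naive",
    rng: np.random.Generator | None = None,
    accuracy: float = 0.9,
    no_change_bias: float = 0.0,
    restrict_to_changes: bool = False,
) -> pd.DataFrame:
    """Three-alternative change-direction judgements at street entries.

    A *naive* observer guesses among {-1, 0, +1}; ``no_change_bias`` shifts
    probability mass onto the 'no change' option (0 = uniform 1/3 each).  An
    *expert* answers correctly with probability ``accuracy``, otherwise
    errs uniformly.  ``restrict_to_changes`` keeps only events whose true
    degree change is nonzero, matching the analysis restricted to events
    where degree increased or decreased.
    """
    if knowledge not in ("naive", "expert"):
        raise ValueError("knowledge must be 'naive' or 'expert'")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for sched in schedules:
        series = compute_modulator(sched, table, "degree")
        for e, cat in zip(series.events, series.categorical):
            if restrict_to_changes and cat == 0:
                continue
            rows.append({"route_id": sched.route.id, "onset_s": e.onset, "truth": cat})
    frame = pd.DataFrame(rows)
    truths = frame["truth"].to_numpy()
    frame["response"] = _draw_responses(truths, knowledge, rng, accuracy, no_change_bias)
    frame["correct"] = frame["response"] == frame["truth"]
    return frame


def _draw_responses(truths, knowledge, rng, accuracy, no_change_bias):
    n = len(truths)
    if knowledge == "expert":
        correct = rng.random(n) < accuracy
        flip = rng.random(n) < 0.5
        alts = np.array([_other_two(t) for t in truths])
        wrong = np.where(flip, alts[:, 0], alts[:, 1])
        return np.where(correct, truths, wrong)
    p0 = 1.0 / 3.0 + no_change_bias
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("no_change_bias puts 'no change' probability outside [0, 1]")
    p_other = (1.0 - p0) / 2.0
    return rng.choice([-1, 0, 1], size=n, p=[p_other, p0, p_other])


def _other_two(truth: int) -> tuple[int, int]:
    opts = [-1, 0, 1]
    opts.remove(int(truth))
    return tuple(opts)


def chance_level_accuracy(
    truths,
    rng: np.random.Generator,
    n_trials: int = 10_000,
    no_change_bias: float = 0.0,
) -> float:
    """Monte-Carlo accuracy of a guessing observer over *n_trials* judgements
    drawn (with replacement) from the given true change directions."""
    truths = np.asarray(truths)
    if truths.size == 0:
        raise ValueError("no events to judge")
    sampled = truths[rng.integers(truths.size, size=n_trials)]
    responses = _draw_responses(sampled, "naive", rng, 0.9, no_change_bias)
    return float((responses == sampled).mean())
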