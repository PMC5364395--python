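"""Recovery-study entry points: the quantitative checks the package makes of itself.

Each function recomputes one headline property from scratch by running the
full forward model and analysis: the chance level of a three-alternative
change-direction guesser, the cross-weighting agreement of BFS planning
demand, statistical power and false-positive rate of the degree-change
model, and the event-locking specificity of an injected street-entry
effect.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .bfs import demand_series
from .glm import run_model
from .pipeline import compare_event_locking
from .network import build_dual_graph, centrality_table
from .routes import TimingConfig, classify_detours, schedule_route
from .synth import (
    NetworkSpec,
    SimulationSpec,
    chance_level_accuracy,
    generate_dataset,
    generate_network,
    generate_routes,
    simulate_observer,
)

__all__ = [
    "guesser_chance_accuracy",
    "bfs_weighting_correlations",
    "model2_contrast",
    "event_locking_outcome",
]

HIPPOCAMPUS = "right_posterior_hippocampus"
DEGREE_KEY = "street_entry:degree"


def guesser_chance_accuracy(seed: int, n_trials: int = 10_000) -> dict:
    """Monte-Carlo accuracy (percent) of a uniform three-alternative guesser
    judging the direction of degree change, restricted to events where the
    degree actually changed."""
    ds = generate_dataset(sim_spec=SimulationSpec(n_subjects=1, n_routes=6), seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    frame = simulate_observer(ds.schedules, ds.table, "naive", rng,
                              restrict_to_changes=True)
    acc = chance_level_accuracy(frame["truth"].to_numpy(), rng, n_trials=n_trials)
    return {"accuracy_percent": 100.0 * acc, "n_trials": n_trials}


def bfs_weighting_correlations(
    route_seed: int,
    network_seed: int = 0,
    n_routes: int = 60,
) -> dict:
    """Pearson correlations between level-1 BFS demand series under degree
    weighting versus closeness and betweenness weighting, pooled over all
    detour events of a fixed synthetic street network."""
    net = generate_network(NetworkSpec(seed=network_seed))
    dual = build_dual_graph(net)
    table = centrality_table(dual)
    sim = SimulationSpec(n_routes=n_routes)
    rng = np.random.default_rng(np.random.SeedSequence([route_seed, 7]))
    timing = TimingConfig(walking_speed=sim.walking_speed)
    routes = generate_routes(dual, sim, rng, timing)
    values = {k: [] for k in ("degree", "closeness", "betweenness")}
    for route in routes:
        sched = classify_detours(schedule_route(route, dual, timing, rng), dual)
        for kind in values:
            _, v = demand_series(sched, dual, table, kind=kind, level="one")
            values[kind] += v
    n = len(values["degree"])
    r_clo = float(stats.pearsonr(values["degree"], values["closeness"])[0])
    r_bet = float(stats.pearsonr(values["degree"], values["betweenness"])[0])
    return {"r_degree_closeness": r_clo, "r_degree_betweenness": r_bet, "n_events": n}


def model2_contrast(seed: int, effect_size: float = 1.0) -> dict:
    """Fit the degree-change model on one simulated experiment and return the
    group navigation>control statistics for the hippocampal ROI."""
    sim = dataclasses.replace(SimulationSpec(), effect_size=effect_size)
    ds = generate_dataset(sim_spec=sim, seed=seed)
    res = run_model(2, ds)
    row = res.result(DEGREE_KEY, "navigation>control", HIPPOCAMPUS)
    return {"effect": float(row.effect), "t": float(row.t), "p": float(row.p)}


def event_locking_outcome(seed: int) -> dict:
    """Paired street-entry-versus-other-family comparison on one simulated
    experiment with the effect injected at street entries only.  Reports the
    mean paired difference and one-sided p value per comparison."""
    ds = generate_dataset(seed=seed)
    table = compare_event_locking(ds)
    hip = table[table.roi == HIPPOCAMPUS]
    out = {}
    for _, row in hip.iterrows():
        one_sided = row.p / 2 if row.mean_diff > 0 else 1 - row.p / 2
        out[row.comparison] = {"mean_diff": float(row.mean_diff),
                               "p_one_sided": float(one_sided)}
    return out
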