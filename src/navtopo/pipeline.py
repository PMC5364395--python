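"""End-to-end orchestration: configs, full runs, and the event-locking comparison.

A run executes network -> centrality -> events -> modulators/demands ->
design -> first level -> second level, writes every intermediate as TSV and
the final statistics as a machine-readable JSON report.  Runs are pure
functions of (config, seed): rerunning the same config reproduces byte
identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bfs import demand_frame
from .glm import MODEL_REGISTRY, ModelRunResult, run_model, second_level_ttest
from .network import centrality_table, read_network_json, write_network_json
from .routes import schedules_to_frame
from .synth import NetworkSpec, SimulationSpec, SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "compare_event_locking"]


@dataclass
class RunConfig:
    """What to run and where to write it."""

    models: tuple = (2,)
    seed: int = 0
    outdir: str | Path = "navtopo_out"
    network_spec: NetworkSpec | None = None
    sim_spec: SimulationSpec | None = None
    network_json: str | None = None  # use a real network file instead of the generator
    ar1: bool = True
    hp_cutoff: float | None = 128.0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model id is required")
        for m in self.models:
            if m not in MODEL_REGISTRY:
                valid = sorted(k for k in MODEL_REGISTRY if isinstance(k, int))
                raise ValueError(f"unknown model {m!r}; valid models: {valid}")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "models": list(self.models),
                "seed": self.seed,
                "network_spec": dataclasses.asdict(self.network_spec) if self.network_spec else None,
                "sim_spec": _spec_dict(self.sim_spec) if self.sim_spec else None,
                "network_json": self.network_json,
                "ar1": self.ar1,
                "hp_cutoff": self.hp_cutoff,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _spec_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    d.pop("effects", None)
    return d


@dataclass
class RunReport:
    """Second-level statistics of a run plus its provenance."""

    results: pd.DataFrame
    seed: int
    config_hash: str
    version: str
    n_models: int
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        obj = {
            "provenance": {
                "seed": self.seed,
                "config_hash": self.config_hash,
                "navtopo_version": self.version,
                "n_models_run_uncorrected": self.n_models,
            },
            "warnings": self.warnings,
            "results": self.results.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def run(config: RunConfig) -> RunReport:
    """Execute the configured models end to end and write report + intermediates."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = _build_dataset(config)
    write_network_json(dataset.net, out / "network.json")
    dataset.table.to_csv(out / "centrality.tsv", sep="\t")
    schedules_to_frame(dataset.schedules).to_csv(out / "schedules.tsv", sep="\t", index=False)
    demand_frame(dataset.schedules, dataset.dual, dataset.table).to_csv(
        out / "bfs_demand.tsv", sep="\t", index=False
    )
    warnings = []
    if len(config.models) > 1:
        warnings.append(
            f"{len(config.models)} models were run; statistics are reported per model "
            "without correction across models"
        )
    tables = []
    for m in config.models:
        res: ModelRunResult = run_model(m, dataset, ar1=config.ar1,
                                        hp_cutoff=config.hp_cutoff)
        res.design.to_tsv(out / f"design_model{m}.tsv")
        res.table.to_csv(out / f"results_model{m}.tsv", sep="\t", index=False)
        tables.append(res.table)
    results = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    report = RunReport(
        results=results, seed=config.seed, config_hash=config.digest(),
        version=__version__, n_models=len(config.models), warnings=warnings,
    )
    report.to_json(out / "report.json")
    results.to_csv(out / "results_all.tsv", sep="\t", index=False)
    return report


def _build_dataset(config: RunConfig) -> SyntheticDataset:
    if config.network_json is not None:
        # real network; synthetic routes/BOLD on top of it
        net = read_network_json(config.network_json)
        from .network import build_dual_graph
        from .routes import TimingConfig, classify_detours, schedule_route
        from .synth import assemble_session, generate_routes
        from . import glm as glm_mod

        sim = config.sim_spec or SimulationSpec()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
        dual = build_dual_graph(net)
        table = centrality_table(dual)
        timing = TimingConfig(walking_speed=sim.walking_speed)
        routes = generate_routes(dual, sim, rng, timing)
        schedules = [classify_detours(schedule_route(r, dual, timing, rng), dual)
                     for r in routes]
        session = assemble_session(schedules, sim)
        design = glm_mod.build_model_design(session, table, dual, "recovery")
        from .synth import generate_bold

        effects = sim.default_effects()
        bold, truth_rows = [], []
        names = design.names
        for s in range(sim.n_subjects):
            beta = np.zeros((len(names), len(sim.rois)))
            for j, roi in enumerate(sim.rois):
                for col, (mu, sd) in effects.get(roi, {}).items():
                    if col in names:
                        b = float(rng.normal(mu, sd))
                        beta[names.index(col), j] = b
                        truth_rows.append({"subject": s, "roi": roi, "column": col, "beta": b})
            bold.append(pd.DataFrame(
                generate_bold(design, beta, sim.rho, sim.sigma, rng),
                columns=list(sim.rois),
            ))
        return SyntheticDataset(
            net=net, dual=dual, table=table, routes=routes, schedules=schedules,
            session=session, design=design, bold=bold,
            truth=pd.DataFrame(truth_rows, columns=["subject", "roi", "column", "beta"]),
            network_spec=config.network_spec or NetworkSpec(), sim_spec=sim,
            seed=config.seed,
        )
    return generate_dataset(config.network_spec, config.sim_spec, seed=config.seed)


def compare_event_locking(dataset: SyntheticDataset, parameter: str = "degree",
                          ar1: bool = True) -> pd.DataFrame:
    """Paired group comparison of a modulator's effect across event families.

    Fits the superset model carrying the parameter at street entries, travel
    periods and decision points, then tests, per ROI, whether the navigation
    street-entry effect exceeds the decision-point and travel-period effects
    (paired one-sample t on the per-subject differences; two-sided p).
    """
    if len(dataset.bold) < 2:
        raise ValueError("event-locking comparison needs at least 2 subjects")
    res = run_model("recovery", dataset, ar1=ar1)
    rois = list(dataset.bold[0].columns)
    families = {
        "street_entry": f"street_entry:{parameter}",
        "decision_point": f"decision_point:{parameter}",
        "travel_period": f"travel_period:{parameter}",
    }
    for fam, key in families.items():
        if (key, "navigation", rois[0]) not in res.subject_effects:
            raise KeyError(f"modulator missing for event family {fam!r}")
    rows = []
    for roi in rois:
        se = res.subject_effects[(families["street_entry"], "navigation", roi)]
        for other in ("decision_point", "travel_period"):
            oth = res.subject_effects[(families[other], "navigation", roi)]
            diff = se - oth
            t2 = second_level_ttest(diff, name=f"street_entry>{other} {roi}")
            rows.append(
                {"roi": roi, "comparison": f"street_entry>{other}",
                 "mean_diff": t2.effect, "t": t2.t, "p": t2.p, "df": t2.df, "n": t2.n}
            )
    return pd.DataFrame(rows)
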