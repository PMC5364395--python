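"""HRF-convolved design matrices and ROI-level GLMs with AR(1) prewhitening.

Events are modelled the standard event-related way: epochs as boxcars,
duration-0 events as stick functions placed on a microtime grid (16 bins per
TR), parametric modulators as amplitude-scaled sticks mean-centered over
their events, everything convolved with the canonical double-gamma
hemodynamic response and resampled at scan onsets.  Low-frequency drift is
modelled with a discrete-cosine basis up to 1/128 Hz and parametric
regressors are never serially orthogonalized: ordinary least squares lets
each regressor account for shared variance symmetrically.

Fitting follows the statsmodels idiom: :class:`RoiGLM` is the model object,
``RoiGLM(...).fit()`` returns :class:`RoiGLMResults` carrying estimates,
standard errors, AR(1) coefficients and a ``summary()`` table.  Group
inference is a one-sample t-test over per-subject contrast effects
(:func:`second_level_ttest`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bfs import demand_series
from .routes import (
    RouteEventSchedule,
    compute_modulator,
    decision_point_modulators,
)

log = logging.getLogger(__name__)

__all__ = [
    "canonical_hrf",
    "Regressor",
    "DesignMatrix",
    "build_design",
    "RoiGLM",
    "RoiGLMResults",
    "ContrastResult",
    "second_level_ttest",
    "Session",
    "MODEL_REGISTRY",
    "build_model_design",
    "run_model",
    "ModelRunResult",
]


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every *dt* seconds, unit peak.

    Response gamma with shape 6, undershoot gamma with shape 16 (both unit
    scale), undershoot ratio 1/6; peak near 5 s, undershoot near 16 s,
    32-s support.  The kernel is normalized to a maximum of 1 so that an
    isolated unit stick produces a unit-peak response.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    t = np.arange(0.0, duration + dt / 2, dt)
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / h.max()


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class Regressor:
    """One task column before convolution: onsets/durations/amplitudes in seconds."""

    name: str
    onsets: np.ndarray
    durations: np.ndarray
    amplitudes: np.ndarray | None = None
    mean_center: bool = False  # parametric modulators center over their events

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.broadcast_to(
            np.asarray(self.durations, dtype=float), self.onsets.shape
        ).copy()
        if self.amplitudes is None:
            self.amplitudes = np.ones_like(self.onsets)
        else:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != self.onsets.shape:
            raise ValueError(f"regressor {self.name!r}: amplitude/onset length mismatch")


@dataclass
class DesignMatrix:
    """Scan-resolution design: one named column per regressor, plus drift + constant."""

    frame: pd.DataFrame
    tr: float
    n_scans: int
    task_columns: list[str]

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="scan")


def _dct_drift(n_scans: int, tr: float, hp_cutoff: float) -> np.ndarray:
    """Discrete-cosine drift basis with frequencies below 1/hp_cutoff Hz."""
    order = int(np.floor(2.0 * n_scans * tr / hp_cutoff))
    t = np.arange(n_scans)
    basis = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, order + 1)
    ]
    return np.column_stack(basis) if basis else np.empty((n_scans, 0))


def build_design(
    regressors: list[Regressor],
    tr: float,
    n_scans: int,
    hp_cutoff: float | None = 128.0,
    oversampling: int = 16,
) -> DesignMatrix:
    """Convolve task regressors with the canonical HRF and assemble the design.

    Duration-0 events enter as unit-area impulses on the microtime grid
    (``tr/oversampling`` resolution); epochs as unit-height boxcars.  An
    all-zero column (e.g. an empty or constant-after-centering modulator) is
    omitted with a log notice.  ``hp_cutoff=None`` disables the drift basis.
    """
    if tr <= 0 or n_scans <= 0:
        raise ValueError("tr and n_scans must be positive")
    names = [r.name for r in regressors]
    if len(set(names)) != len(names):
        raise ValueError("duplicate regressor names")
    dt = tr / oversampling
    n_bins = n_scans * oversampling
    t_max = n_scans * tr
    hrf = canonical_hrf(dt)
    cols: dict[str, np.ndarray] = {}
    task_columns: list[str] = []
    for reg in regressors:
        if reg.onsets.size and reg.onsets.max() >= t_max:
            raise ValueError(
                f"regressor {reg.name!r}: onset {reg.onsets.max():.1f}s beyond the "
                f"{t_max:.1f}s scan window"
            )
        amps = reg.amplitudes.copy()
        if reg.mean_center and amps.size:
            amps = amps - amps.mean()
        if not amps.size or np.allclose(amps, 0.0):
            log.info("design: column %r is empty or all-zero; omitted", reg.name)
            continue
        u = np.zeros(n_bins)
        for onset, dur, amp in zip(reg.onsets, reg.durations, amps):
            i0 = int(round(onset / dt))
            if dur == 0.0:
                u[i0] += amp / dt  # unit-area impulse
            else:
                i1 = min(int(round((onset + dur) / dt)), n_bins)
                u[i0:i1] += amp
        x = np.convolve(u, hrf)[:n_bins] * dt
        cols[reg.name] = x[::oversampling]
        task_columns.append(reg.name)
    if hp_cutoff is not None:
        drift = _dct_drift(n_scans, tr, hp_cutoff)
        for k in range(drift.shape[1]):
            cols[f"drift_{k + 1}"] = drift[:, k]
    cols["constant"] = np.ones(n_scans)
    frame = pd.DataFrame(cols, index=np.arange(n_scans) * tr)
    frame.index.name = "time_s"
    return DesignMatrix(frame=frame, tr=tr, n_scans=n_scans, task_columns=task_columns)


# ---------------------------------------------------------------------------
# first-level model / results
# ---------------------------------------------------------------------------

def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < diag.max() * 1e-10
    return [n for n, b in zip(names, bad) if b]


class RoiGLM:
    """First-level GLM of one or more ROI time series against a design matrix.

    Parameters
    ----------
    endog : array-like or DataFrame, shape (n_scans,) or (n_scans, n_rois)
    design : DesignMatrix
    """

    def __init__(self, endog, design: DesignMatrix):
        if isinstance(endog, pd.DataFrame):
            self.roi_names = list(endog.columns)
            y = endog.to_numpy(dtype=float)
        else:
            y = np.asarray(endog, dtype=float)
            if y.ndim == 1:
                y = y[:, None]
            self.roi_names = [f"roi{i}" for i in range(y.shape[1])]
        if y.shape[0] != design.n_scans:
            raise ValueError(
                f"endog has {y.shape[0]} scans, design expects {design.n_scans}"
            )
        self.endog = y
        self.design = design
        X = design.values()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            bad = _collinear_columns(X, design.names)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    def fit(self, ar1: bool = True) -> "RoiGLMResults":
        """OLS fit; with ``ar1`` a lag-1 residual autocorrelation is estimated
        per ROI, data and design are prewhitened once and refitted."""
        X = self.design.values()
        n, p = X.shape
        pinv = np.linalg.pinv(X)
        betas = pinv @ self.endog  # p x rois
        resid = self.endog - X @ betas
        rhos = np.zeros(len(self.roi_names))
        if ar1:
            for j in range(self.endog.shape[1]):
                r = resid[:, j]
                denom = float(r @ r)
                rho = float(r[1:] @ r[:-1]) / denom if denom > 0 else 0.0
                rho = float(np.clip(rho, -0.99, 0.99))
                rhos[j] = rho
                yw = _ar1_whiten(self.endog[:, j], rho)
                Xw = _ar1_whiten(X, rho)
                betas[:, j] = np.linalg.pinv(Xw) @ yw
                resid[:, j] = yw - Xw @ betas[:, j]
        df = n - p
        sigma2 = (resid**2).sum(axis=0) / df
        # per-ROI bse need the whitened X; recompute per rho
        bse = np.empty_like(betas)
        for j in range(self.endog.shape[1]):
            Xj = _ar1_whiten(X, rhos[j]) if ar1 else X
            xtx_inv = np.linalg.inv(Xj.T @ Xj)
            bse[:, j] = np.sqrt(np.diag(xtx_inv) * sigma2[j])
        return RoiGLMResults(
            model=self,
            params=pd.DataFrame(betas, index=self.design.names, columns=self.roi_names),
            bse=pd.DataFrame(bse, index=self.design.names, columns=self.roi_names),
            resid=resid,
            df_resid=df,
            sigma2=pd.Series(sigma2, index=self.roi_names),
            rho=pd.Series(rhos, index=self.roi_names) if ar1 else None,
        )


def _ar1_whiten(a: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) prewhitening transform: x'_0 = sqrt(1-rho^2) x_0, x'_t = x_t - rho x_{t-1}."""
    out = np.empty_like(a, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * a[0]
    out[1:] = a[1:] - rho * a[:-1]
    return out


@dataclass
class RoiGLMResults:
    """First-level fit: betas, standard errors, residuals, AR(1) coefficients."""

    model: RoiGLM
    params: pd.DataFrame  # columns x rois
    bse: pd.DataFrame
    resid: np.ndarray
    df_resid: int
    sigma2: pd.Series
    rho: pd.Series | None = None

    @property
    def tvalues(self) -> pd.DataFrame:
        return self.params / self.bse

    def t_contrast(self, weights: dict[str, float], roi: str | None = None):
        """First-level t contrast; *weights* maps column names to weights.

        Returns a :class:`ContrastResult` for one ROI, or a dict over ROIs.
        """
        w = np.zeros(len(self.params.index))
        for name, val in weights.items():
            if name not in self.params.index:
                raise KeyError(f"unknown design column {name!r}")
            w[self.params.index.get_loc(name)] = val
        rois = [roi] if roi is not None else list(self.params.columns)
        out = {}
        X = self.model.design.values()
        for r in rois:
            rho = float(self.rho[r]) if self.rho is not None else 0.0
            Xw = _ar1_whiten(X, rho)
            xtx_inv = np.linalg.inv(Xw.T @ Xw)
            eff = float(w @ self.params[r].to_numpy())
            se = float(np.sqrt(w @ xtx_inv @ w * self.sigma2[r]))
            t = eff / se if se > 0 else 0.0
            p = 2 * stats.t.sf(abs(t), self.df_resid)
            out[r] = ContrastResult(
                name="+".join(f"{v:+g}*{k}" for k, v in weights.items()),
                effect=eff, se=se, t=t, p=p, df=self.df_resid, level="first", n=1,
            )
        return out[roi] if roi is not None else out

    def summary(self) -> str:
        lines = ["ROI GLM results", f"n_scans={self.model.design.n_scans} "
                 f"df_resid={self.df_resid}"]
        if self.rho is not None:
            lines.append("AR(1) rho: " + ", ".join(
                f"{r}={v:.3f}" for r, v in self.rho.items()))
        task = self.model.design.task_columns
        tab = pd.concat(
            {"beta": self.params.loc[task], "se": self.bse.loc[task],
             "t": self.tvalues.loc[task]},
            axis=1,
        )
        lines.append(tab.round(4).to_string())
        return "\n".join(lines)


@dataclass(frozen=True)
class ContrastResult:
    """An effect with its t statistic; ``level`` is 'first' or 'second'."""

    name: str
    effect: float
    se: float
    t: float
    p: float
    df: int
    level: str
    n: int


def second_level_ttest(effects, name: str = "effect") -> ContrastResult:
    """Random-effects group test: one-sample t of per-subject effects vs 0."""
    effects = np.asarray(effects, dtype=float)
    if effects.size < 2:
        raise ValueError("second-level test needs at least 2 subjects")
    n = effects.size
    mean = float(effects.mean())
    se = float(effects.std(ddof=1) / np.sqrt(n))
    t = mean / se if se > 0 else 0.0
    p = float(2 * stats.t.sf(abs(t), n - 1)) if se > 0 else (1.0 if mean == 0 else 0.0)
    return ContrastResult(name=name, effect=mean, se=se, t=t, p=p,
                          df=n - 1, level="second", n=n)


# ---------------------------------------------------------------------------
# sessions and the model registry
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """Route schedules laid out on one scanning session's clock."""

    schedules: list[RouteEventSchedule]
    route_onsets: list[float]  # session time of each route's local t=0
    tr: float
    n_scans: int

    def condition_schedules(self, condition: str):
        return [
            (sched, onset)
            for sched, onset in zip(self.schedules, self.route_onsets)
            if sched.route.condition == condition
        ]


@dataclass(frozen=True)
class ModulatorSpec:
    """One parametric-modulation column of a model."""

    parameter: str
    coding: str = "categorical"  # raw | delta | categorical
    detours_only: bool = False
    exclude_zero_change: bool = False
    bfs_kind: str | None = None  # degree/closeness/betweenness -> BFS demand modulator
    dp_reference: str = "past"


@dataclass(frozen=True)
class ModelSpec:
    """A named model: the modulated event family plus its modulator list."""

    id: int | str
    family: str  # street_entry | travel_period | decision_point
    modulators: tuple[ModulatorSpec, ...]
    description: str = ""


def _m(parameter, coding="categorical", **kw) -> ModulatorSpec:
    return ModulatorSpec(parameter=parameter, coding=coding, **kw)


MODEL_REGISTRY: dict[int | str, ModelSpec] = {
    1: ModelSpec(1, "street_entry", (_m("degree", "raw"),), "raw degree at entries"),
    2: ModelSpec(2, "street_entry", (_m("degree"),), "categorical change in degree"),
    3: ModelSpec(3, "street_entry", (_m("betweenness", "raw"),), "raw betweenness"),
    4: ModelSpec(4, "street_entry", (_m("closeness", "raw"),), "raw closeness"),
    5: ModelSpec(5, "street_entry", (_m("betweenness"),), "categorical change in betweenness"),
    6: ModelSpec(6, "street_entry", (_m("closeness"),), "categorical change in closeness"),
    7: ModelSpec(
        7, "street_entry",
        (_m("degree"), _m("betweenness"), _m("closeness")),
        "categorical change in all three centralities",
    ),
    8: ModelSpec(
        8, "street_entry", (_m("degree"), _m("step_depth_to_goal")),
        "degree change plus a covariate of no interest (default step depth to goal)",
    ),
    9: ModelSpec(9, "travel_period", (_m("degree"),), "degree change at travel periods"),
    10: ModelSpec(10, "decision_point", (_m("degree"),), "degree change at decision points"),
    11: ModelSpec(
        11, "street_entry",
        (_m("degree"), _m("path_distance_to_goal", "delta", detours_only=True)),
        "degree change plus change in metric path distance at detours",
    ),
    12: ModelSpec(
        12, "street_entry", (_m("degree", exclude_zero_change=True),),
        "degree change, zero-change entries excluded",
    ),
    13: ModelSpec(
        13, "street_entry", (_m("bfs_degree", "raw", bfs_kind="degree", detours_only=True),),
        "level-1 BFS planning demand (degree weighting) at detours",
    ),
    14: ModelSpec(
        14, "street_entry",
        (_m("bfs_betweenness", "raw", bfs_kind="betweenness", detours_only=True),),
        "level-1 BFS planning demand (betweenness weighting) at detours",
    ),
    15: ModelSpec(
        15, "street_entry", (_m("bfs_closeness", "raw", bfs_kind="closeness", detours_only=True),),
        "level-1 BFS planning demand (closeness weighting) at detours",
    ),
    # superset model used to generate synthetic data and for event-locking
    # comparisons: degree change at all three event families plus BFS demand
    "recovery": ModelSpec(
        "recovery", "street_entry",
        (_m("degree"), _m("bfs_degree", "raw", bfs_kind="degree", detours_only=True)),
        "degree change at entries, travel periods and decision points + BFS demand",
    ),
}
_EXTRA_FAMILY_MODULATORS: dict[int | str, tuple[tuple[str, ModulatorSpec], ...]] = {
    # model id -> additional (family, modulator) columns beyond the main family
    "recovery": (
        ("travel_period", _m("degree")),
        ("decision_point", _m("degree")),
    ),
}

CONDITIONS = ("navigation", "control")
EVENT_FAMILIES = ("street_entry", "new_goal", "decision_point", "travel_period")


def _modulator_column(
    cond: str,
    family: str,
    mod: ModulatorSpec,
    session: Session,
    table: pd.DataFrame,
    g,
    bfs_level: str = "one",
) -> Regressor | None:
    """Collect one modulator's events across a condition's routes."""
    onsets, amps = [], []
    for sched, r_on in session.condition_schedules(cond):
        if mod.bfs_kind is not None:
            events, values = demand_series(sched, g, table, kind=mod.bfs_kind, level=bfs_level)
            for e, v in zip(events, values):
                onsets.append(r_on + e.onset)
                amps.append(v)
            continue
        if family == "decision_point":
            series = decision_point_modulators(
                sched, table, mod.parameter, reference=mod.dp_reference, g=g
            )
        else:
            series = compute_modulator(sched, table, mod.parameter, g=g, event_type=family)
        values = {"raw": series.raw, "delta": series.delta,
                  "categorical": series.categorical}[mod.coding]
        for e, v, c in zip(series.events, values, series.categorical):
            if mod.detours_only and not e.is_detour:
                continue
            if mod.exclude_zero_change and c == 0:
                continue
            onsets.append(r_on + e.onset)
            amps.append(float(v))
    name = f"{cond}_{family}_x_{mod.parameter}_{mod.coding[:3]}"
    if not onsets:
        log.info("model design: no events for %s; column omitted", name)
        return None
    return Regressor(name=name, onsets=np.array(onsets), durations=0.0,
                     amplitudes=np.array(amps), mean_center=True)


def build_model_design(
    session: Session,
    table: pd.DataFrame,
    g,
    model_id: int | str,
    hp_cutoff: float | None = 128.0,
    oversampling: int = 16,
) -> DesignMatrix:
    """Build the full design for one model of the registry.

    All key event families (task epochs, street entries, new-goal and
    decision-point epochs, travel periods) are included for both conditions
    in every model; the model only determines which parametric modulators are
    attached and to which family.
    """
    if model_id not in MODEL_REGISTRY:
        raise KeyError(
            f"unknown model {model_id!r}; valid ids: {sorted(k for k in MODEL_REGISTRY if isinstance(k, int))} "
            f"plus {sorted(k for k in MODEL_REGISTRY if isinstance(k, str))!r}"
        )
    spec = MODEL_REGISTRY[model_id]
    regs: list[Regressor] = []
    for cond in CONDITIONS:
        pairs = session.condition_schedules(cond)
        if not pairs:
            continue
        regs.append(
            Regressor(
                name=f"{cond}_task",
                onsets=np.array([on for _, on in pairs]),
                durations=np.array([s.total_duration for s, _ in pairs]),
            )
        )
        for family in EVENT_FAMILIES:
            onsets, durs = [], []
            for sched, r_on in pairs:
                for e in sched.of_type(family):
                    onsets.append(r_on + e.onset)
                    durs.append(e.duration)
            if onsets:
                regs.append(
                    Regressor(name=f"{cond}_{family}", onsets=np.array(onsets),
                              durations=np.array(durs))
                )
        for mod in spec.modulators:
            col = _modulator_column(cond, spec.family, mod, session, table, g)
            if col is not None:
                regs.append(col)
        for family, mod in _EXTRA_FAMILY_MODULATORS.get(model_id, ()):
            col = _modulator_column(cond, family, mod, session, table, g)
            if col is not None:
                regs.append(col)
    return build_design(regs, tr=session.tr, n_scans=session.n_scans,
                        hp_cutoff=hp_cutoff, oversampling=oversampling)


@dataclass
class ModelRunResult:
    """Second-level results of one model over a dataset's subjects."""

    model_id: int | str
    table: pd.DataFrame  # parameter, contrast, roi, effect, t, p, df, n
    subject_effects: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    design: DesignMatrix | None = None

    def result(self, parameter: str, contrast: str, roi: str) -> pd.Series:
        t = self.table
        row = t[(t.parameter == parameter) & (t.contrast == contrast) & (t.roi == roi)]
        if row.empty:
            raise KeyError((parameter, contrast, roi))
        return row.iloc[0]


def run_model(model_id: int | str, dataset, ar1: bool = True,
              hp_cutoff: float | None = 128.0) -> ModelRunResult:
    """Fit one registry model for every subject of a dataset and test the
    navigation, control and navigation>control effects of each modulator at
    the group level.

    *dataset* must provide ``session`` (:class:`Session`), ``table``
    (centrality table), ``dual`` (dual graph) and ``bold`` (list of per
    subject DataFrames, scans x ROIs).
    """
    spec = MODEL_REGISTRY[model_id] if model_id in MODEL_REGISTRY else None
    if spec is None:
        raise KeyError(
            f"unknown model {model_id!r}; valid ids: "
            f"{sorted(k for k in MODEL_REGISTRY if isinstance(k, int))}"
        )
    design = build_model_design(dataset.session, dataset.table, dataset.dual,
                                model_id, hp_cutoff=hp_cutoff)
    mod_cols: dict[str, dict[str, str]] = {}
    families = [(spec.family, m) for m in spec.modulators]
    families += list(_EXTRA_FAMILY_MODULATORS.get(model_id, ()))
    for family, mod in families:
        per_cond = {}
        for cond in CONDITIONS:
            name = f"{cond}_{family}_x_{mod.parameter}_{mod.coding[:3]}"
            if name in design.names:
                per_cond[cond] = name
        if per_cond:
            key = f"{family}:{mod.parameter}"
            mod_cols[key] = per_cond
        else:
            log.info("model %s: modulator %s has no usable column in either condition",
                     model_id, mod.parameter)
    rois = list(dataset.bold[0].columns)
    effects: dict[tuple[str, str, str], list[float]] = {}
    for y in dataset.bold:
        res = RoiGLM(y, design).fit(ar1=ar1)
        for key, per_cond in mod_cols.items():
            for roi in rois:
                nav = float(res.params.at[per_cond["navigation"], roi]) \
                    if "navigation" in per_cond else np.nan
                con = float(res.params.at[per_cond["control"], roi]) \
                    if "control" in per_cond else np.nan
                effects.setdefault((key, "navigation", roi), []).append(nav)
                effects.setdefault((key, "control", roi), []).append(con)
                effects.setdefault((key, "navigation>control", roi), []).append(nav - con)
    rows = []
    subject_effects = {}
    for (key, contrast, roi), vals in effects.items():
        arr = np.asarray(vals)
        subject_effects[(key, contrast, roi)] = arr
        if np.isnan(arr).any():
            continue
        res2 = second_level_ttest(arr, name=f"{key} {contrast} {roi}")
        rows.append(
            {"model": model_id, "parameter": key, "contrast": contrast, "roi": roi,
             "effect": res2.effect, "se": res2.se, "t": res2.t, "p": res2.p,
             "df": res2.df, "n": res2.n}
        )
    return ModelRunResult(model_id=model_id, table=pd.DataFrame(rows),
                          subject_effects=subject_effects, design=design)
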