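"""HRF, design construction, first-level fitting and group inference."""

import numpy as np
import pandas as pd
import pytest

from navtopo.glm import (
    Regressor,
    RoiGLM,
    MODEL_REGISTRY,
    build_design,
    build_model_design,
    canonical_hrf,
    run_model,
    second_level_ttest,
)
from navtopo.synth import SimulationSpec, generate_bold, generate_dataset

from _oracles import naive_design_column


class TestCanonicalHrf:
    def test_peak_latency(self):
        h = canonical_hrf(dt=0.1)
        assert 4.5 <= 0.1 * int(np.argmax(h)) <= 6.5
        assert h.max() == pytest.approx(1.0)

    def test_zero_at_onset_and_undershoot(self):
        h = canonical_hrf(dt=0.1)
        assert h[0] == 0.0
        assert h[int(16 / 0.1)] < 0  # undershoot around 16 s

    def test_subsampling_consistency(self):
        fine = canonical_hrf(dt=0.1)
        coarse = canonical_hrf(dt=1.0)
        assert np.allclose(coarse, fine[::10][: len(coarse)], atol=1e-6)

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf(dt=0.0)


class TestBuildDesign:
    def test_single_stick_is_sampled_hrf(self):
        tr = 2.0
        d = build_design([Regressor("stick", onsets=[0.0], durations=0.0)],
                         tr=tr, n_scans=16, hp_cutoff=None)
        h = canonical_hrf(dt=tr / 16)
        expected = h[:: 16][:16]
        assert np.allclose(d.frame["stick"].to_numpy(), expected, atol=1e-12)

    def test_mean_centered_modulator(self):
        d = build_design(
            [Regressor("mod", onsets=[10.0, 60.0], durations=0.0,
                       amplitudes=[1.0, -1.0], mean_center=True)],
            tr=2.0, n_scans=60, hp_cutoff=None,
        )
        # +1/-1 amplitudes are already centered; responses cancel in total
        assert abs(d.frame["mod"].sum()) < 1e-8

    def test_constant_modulator_column_omitted(self, caplog):
        with caplog.at_level("INFO"):
            d = build_design(
                [Regressor("mod", onsets=[10.0, 30.0], durations=0.0,
                           amplitudes=[2.0, 2.0], mean_center=True)],
                tr=2.0, n_scans=40, hp_cutoff=None,
            )
        assert "mod" not in d.frame.columns
        assert any("omitted" in r.message for r in caplog.records)

    def test_onset_beyond_window_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            build_design([Regressor("x", onsets=[100.0], durations=0.0)],
                         tr=2.0, n_scans=10)

    def test_drift_columns_cover_cutoff(self):
        d = build_design([Regressor("x", onsets=[5.0], durations=0.0)],
                         tr=2.0, n_scans=200, hp_cutoff=128.0)
        n_drift = sum(1 for c in d.frame.columns if c.startswith("drift"))
        assert n_drift == int(np.floor(2 * 200 * 2.0 / 128.0))
        assert "constant" in d.frame.columns

    def test_matches_naive_convolution_oracle(self):
        tr, n_scans = 2.0, 120
        onsets = [7.3, 31.0, 55.9, 100.2]
        durations = [0.0, 5.0, 0.0, 9.0]
        amps = [1.0, 1.0, -0.5, 1.0]
        d = build_design(
            [Regressor("ev", onsets=onsets, durations=durations, amplitudes=amps)],
            tr=tr, n_scans=n_scans, hp_cutoff=None,
        )
        kernel = list(canonical_hrf(dt=tr / 16))
        expected = naive_design_column(onsets, durations, amps, kernel, tr, n_scans)
        assert np.allclose(d.frame["ev"].to_numpy(), expected, atol=1e-8)


def _toy_design(n_scans=120, tr=2.0, seed=0):
    rng = np.random.default_rng(seed)
    onsets_a = np.sort(rng.uniform(0, n_scans * tr - 35, size=12))
    onsets_b = np.sort(rng.uniform(0, n_scans * tr - 35, size=12))
    return build_design(
        [
            Regressor("a", onsets=onsets_a, durations=0.0),
            Regressor("b", onsets=onsets_b, durations=0.0,
                      amplitudes=rng.choice([-1.0, 1.0], 12), mean_center=True),
        ],
        tr=tr, n_scans=n_scans,
    )


class TestFirstLevel:
    def test_noiseless_recovery(self):
        d = _toy_design()
        beta = np.zeros(len(d.names))
        beta[d.names.index("a")] = 1.3
        beta[d.names.index("b")] = -0.7
        beta[d.names.index("constant")] = 10.0
        y = d.values() @ beta
        res = RoiGLM(y, d).fit(ar1=False)
        assert res.params["roi0"]["a"] == pytest.approx(1.3, abs=1e-10)
        assert res.params["roi0"]["b"] == pytest.approx(-0.7, abs=1e-10)

    def test_ar1_noise_recovery_within_three_se(self):
        d = _toy_design(n_scans=240)
        rng = np.random.default_rng(11)
        beta = np.zeros(len(d.names))
        beta[d.names.index("a")] = 1.0
        y = generate_bold(d, beta, rho=0.3, sigma=1.0, rng=rng)
        res = RoiGLM(y, d).fit(ar1=True)
        err = abs(res.params["roi0"]["a"] - 1.0)
        assert err < 3 * res.bse["roi0"]["a"]
        assert 0.0 < res.rho["roi0"] < 0.6

    def test_duplicate_column_rank_error(self):
        d = _toy_design()
        d.frame["a_copy"] = d.frame["a"]
        with pytest.raises(ValueError, match="collinear"):
            RoiGLM(np.zeros(d.n_scans), d)

    def test_order_invariance_no_serial_orthogonalization(self):
        """Permuting parametric columns leaves every beta unchanged (pure OLS)."""
        d = _toy_design()
        rng = np.random.default_rng(5)
        y = rng.standard_normal(d.n_scans)
        res = RoiGLM(y, d).fit(ar1=False)
        permuted = d.frame[[c for c in reversed(d.frame.columns)]]
        from navtopo.glm import DesignMatrix

        d2 = DesignMatrix(frame=permuted, tr=d.tr, n_scans=d.n_scans,
                          task_columns=d.task_columns)
        res2 = RoiGLM(y, d2).fit(ar1=False)
        for c in d.frame.columns:
            assert res2.params["roi0"][c] == pytest.approx(res.params["roi0"][c], abs=1e-9)

    def test_highpass_absorbs_slow_drift(self):
        """A slow sinusoid well below the 1/128 Hz cutoff barely moves the
        task estimates (the filter's transition band sits near the cutoff,
        so a 300-s drift is representative of scanner drift)."""
        rng = np.random.default_rng(7)
        tr, n_scans = 2.897, 1000  # a full session's worth of drift basis
        d = build_design(
            [
                Regressor("a", onsets=np.sort(rng.uniform(0, n_scans * tr - 35, 60)),
                          durations=0.0),
                Regressor("b", onsets=np.sort(rng.uniform(0, n_scans * tr - 35, 60)),
                          durations=0.0, amplitudes=rng.choice([-1.0, 1.0], 60),
                          mean_center=True),
            ],
            tr=tr, n_scans=n_scans,
        )
        beta = np.zeros(len(d.names))
        beta[d.names.index("a")] = 1.0
        beta[d.names.index("b")] = 0.8
        clean = d.values() @ beta + 0.1 * rng.standard_normal(d.n_scans)
        t = np.arange(d.n_scans) * d.tr
        drift = 3.0 * np.sin(2 * np.pi * t / 300.0 + 0.7)
        res_clean = RoiGLM(clean, d).fit(ar1=False)
        res_drift = RoiGLM(clean + drift, d).fit(ar1=False)
        for c in ("a", "b"):
            rel = abs(res_drift.params["roi0"][c] - res_clean.params["roi0"][c]) / abs(
                res_clean.params["roi0"][c]
            )
            assert rel < 0.01

    def test_summary_mentions_columns_and_rho(self):
        d = _toy_design()
        y = np.random.default_rng(0).standard_normal(d.n_scans)
        text = RoiGLM(y, d).fit().summary()
        assert "AR(1)" in text and "a" in text and "beta" in text


class TestSecondLevel:
    def test_all_zero_effects(self):
        res = second_level_ttest(np.zeros(10))
        assert res.t == 0.0 and res.p == pytest.approx(1.0)
        assert res.df == 9

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            second_level_ttest([1.0])

    def test_monte_carlo_matches_noncentral_t(self):
        """t statistics of n=24 samples from N(0.5, 1) follow noncentral t."""
        from scipy import stats

        rng = np.random.default_rng(123)
        n, reps = 24, 1000
        ts = np.array([
            second_level_ttest(rng.normal(0.5, 1.0, size=n)).t for _ in range(reps)
        ])
        ncp = 0.5 * np.sqrt(n)
        theory = stats.nct(df=n - 1, nc=ncp)
        lo, hi = theory.ppf([0.005, 0.995])
        assert lo < np.median(ts) < hi
        assert abs(np.mean(ts) - theory.mean()) < 4 * theory.std() / np.sqrt(reps)


class TestModelRegistry:
    def test_registry_has_all_fifteen_models(self):
        assert {k for k in MODEL_REGISTRY if isinstance(k, int)} == set(range(1, 16))

    def test_unknown_model_errors_listing_ids(self):
        ds = generate_dataset(sim_spec=SimulationSpec(n_subjects=2, n_routes=2), seed=0)
        with pytest.raises(KeyError, match="valid"):
            run_model(99, ds)

    def test_model_designs_modulate_the_right_family(self):
        ds = generate_dataset(sim_spec=SimulationSpec(n_subjects=2, n_routes=2), seed=0)
        d9 = build_model_design(ds.session, ds.table, ds.dual, 9)
        d10 = build_model_design(ds.session, ds.table, ds.dual, 10)
        assert "navigation_travel_period_x_degree_cat" in d9.names
        assert "navigation_decision_point_x_degree_cat" in d10.names

    def test_model2_recovers_injected_effect(self):
        ds = generate_dataset(seed=17)
        res = run_model(2, ds)
        row = res.result("street_entry:degree", "navigation>control",
                         "right_posterior_hippocampus")
        assert row.effect > 0 and row.p < 0.05
        null_row = res.result("street_entry:degree", "navigation>control",
                              "parietal_control")
        assert abs(null_row.t) < abs(row.t)

    def test_model13_runs_on_detour_demand(self):
        ds = generate_dataset(sim_spec=SimulationSpec(n_subjects=3, n_routes=4), seed=2)
        res = run_model(13, ds)
        assert not res.table.empty
        assert (res.table.parameter == "street_entry:bfs_degree").any()
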