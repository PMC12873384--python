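import math
import warnings

import numpy as np
import pytest

import silkgel as sg
from silkgel import synthetic as syn
from silkgel.model import (
    DEFAULT_BOUNDS,
    TWO_PI,
    eval_network_model,
    eval_peak_model,
    fit_network_model,
    fit_peak_model,
    residual_norm,
)


def oracle_network(p, q):
    """Independent scalar arithmetic, no vectorisation shared with the code."""
    return [p.a / qi**p.n + p.c / (1.0 + (p.eta * qi) ** p.m) + p.b for qi in q]


def oracle_peak(p, q):
    out = []
    for qi in q:
        u = (p.eta * qi) ** p.m
        out.append(
            p.a / qi**p.n * math.exp(-u)
            + p.c / (1.0 + u)
            + p.d * math.exp(-((qi - p.q0) ** 2) / (2.0 * p.sigma**2))
            + p.b
        )
    return out


def random_params(rng, stage):
    kw = dict(
        a=10.0 ** rng.uniform(-8, -3), n=rng.uniform(0.5, 5.0),
        c=10.0 ** rng.uniform(-2, 1), eta=rng.uniform(5, 500),
        m=rng.uniform(0.5, 5.0), b=10.0 ** rng.uniform(-3, 0),
    )
    if stage == "peak":
        kw.update(d=10.0 ** rng.uniform(-3, 0.5), q0=rng.uniform(0.013, 0.025),
                  sigma=rng.uniform(1e-3, 1e-2))
    return sg.HierParams(stage=stage, **kw)


class TestEvaluation:
    def test_pure_power_law(self):
        p = sg.HierParams(a=1.0, n=2.0, c=0.0, eta=1.0, m=2.0, b=0.0)
        assert eval_network_model(p, np.array([0.1]))[0] == pytest.approx(100.0)

    def test_lorentzian_plus_background(self):
        # (eta*q)^m = 1 at eta=10, q=0.1, m=2 -> c/2 + b
        p = sg.HierParams(a=0.0, n=1.0, c=3.0, eta=10.0, m=2.0, b=0.5)
        assert eval_network_model(p, np.array([0.1]))[0] == pytest.approx(2.0)

    def test_constant_background_only(self):
        p = sg.HierParams(a=0.0, n=1.0, c=0.0, eta=1.0, m=1.0, b=0.05,
                          d=0.0, q0=0.015, sigma=0.003, stage="peak")
        np.testing.assert_allclose(
            eval_peak_model(p, np.geomspace(0.002, 0.5, 20)), 0.05
        )

    def test_gaussian_maximum_at_centre(self):
        p = sg.HierParams(a=0.0, n=1.0, c=0.0, eta=1.0, m=1.0, b=0.0,
                          d=0.35, q0=0.015, sigma=0.003, stage="peak")
        assert eval_peak_model(p, np.array([0.015]))[0] == pytest.approx(0.35)

    @pytest.mark.parametrize("stage", ["network", "peak"])
    def test_matches_independent_arithmetic_oracle(self, stage):
        rng = np.random.default_rng(42)
        q = np.array([0.002, 0.01, 0.015, 0.1, 0.5])
        for _ in range(100):
            p = random_params(rng, stage)
            ours = (eval_peak_model if stage == "peak" else eval_network_model)(p, q)
            oracle = (oracle_peak if stage == "peak" else oracle_network)(p, q)
            np.testing.assert_allclose(ours, oracle, rtol=1e-12)

    def test_vanishing_cutoff_degrades_to_network_plus_gaussian(self):
        q = np.geomspace(0.002, 0.5, 50)
        peak = sg.HierParams(a=1e-5, n=3.0, c=0.8, eta=1e-9, m=2.7, b=0.03,
                             d=0.35, q0=0.015, sigma=0.003, stage="peak")
        net = sg.HierParams(a=1e-5, n=3.0, c=0.8, eta=1e-9, m=2.7, b=0.03)
        gauss = 0.35 * np.exp(-((q - 0.015) ** 2) / (2 * 0.003**2))
        np.testing.assert_allclose(
            eval_peak_model(peak, q), eval_network_model(net, q) + gauss,
            rtol=1e-9,
        )


class TestNetworkFit:
    TRUTH = sg.HierParams(a=0.001, n=2.5, c=1.2, eta=50.0, m=2.7, b=0.03)

    def _curve(self, noise=0.0, seed=0):
        q = np.geomspace(0.002, 0.5, 120)
        i = eval_network_model(self.TRUTH, q)
        if noise:
            rng = np.random.default_rng(seed)
            i = i * (1 + noise * rng.normal(size=q.size))
        return sg.ScatteringCurve(q=q, intensity=i)

    def test_noiseless_recovery_within_0p1_percent(self):
        res = fit_network_model(self._curve())
        assert res.converged
        for name in ("a", "n", "c", "eta", "m", "b"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(self.TRUTH, name), rel=1e-3
            ), name

    def test_noisy_recovery_within_5_percent(self):
        # balanced amplitudes: every component visible above the 2% noise
        truth = sg.HierParams(a=1e-6, n=2.5, c=1.2, eta=50.0, m=2.7, b=0.03)
        q = np.geomspace(0.002, 0.5, 120)
        rng = np.random.default_rng(1)
        i = eval_network_model(truth, q) * (1 + 0.02 * rng.normal(size=q.size))
        res = fit_network_model(sg.ScatteringCurve(q=q, intensity=i))
        for name in ("n", "c", "eta", "m", "b"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.05
            ), name

    def test_pure_background_recovers_level(self):
        q = np.geomspace(0.002, 0.5, 120)
        c = sg.ScatteringCurve(q=q, intensity=np.full(q.size, 0.05))
        res = fit_network_model(c)
        assert res.params.b == pytest.approx(0.05, rel=0.01)

    def test_too_few_positive_points(self):
        q = np.geomspace(0.002, 0.5, 20)
        i = np.full(q.size, -1.0)
        i[:5] = 1.0
        with pytest.raises(ValueError, match="usable"):
            fit_network_model(sg.ScatteringCurve(q=q, intensity=i))


class TestPeakFit:
    def _curve(self, d=0.35, noise=0.0, seed=0, **overrides):
        kw = dict(a=3e-7, n=3.0, c=0.8, eta=50.0, m=2.7, b=0.03,
                  d=d, q0=0.015, sigma=0.003, stage="peak")
        kw.update(overrides)
        truth = sg.HierParams(**kw)
        q = np.geomspace(0.002, 0.5, 120)
        i = eval_peak_model(truth, q)
        if noise:
            rng = np.random.default_rng(seed)
            i = i * (1 + noise * rng.normal(size=q.size))
        return sg.ScatteringCurve(q=q, intensity=i), truth

    def test_noiseless_recovery(self):
        curve, truth = self._curve()
        res = fit_peak_model(curve, fit_network_model(curve))
        assert res.params.q0 == pytest.approx(truth.q0, rel=0.005)
        assert res.params.d == pytest.approx(truth.d, rel=0.01)

    def test_null_gaussian_not_hallucinated(self):
        curve, truth = self._curve(d=1e-9)
        res = fit_peak_model(curve, fit_network_model(curve))
        assert res.params.d <= 0.01 * truth.b

    def test_d_star_identity(self):
        q0 = TWO_PI / 400.0
        curve, _ = self._curve(q0=q0)
        res = fit_peak_model(curve, fit_network_model(curve))
        assert res.d_star * res.params.q0 == pytest.approx(TWO_PI, abs=1e-12)

    def test_monotone_improvement_over_seed(self):
        curve, _ = self._curve(noise=0.02, seed=3)
        net = fit_network_model(curve)
        res = fit_peak_model(curve, net)
        warm = sg.HierParams(
            a=net.params.a, n=net.params.n, c=net.params.c, eta=net.params.eta,
            m=net.params.m, b=net.params.b, d=0.1, q0=0.015, sigma=0.003,
            stage="peak",
        )
        assert res.residual_norm <= residual_norm(warm, curve) + 1e-12


class TestRecoveryRegression:
    def test_median_errors_over_seeded_replicates(self):
        """50 noisy replicates of one truth: median recovery of the
        structure-defining parameters stays below 5%."""
        truth = sg.HierParams(a=3e-7, n=3.0, c=0.8, eta=50.0, m=2.7, b=0.03,
                              d=0.35, q0=0.015, sigma=0.003, stage="peak")
        q = np.geomspace(0.002, 0.5, 120)
        clean = eval_peak_model(truth, q)
        errs = {k: [] for k in ("n", "m", "eta", "q0")}
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            i = clean * (1 + 0.02 * rng.normal(size=q.size))
            curve = sg.ScatteringCurve(q=q, intensity=i)
            res = fit_peak_model(curve, fit_network_model(curve))
            for k in errs:
                errs[k].append(
                    abs(getattr(res.params, k) - getattr(truth, k))
                    / getattr(truth, k)
                )
        for k, v in errs.items():
            assert np.median(v) < 0.05, k


class TestFitSeries:
    def test_methanol_mode_stops_at_network_stage(self):
        met = syn.simulate_methanol_series(noise=0.02, seed=5)
        traj = sg.fit_series(met)
        assert traj.mode == "methanol"
        assert all(r.params.stage == "network" for r in traj.results)

    def test_methanol_recovers_exponent_trend(self):
        met = syn.simulate_methanol_series(noise=0.02, seed=5)
        traj = sg.fit_series(met)
        df = traj.to_frame()
        t = df.time_min.to_numpy()
        truth_n = 2.5 + 1.0 * (1.0 - np.exp(-t / 40.0))
        err = np.abs(df.n.to_numpy() - truth_n) / truth_n
        assert np.median(err) < 0.05

    def test_all_negative_frame_marked_failed_others_fitted(self):
        q = np.geomspace(0.002, 0.5, 120)
        truth = sg.HierParams(a=0.001, n=2.5, c=1.2, eta=50.0, m=2.7, b=0.03)
        good = eval_network_model(truth, q)
        frames = [
            sg.ScatteringCurve(q=q, intensity=good, time_min=5.0),
            sg.ScatteringCurve(q=q, intensity=-np.ones(q.size), time_min=10.0),
            sg.ScatteringCurve(q=q, intensity=good, time_min=15.0),
        ]
        series = sg.CurveSeries(frames=tuple(frames), trigger="methanol")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = sg.fit_series(series, mode="methanol")
        assert traj.results[1].failed
        assert not traj.results[0].failed and not traj.results[2].failed

    def test_trajectory_recovery_on_gdl_series(self, reference_data,
                                               reference_trajectory):
        truth = reference_data["truth"]
        df = reference_trajectory.to_frame()
        for p in ("n", "m", "eta", "q0"):
            err = np.abs(df[p].to_numpy() - truth[p].to_numpy()) / truth[p].to_numpy()
            assert np.median(err) < 0.05, p
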