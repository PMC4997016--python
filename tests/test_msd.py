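"""MSD analysis: brute-force oracle equivalence, closed forms, ensemble
weighting, the anomalous fit, the two-point diffusion rate and transient-D
segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import raftspt as r
from raftspt.msd import MSDCurve, pseudo_log_lags
from raftspt.trajectory import Trajectory


def _random_walk(seed: int, n: int, dt: float = 2e-5) -> Trajectory:
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0, 5e-3, size=(n, 2)), axis=0)
    return Trajectory(frame=np.arange(n), t=np.arange(n) * dt, x=xy[:, 0], y=xy[:, 1])


def _brute_force_msd(traj: Trajectory, lags: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit double loop over (start, lag) pairs."""
    out = np.empty(lags.size)
    for i, k in enumerate(lags):
        acc = []
        for s in range(traj.n_steps - k):
            acc.append(
                (traj.x[s + k] - traj.x[s]) ** 2 + (traj.y[s + k] - traj.y[s]) ** 2
            )
        out[i] = np.mean(acc)
    return out


class TestTimeAveragedMSD:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(20, 100))
    def test_matches_brute_force_oracle(self, seed, n):
        """Vectorized overlapping-pair MSD equals the explicit double loop to
        machine precision on any short trajectory."""
        traj = _random_walk(seed, n)
        lags = np.arange(1, n - 9)
        curve = r.time_averaged_msd(traj, lags=lags)
        expect = _brute_force_msd(traj, np.round(curve.lag_s / 2e-5).astype(int))
        np.testing.assert_allclose(curve.msd_um2, expect, rtol=1e-12)
        np.testing.assert_array_equal(curve.n_pairs, n - lags)

    def test_stationary_trajectory_zero(self):
        n = 200
        traj = Trajectory(
            frame=np.arange(n), t=np.arange(n) * 2e-5, x=np.ones(n), y=np.ones(n)
        )
        curve = r.time_averaged_msd(traj, max_lag_s=1e-3)
        assert np.all(curve.msd_um2 == 0)

    def test_ballistic_closed_form(self):
        """x = v*t gives MSD(k*dt) = v^2*(k*dt)^2 exactly."""
        n, v, dt = 500, 3.0, 2e-5
        t = np.arange(n) * dt
        traj = Trajectory(frame=np.arange(n), t=t, x=v * t, y=np.zeros(n))
        curve = r.time_averaged_msd(traj, max_lag_s=2e-3)
        np.testing.assert_allclose(curve.msd_um2, (v * curve.lag_s) ** 2, rtol=1e-10)

    def test_pair_count_normalization_insensitive_at_scale(self):
        """N-k vs N-k+1 pair conventions agree to <1% for N >= 1,000."""
        traj = _random_walk(123, 1000)
        lags = np.arange(1, 51)
        curve = r.time_averaged_msd(traj, lags=lags)
        alt = np.empty(lags.size)
        for i, k in enumerate(lags):
            # alternative convention: include the wrap-less final start index
            d = np.column_stack([traj.x, traj.y])
            disp = d[k:] - d[:-k]
            s = np.sum(disp[:, 0] ** 2 + disp[:, 1] ** 2)
            alt[i] = s / (1000 - k + 1)
        np.testing.assert_allclose(curve.msd_um2, alt, rtol=0.01)

    def test_sparse_lag_dropped_with_warning(self):
        traj = _random_walk(5, 30)
        with pytest.warns(UserWarning, match="fewer than"):
            curve = r.time_averaged_msd(traj, lags=np.array([1, 2, 25]))
        assert curve.lag_s.size == 2


class TestEnsembleMSD:
    def test_identical_curves_identity(self):
        c = r.time_averaged_msd(_random_walk(1, 300), max_lag_s=1e-3)
        ens = r.ensemble_msd([c, c, c])
        np.testing.assert_allclose(ens.msd_um2, c.msd_um2)

    def test_single_curve_is_identity(self):
        c = r.time_averaged_msd(_random_walk(2, 300), max_lag_s=1e-3)
        np.testing.assert_allclose(r.ensemble_msd([c]).msd_um2, c.msd_um2)

    def test_two_curve_weighted_mean(self):
        """N1=100 at MSD 1.0 and N2=300 at MSD 2.0 average to 1.75."""
        lag = np.array([2e-5, 4e-5])
        c1 = MSDCurve(lag, np.array([1.0, 1.0]), np.array([99, 98]), n_steps=100)
        c2 = MSDCurve(lag, np.array([2.0, 2.0]), np.array([299, 298]), n_steps=300)
        ens = r.ensemble_msd([c1, c2])
        np.testing.assert_allclose(ens.msd_um2, 1.75)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            r.ensemble_msd([])


class TestAnomalousFit:
    def test_exact_model_inversion(self):
        """A noiseless synthetic curve returns its own parameters to 1e-6
        relative accuracy."""
        lag = pseudo_log_lags(1000, 20) * 2e-5
        gamma, alpha, offset = 0.3, 0.75, 4e-4
        msd = 4 * gamma * lag**alpha + offset
        curve = MSDCurve(lag, msd, np.full(lag.size, 1000), n_steps=2000)
        fit = r.fit_anomalous(curve, fit_range_s=(2e-5, 2e-2))
        assert fit.gamma == pytest.approx(gamma, rel=1e-6)
        assert fit.alpha == pytest.approx(alpha, rel=1e-6)
        assert fit.offset_um2 == pytest.approx(offset, rel=1e-6)
        assert fit.classification == "SUB"

    def test_degenerate_constant_curve_flagged(self):
        lag = np.arange(1, 10) * 2e-5
        curve = MSDCurve(lag, np.full(9, 1e-4), np.full(9, 500), n_steps=600)
        fit = r.fit_anomalous(curve, fit_range_s=(2e-5, 2e-2))
        assert fit.classification == "DEGENERATE"
        assert fit.gamma == 0.0

    def test_brownian_classification_band(self):
        lag = pseudo_log_lags(500, 20) * 2e-5
        for alpha, expected in [(0.95, "BROWNIAN"), (0.8, "SUB"), (1.2, "SUPER")]:
            msd = 4 * 0.5 * lag**alpha + 1e-5
            curve = MSDCurve(lag, msd, np.full(lag.size, 1000), n_steps=2000)
            assert r.fit_anomalous(curve, (2e-5, 1e-2)).classification == expected

    def test_summary_reports_parameters(self):
        lag = pseudo_log_lags(500, 20) * 2e-5
        curve = MSDCurve(lag, 4 * 0.5 * lag + 1e-5, np.full(lag.size, 1000), 2000)
        model = r.AnomalousDiffusionModel(curve, fit_range_s=(2e-5, 1e-2))
        text = model.fit().summary()
        assert "alpha" in text and "Gamma" in text and "BROWNIAN" in text


class TestMicroscopicD:
    def test_offset_cancellation(self):
        """The two-point rate recovers D from MSD = 4*D*lag + c for any c."""
        lag = np.array([2e-5, 4e-5, 8e-5])
        for c in (0.0, 1e-4, -1e-5):
            msd = np.clip(4 * 0.7 * lag + c, 0, None)
            if np.any(msd <= 0):
                continue
            curve = MSDCurve(lag, msd, np.array([100, 99, 98]), n_steps=200)
            assert r.microscopic_d(curve) == pytest.approx(0.7, rel=1e-12)

    def test_noise_dominated_returns_negative_with_warning(self):
        lag = np.array([2e-5, 4e-5])
        curve = MSDCurve(lag, np.array([2e-4, 1.5e-4]), np.array([50, 49]), 100)
        with pytest.warns(UserWarning, match="negative"):
            assert r.microscopic_d(curve) < 0

    def test_estimator_consistency_on_benchmark_ensemble(self):
        """Mean per-track two-point D over a simulated free ensemble recovers
        the configured truth within 5%."""
        ds = []
        for i in range(20):
            cfg = r.SimConfig(n_steps=6000, d_free=1.48, seed=700 + i)
            curve = r.time_averaged_msd(r.simulate_brownian(cfg), max_lag_s=3 * 2e-5)
            ds.append(r.microscopic_d(curve))
        assert np.mean(ds) == pytest.approx(1.48, rel=0.05)


class TestTransientD:
    def test_segment_count(self):
        traj = _random_walk(9, 1000)
        out = r.transient_d(traj, segment_len=146)
        assert len(out) == 1000 // 146 == 6

    def test_short_trajectory_single_segment_warns(self):
        traj = _random_walk(10, 200)
        with pytest.warns(UserWarning, match="single-segment"):
            out = r.transient_d(traj, segment_len=146)
        assert len(out) == 1

    def test_change_point_recovery(self):
        """A piecewise walk (D 1.2 then 0.13) shows the step change, each
        plateau within 30% of truth."""
        rng = np.random.default_rng(42)
        n_half, dt = 2920, 2e-5
        s1 = np.sqrt(2 * 1.2 * dt)
        s2 = np.sqrt(2 * 0.13 * dt)
        inc = np.concatenate(
            [rng.normal(0, s1, (n_half, 2)), rng.normal(0, s2, (n_half, 2))]
        )
        xy = np.cumsum(inc, axis=0)
        traj = Trajectory(
            frame=np.arange(2 * n_half), t=np.arange(2 * n_half) * dt, x=xy[:, 0], y=xy[:, 1]
        )
        out = r.transient_d(traj, segment_len=146)
        half = len(out) // 2
        assert out["d_um2_s"][:half].mean() == pytest.approx(1.2, rel=0.3)
        assert out["d_um2_s"][half:].mean() == pytest.approx(0.13, rel=0.3)

    def test_homogeneous_walk_has_no_trend(self):
        """Segment D series of a free walk scatters without a time trend."""
        cfg = r.SimConfig(n_steps=20000, d_free=1.0, seed=13)
        out = r.transient_d(r.simulate_brownian(cfg))
        res = stats.linregress(out["t_center_s"], out["d_um2_s"])
        assert res.pvalue > 0.01


class TestTemporalResolution:
    def test_downsampling_restores_apparent_brownian_motion(self, lo_model):
        """The trap-model subdiffusion is a fast-timescale feature: analyzed
        at the full 50 kHz the Lo ensemble is subdiffusive (alpha < 0.9), but
        downsampled to 1 kHz the same tracks fit as apparent Brownian motion."""
        curves_fast, curves_slow = [], []
        for i in range(4):
            cfg = r.SimConfig(n_steps=25000, d_free=0.26, seed=4000 + i)
            tr = r.simulate_membrane(cfg, lo_model, d_lo_free=0.26, burn_in_steps=250)
            curves_fast.append(r.time_averaged_msd(tr, max_lag_s=1e-3))
            slow = tr.downsample(50)  # 1 kHz
            curves_slow.append(r.time_averaged_msd(slow, max_lag_s=2e-2))
        fast = r.fit_anomalous(r.ensemble_msd(curves_fast), fit_range_s=(2e-5, 1e-3))
        slow = r.fit_anomalous(r.ensemble_msd(curves_slow), fit_range_s=(1e-3, 2e-2))
        assert fast.alpha < 0.9
        assert abs(slow.alpha - 1.0) <= 0.1
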