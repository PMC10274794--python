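"""MSD computation, Brownian D_eff fitting and the Phillies model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from turgorkit import io as io_mod
from turgorkit import synth
from turgorkit.rheology import (
    D0_WATER_40NM,
    DeffEstimate,
    MSDCurve,
    PhilliesFit,
    Track,
    compute_msd,
    fit_deff,
    fit_phillies,
    invert_phillies,
    msd_curves_from_arrays,
    predict_deff,
)

DT = 0.01


def _track(x, y, dt=DT, tid="t0"):
    times = tuple(i * dt for i in range(len(x)))
    return Track(tid, times, tuple(x), tuple(y))


def _exact_curve(d, n=10, dt=DT):
    lags = tuple((k + 1) * dt for k in range(n))
    return MSDCurve(lags, tuple(4 * d * t for t in lags), (100,) * n, (0.0,) * n)


class TestTrack:
    def test_requires_uniform_increasing_times(self):
        with pytest.raises(ValueError, match="uniform"):
            Track("t", (0.0, 0.01, 0.03), (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError, match="increasing"):
            Track("t", (0.0, 0.01, 0.01), (0, 0, 0), (0, 0, 0))

    def test_frame_interval(self):
        assert _track(np.zeros(12), np.zeros(12)).frame_interval == pytest.approx(DT)


class TestComputeMSD:
    def test_stationary_track_is_zero(self):
        curve = compute_msd(_track(np.zeros(20), np.zeros(20)))
        assert all(m == 0.0 for m in curve.msd)

    def test_ballistic_closed_form(self):
        """A constant-velocity track has MSD(k dt) = (v k dt)^2 exactly."""
        v = 3.0
        x = v * DT * np.arange(30)
        curve = compute_msd(_track(x, np.zeros(30)))
        for lag, m in zip(curve.lags, curve.msd):
            assert m == pytest.approx((v * lag) ** 2, rel=1e-10)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            compute_msd(_track(np.zeros(10), np.zeros(10)), max_lag=10)

    def test_pair_counts(self):
        curve = compute_msd(_track(np.zeros(15), np.zeros(15)), max_lag=3)
        assert curve.n_pairs_per_lag == (14, 13, 12)
        assert curve.lags == pytest.approx((DT, 2 * DT, 3 * DT))

    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        theta=st.floats(0, 2 * math.pi),
    )
    def test_rigid_motion_invariance(self, dx, dy, theta):
        """MSD is unchanged by global translation and rotation of a track."""
        rng = np.random.default_rng(99)
        x = np.cumsum(rng.normal(0, 0.1, 40))
        y = np.cumsum(rng.normal(0, 0.1, 40))
        base = compute_msd(_track(x, y))
        xr = dx + x * math.cos(theta) - y * math.sin(theta)
        yr = dy + x * math.sin(theta) + y * math.cos(theta)
        moved = compute_msd(_track(xr, yr))
        assert np.allclose(moved.msd, base.msd, rtol=1e-8, atol=1e-12)

    def test_vectorized_matches_per_track(self, rng):
        times, xs, ys = synth.brownian_positions(rng, 5, 40, DT, 0.3, 0.02)
        fast = msd_curves_from_arrays(times, xs, ys)
        for i, curve in enumerate(fast):
            slow = compute_msd(_track(xs[i], ys[i], tid=str(i)))
            assert np.allclose(curve.msd, slow.msd, rtol=1e-12)
            assert np.allclose(curve.sem_per_lag, slow.sem_per_lag, rtol=1e-12)

    def test_brownian_ensemble_matches_4dtau(self, rng):
        """Ensemble MSD of seeded Brownian tracks sits within 3 SEM of the
        2D diffusion law 4 D tau at each of the first 10 lags."""
        d = 0.40
        times, xs, ys = synth.brownian_positions(rng, 1000, 500, DT, d)
        curves = msd_curves_from_arrays(times, xs, ys)
        msd = np.array([c.msd for c in curves])
        mean = msd.mean(axis=0)
        sem = msd.std(axis=0, ddof=1) / math.sqrt(msd.shape[0])
        taus = np.asarray(curves[0].lags)
        assert np.all(np.abs(mean - 4 * d * taus) < 3 * sem)


class TestFitDeff:
    def test_exact_curve(self):
        est = fit_deff([_exact_curve(0.36)])
        assert est.d_eff == pytest.approx(0.36, rel=1e-12)

    def test_linearity(self):
        base = fit_deff([_exact_curve(0.25)])
        doubled = MSDCurve(
            _exact_curve(0.25).lags,
            tuple(2 * m for m in _exact_curve(0.25).msd),
            (100,) * 10,
            (0.0,) * 10,
        )
        assert fit_deff([doubled]).d_eff == pytest.approx(2 * base.d_eff, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_deff([])

    def test_short_curves_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            est = fit_deff([_exact_curve(0.3), _exact_curve(0.3, n=4)])
        assert est.n_tracks == 1
        assert "excluded 1" in caplog.text

    def test_brownian_recovery(self, rng):
        d = 0.24
        times, xs, ys = synth.brownian_positions(rng, 1000, 500, DT, d)
        est = fit_deff(msd_curves_from_arrays(times, xs, ys))
        assert abs(est.d_eff - d) < 3 * est.sem
        assert est.n_tracks == 1000

    def test_intercept_absorbs_localization_offset(self, rng):
        """With localization noise, the free-intercept fit removes most of
        the static MSD offset that biases the through-origin slope up."""
        d, loc = 0.20, 0.05
        times, xs, ys = synth.brownian_positions(rng, 2000, 500, DT, d, loc)
        curves = msd_curves_from_arrays(times, xs, ys)
        plain = fit_deff(curves).d_eff
        with_icpt = fit_deff(curves, intercept=True).d_eff
        assert plain > d  # offset inflates the origin-constrained slope
        assert abs(with_icpt - d) < abs(plain - d)


class TestPhillies:
    def test_exact_beta_recovery(self):
        beta, c0 = 3.0, 0.3
        c = np.array([0.1, 0.3, 0.5])
        d = D0_WATER_40NM * np.exp(-beta * (c + c0))
        assert d[0] == pytest.approx(4.0842, abs=1e-4)
        fit = fit_phillies(c, d, c0_medium=c0)
        assert fit.beta == pytest.approx(beta, rel=1e-12)
        assert predict_deff(fit, 0.1) == pytest.approx(d[0], rel=1e-12)

    def test_log_and_linear_space_agree_noiseless(self):
        beta, c0 = 4.8, 0.3
        c = np.linspace(0.1, 0.6, 6)
        d = D0_WATER_40NM * np.exp(-beta * (c + c0))
        log_fit = fit_phillies(c, d, c0_medium=c0, space="log")
        lin_fit = fit_phillies(c, d, c0_medium=c0, space="linear")
        assert lin_fit.beta == pytest.approx(log_fit.beta, rel=0.01)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_phillies([0.2, 0.2], [1.0, 1.1], c0_medium=0.3)

    def test_unphysical_deff_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            fit_phillies([0.1, 0.2], [14.0, 1.0], c0_medium=0.3)

    def test_noisy_beta_within_errors(self, rng):
        beta, c0 = 4.0, 0.3
        c = np.linspace(0.1, 0.6, 6)
        d = D0_WATER_40NM * np.exp(-beta * (c + c0)) * (1 + rng.normal(0, 0.05, 6))
        fit = fit_phillies(c, d, c0_medium=c0)
        assert abs(fit.beta - beta) < 3 * math.sqrt(fit.beta_variance)

    def test_predicted_deff_strictly_decreasing(self):
        fit = PhilliesFit(D0_WATER_40NM, 3.0, 0.3, 0.0)
        d = [predict_deff(fit, c) for c in np.linspace(0, 1, 20)]
        assert np.all(np.diff(d) < 0)
        assert max(d) <= fit.d0


class TestInvertPhillies:
    fit = PhilliesFit(d0=D0_WATER_40NM, beta=3.0, c0_medium=0.3, beta_variance=0.0)

    def test_inverse_of_forward_example(self):
        est = invert_phillies(self.fit, DeffEstimate(4.084194, 0.0, 100))
        assert est.c_iso == pytest.approx(0.1, abs=1e-6)
        assert est.method == "rheology"

    def test_round_trip(self):
        for c in (0.05, 0.25, 0.55):
            d = predict_deff(self.fit, c)
            est = invert_phillies(self.fit, DeffEstimate(d, 0.0, 1))
            assert est.c_iso == pytest.approx(c, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            invert_phillies(self.fit, DeffEstimate(14.0, 0.0, 1))
        with pytest.raises(ValueError):
            invert_phillies(self.fit, DeffEstimate(0.0, 0.0, 1))

    def test_negative_concentration_diagnostic(self):
        d_above_medium = predict_deff(self.fit, -0.1)  # mobility too high
        with pytest.raises(ValueError, match="negative"):
            invert_phillies(self.fit, DeffEstimate(d_above_medium, 0.0, 1))

    def test_error_terms(self):
        fit = PhilliesFit(D0_WATER_40NM, 3.0, 0.3, beta_variance=0.01)
        d = predict_deff(fit, 0.2)
        est = invert_phillies(fit, DeffEstimate(d, 0.02, 500))
        log_ratio = math.log(fit.d0 / d)
        expected = math.sqrt(
            (log_ratio / 9.0) ** 2 * 0.01 + (1.0 / (3.0 * d)) ** 2 * 0.02**2
        )
        assert est.c_iso_err == pytest.approx(expected)


def test_rheology_pipeline_recovers_truth():
    """Full track pipeline on the default scenario recovers the generating
    isotonic concentration (0.43 mol/L) within 5%."""
    for seed in (11, 12):
        df = synth.gen_brownian_tracks(synth.default_rheology_scenario(seed))
        est, fit, per_cond = io_mod.run_rheology_method(df)
        assert est.c_iso == pytest.approx(0.43, rel=0.05)
        assert all(e.n_tracks == 1000 for e in per_cond.values())
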