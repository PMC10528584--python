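"""P_HR ratio, dose scan and the near-exponential decay fit."""

import numpy as np
import pytest

from dsbrepair import (
    FociTimecourse,
    fit_exponential_decay,
    foci_readout,
    phr,
    phr_dose_scan,
    time_mean,
)
from dsbrepair.hr import UndefinedRatioError, dose_grid_mgy, sample_mean


class TestTimeMean:
    def test_constant_series(self):
        t = np.linspace(0, 24, 49)
        tc = FociTimecourse(times=t, gamma_h2ax=np.full_like(t, 3.5), rad51=t)
        assert time_mean(tc, "gammaH2AX") == pytest.approx(3.5)

    def test_linear_series(self):
        t = np.linspace(0, 24, 49)
        tc = FociTimecourse(times=t, gamma_h2ax=t.copy(), rad51=t.copy())
        assert time_mean(tc, "gammaH2AX") == pytest.approx(12.0)

    def test_window_outside_grid_rejected(self):
        t = np.linspace(0, 10, 11)
        tc = FociTimecourse(times=t, gamma_h2ax=t, rad51=t)
        with pytest.raises(ValueError):
            time_mean(tc, "gammaH2AX", window=(0, 24))

    def test_dense_grid_quadrature_converged(self, params, model):
        """Default dense grid agrees with a 10x finer quadrature."""
        from dsbrepair import ExposureProtocol, run_protocol

        proto = ExposureProtocol.from_mgy(250.0)
        coarse = np.arange(0.0, 24.0 + 1e-9, 0.05)
        fine = np.arange(0.0, 24.0 + 1e-9, 0.005)
        m_c = time_mean(
            foci_readout(run_protocol(proto, params, coarse, model=model), params),
            "gammaH2AX",
        )
        m_f = time_mean(
            foci_readout(run_protocol(proto, params, fine, model=model), params),
            "gammaH2AX",
        )
        assert abs(m_c - m_f) / m_f < 1e-4


class TestPhr:
    def test_identical_channels_give_100(self, trajectory_at, params):
        p = params.with_updates({})
        traj = trajectory_at(250.0)
        tc = foci_readout(traj, p, include_background=False)
        # force the two channels equal through the scale-free ratio identity
        ratio = phr(traj, p)
        y9 = time_mean(tc, "Rad51")
        x14 = time_mean(tc, "gammaH2AX")
        assert ratio == pytest.approx(100.0 * y9 / x14)
        same = FociTimecourse(times=tc.times, gamma_h2ax=tc.gamma_h2ax,
                              rad51=tc.gamma_h2ax.copy())
        assert 100.0 * time_mean(same, "Rad51") / time_mean(same, "gammaH2AX") == pytest.approx(100.0)

    def test_zero_rad51_gives_zero(self, params, trajectory_at):
        p = params.with_updates({"P6": 0.0})  # no Rad51 loading
        from dsbrepair import ExposureProtocol, RepairModel, run_protocol

        traj = run_protocol(ExposureProtocol.from_mgy(100.0), p, model=RepairModel(p))
        assert phr(traj, p) == pytest.approx(0.0, abs=1e-12)

    def test_zero_dose_without_background_is_undefined(self, params, trajectory_at):
        with pytest.raises(UndefinedRatioError):
            phr(trajectory_at(0.0), params)

    def test_mean_linearity_over_marker_species(self, params, trajectory_at):
        """Mean of the summed Rad51 channel equals the sum of species means."""
        traj = trajectory_at(500.0)
        model = traj.model
        total = 0.0
        for idx in model.rad51_idx:
            series = traj.states[:, idx]
            total += np.trapezoid(series, traj.times) / (traj.times[-1] - traj.times[0])
        tc = foci_readout(traj, params, include_background=False)
        assert time_mean(tc, "Rad51") == pytest.approx(total)


class TestDoseScan:
    def test_grid_arithmetic(self):
        assert len(dose_grid_mgy(0, 1000, 250, skip_zero=False)) == 5
        assert len(dose_grid_mgy(0, 1000, 250, skip_zero=True)) == 4
        assert len(dose_grid_mgy(20, 1000, 245, skip_zero=True)) == 5

    def test_shared_doses_bitwise_equal_across_steps(self):
        g10 = dose_grid_mgy(20, 60, 10)
        g01 = dose_grid_mgy(20, 60, 0.1)
        shared = np.intersect1d(g10, g01)
        assert len(shared) == len(g10) == 5

    def test_scan_is_deterministic(self, params):
        a = phr_dose_scan(params, 100, 400, 100, fit_decay=False)
        b = phr_dose_scan(params, 100, 400, 100, fit_decay=False)
        assert np.array_equal(a.phr_percent, b.phr_percent)

    def test_scan_smoothness(self, params):
        """Neighbouring scan values move smoothly: step sizes stay below the
        curve-scale bound and second differences are far smaller than first
        differences (no numerical jitter)."""
        curve = phr_dose_scan(params, 100, 300, 25, fit_decay=False)
        steps = np.diff(curve.phr_percent)
        assert np.abs(steps).max() < 2.0  # percent per 25 mGy
        assert np.abs(np.diff(steps)).max() < 0.3 * np.abs(steps).max()


class TestExponentialDecayFit:
    def test_exact_recovery_on_noiseless_input(self):
        d = np.linspace(0, 1000, 60)
        y = 5.0 + 40.0 * np.exp(-0.004 * d)
        fitp = fit_exponential_decay(d, y)
        assert fitp["asymptote"] == pytest.approx(5.0, abs=1e-6)
        assert fitp["amplitude"] == pytest.approx(40.0, abs=1e-6)
        assert fitp["rate_per_mgy"] == pytest.approx(0.004, abs=1e-9)
        assert fitp["rms_residual"] < 1e-8

    def test_constant_data(self):
        d = np.linspace(0, 1000, 20)
        fitp = fit_exponential_decay(d, np.full_like(d, 7.0))
        assert fitp["amplitude"] == pytest.approx(0.0, abs=1e-6)
        assert fitp["asymptote"] + fitp["amplitude"] == pytest.approx(7.0, abs=1e-6)

    def test_beats_linear_fit_on_curved_data(self):
        d = np.linspace(0, 1000, 40)
        y = 2.0 + 30.0 * np.exp(-0.006 * d)
        fitp = fit_exponential_decay(d, y)
        assert fitp["rms_residual"] < fitp["rms_linear"]

    def test_too_few_points_rejected(self):
        from dsbrepair.hr import FitError

        with pytest.raises(FitError):
            fit_exponential_decay(np.array([0, 1, 2]), np.array([1.0, 0.5, 0.2]))


def test_sample_mean_matches_figure_style_estimate(params, trajectory_at):
    tc = foci_readout(trajectory_at(250.0), params)
    pts = np.array([0.25, 0.5, 1, 2, 4, 6, 16, 24])
    m = sample_mean(tc, "gammaH2AX", pts)
    assert m == pytest.approx(np.interp(pts, tc.times, tc.gamma_h2ax).mean())
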