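"""Percentage contribution of homologous recombination to DSB repair.

The HR contribution at a dose D is the ratio of the 24-h time-averaged
Rad51 and gamma-H2AX foci counts::

    P_HR(D) = 100 * mean_24h(Rad51) / mean_24h(gamma-H2AX)

scanned over a dose grid to give the near-exponentially decreasing curve
P_HR(D) = asymptote + amplitude * exp(-rate * D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import RepairModel
from .parameters import ModelParameters
from .simulate import (
    ExposureProtocol,
    FociTimecourse,
    Trajectory,
    default_output_times,
    foci_readout,
    run_protocol,
)


class UndefinedRatioError(ZeroDivisionError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class PHRCurve:
    """P_HR values on a dose grid with the fitted exponential decay."""

    dose_mgy: np.ndarray
    phr_percent: np.ndarray
    decay: dict | None = None
    failures: dict | None = None

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.dose_mgy) > 0):
            raise ValueError("dose grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_mGy": self.dose_mgy, "phr_percent": self.phr_percent}
        )


def time_mean(tc: FociTimecourse, channel: str, window: tuple[float, float] = (0.0, 24.0)) -> float:
    """Trapezoidal time-average of a foci channel over ``window`` (hours)."""
    t0, t1 = window
    if t0 < tc.times[0] - 1e-12 or t1 > tc.times[-1] + 1e-12:
        raise ValueError(f"window {window} outside the trajectory grid")
    if t1 <= t0:
        raise ValueError("window must have positive length")
    mask = (tc.times >= t0 - 1e-12) & (tc.times <= t1 + 1e-12)
    t = tc.times[mask]
    y = tc.channel(channel)[mask]
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def sample_mean(tc: FociTimecourse, channel: str, times: np.ndarray) -> float:
    """Plain mean over sampled timepoints (figure-style estimate)."""
    y = np.interp(times, tc.times, tc.channel(channel))
    return float(np.mean(y))


def phr(traj: Trajectory, params: ModelParameters | None = None,
        include_background: bool = False,
        window: tuple[float, float] = (0.0, 24.0)) -> float:
    """P_HR (percent) from a trajectory.

    Backgrounds are excluded by default: the ratio is defined on the model's
    own Rad51 and gamma-H2AX variables.
    """
    tc = foci_readout(traj, params, include_background=include_background)
    x14 = time_mean(tc, "gammaH2AX", window)
    y9 = time_mean(tc, "Rad51", window)
    if x14 <= 0:
        raise UndefinedRatioError("mean gamma-H2AX is zero; P_HR undefined")
    return 100.0 * y9 / x14


def dose_grid_mgy(dose_min: float, dose_max: float, step: float,
                  skip_zero: bool = True) -> np.ndarray:
    """Strictly increasing dose grid in mGy.

    Doses are rounded to 1e-6 mGy so grids built with different steps agree
    bitwise at shared doses.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if dose_max <= dose_min or dose_min < 0:
        raise ValueError("need dose_max > dose_min >= 0")
    n = int(np.floor((dose_max - dose_min) / step + 1e-9)) + 1
    grid = np.round(dose_min + step * np.arange(n), 6)
    if skip_zero:
        grid = grid[grid > 0]
    return grid


def phr_dose_scan(
    params: ModelParameters,
    dose_min_mgy: float = 0.0,
    dose_max_mgy: float = 1000.0,
    step_mgy: float = 0.1,
    skip_zero: bool = True,
    include_background: bool = False,
    fit_decay: bool = True,
    model: RepairModel | None = None,
    output_times: np.ndarray | None = None,
) -> PHRCurve:
    """One independent simulation per grid dose; P_HR at each.

    Simulation failures at individual doses are recorded in
    ``curve.failures`` and the scan continues.
    """
    if model is None:
        model = RepairModel(params)
    if output_times is None:
        output_times = default_output_times()
    doses = dose_grid_mgy(dose_min_mgy, dose_max_mgy, step_mgy, skip_zero)
    values = []
    kept = []
    failures: dict[float, str] = {}
    for d in doses:
        try:
            traj = run_protocol(
                ExposureProtocol.from_mgy(d), params, output_times, model=model
            )
            values.append(phr(traj, params, include_background=include_background))
            kept.append(d)
        except Exception as exc:  # noqa: BLE001 - reported per dose
            failures[float(d)] = str(exc)
    curve = PHRCurve(
        dose_mgy=np.array(kept),
        phr_percent=np.array(values),
        failures=failures or None,
    )
    if fit_decay and len(kept) >= 4:
        curve.decay = fit_exponential_decay(curve.dose_mgy, curve.phr_percent)
    return curve


def fit_exponential_decay(x: np.ndarray, y: np.ndarray) -> dict:
    """Least-squares fit of ``y = asymptote + amplitude * exp(-rate * x)``.

    Returns the parameters, the RMS residual, and the RMS of a straight-line
    fit for comparison.  Raises :class:`FitError` on non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise FitError("need at least 4 points to fit the decay")
    span = x.max() - x.min()
    amp0 = y.max() - y.min()
    theta0 = np.array([y.min(), max(amp0, 1e-12), 1.0 / max(span, 1e-12)])

    def resid(theta):
        a, b, k = theta
        return a + b * np.exp(-k * x) - y

    res = least_squares(
        resid,
        theta0,
        bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
    )
    if not res.success:
        raise FitError(f"exponential decay fit did not converge: {res.message}")
    a, b, k = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    lin = np.polyfit(x, y, 1)
    rms_linear = float(np.sqrt(np.mean((np.polyval(lin, x) - y) ** 2)))
    return {
        "asymptote": float(a),
        "amplitude": float(b),
        "rate_per_mgy": float(k),
        "rms_residual": rms,
        "rms_linear": rms_linear,
    }
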