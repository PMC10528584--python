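"""Calibration of model parameters against foci time-course data.

The objective mirrors the presentation convention of the emulated study:
model and data curves are both normalized to their own 24-h maximum per
channel per dose, and compared by weighted least squares (weights 1/SE**2
where SE > 0, unit weight otherwise).  Fitting runs in log-parameter space
(positivity for free), bounded, multistart, and is deterministic given a
seed.  With ~50 rate constants and two readout channels the full model is
not identifiable, so the interface requires an explicit free-parameter
subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datasets import FociDataset
from .model import RepairModel
from .parameters import ModelParameters
from .simulate import ExposureProtocol, foci_readout, run_protocol

logger = logging.getLogger(__name__)

#: Penalty residual magnitude substituted when a simulation fails.
PENALTY = 1e3


@dataclass
class LossOptions:
    normalize: bool = True
    rtol: float | None = None  # None = use params.solver settings
    atol: float | None = None
    window_h: float = 24.0


@dataclass
class FitResult:
    values: dict[str, float]
    loss: float
    per_dose_loss: dict[float, float]
    converged: bool
    at_bounds: dict[str, bool]
    n_starts: int
    seed: int | None
    starts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "loss": self.loss,
            "per_dose_loss": {str(k): v for k, v in self.per_dose_loss.items()},
            "converged": self.converged,
            "at_bounds": self.at_bounds,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "starts": self.starts,
        }


def _residual_blocks(
    trial: ModelParameters,
    dataset: FociDataset,
    options: LossOptions,
) -> dict[float, tuple[np.ndarray, bool]]:
    """Weighted residuals per dose; second element flags a failed simulation."""
    model = RepairModel(trial)
    out: dict[float, tuple[np.ndarray, bool]] = {}
    for dose in dataset.doses:
        sub = dataset.df[dataset.df["dose_mGy"] == dose]
        times = np.sort(sub["time_h"].unique())
        try:
            traj = run_protocol(
                ExposureProtocol.from_mgy(dose),
                trial,
                times,
                model=model,
                rtol=options.rtol,
                atol=options.atol,
            )
            tc = foci_readout(traj, trial)
        except Exception as exc:  # noqa: BLE001 - converted to penalty
            n = len(sub)
            logger.warning("simulation failed at %s mGy: %s", dose, exc)
            out[float(dose)] = (np.full(n, PENALTY), True)
            continue
        resids = []
        for channel in ("gammaH2AX", "Rad51"):
            rows = dataset.select(dose, channel)
            if rows.empty:
                continue
            model_vals = np.interp(rows["time_h"].to_numpy(), tc.times, tc.channel(channel))
            data_vals = rows["mean"].to_numpy(dtype=float)
            se = rows["se"].to_numpy(dtype=float)
            if options.normalize:
                mmax, dmax = model_vals.max(), data_vals.max()
                if mmax > 0:
                    model_vals = model_vals / mmax
                if dmax > 0:
                    data_vals = data_vals / dmax
                    se = se / dmax  # normalization rescales the data error too
            w = np.where(se > 0, 1.0 / np.where(se > 0, se, 1.0) ** 2, 1.0)
            resids.append(np.sqrt(w) * (model_vals - data_vals))
        out[float(dose)] = (np.concatenate(resids), False)
    return out


def loss(
    free_params: dict[str, float],
    dataset: FociDataset,
    params: ModelParameters,
    options: LossOptions | None = None,
) -> float:
    """Weighted sum of squared residuals for a candidate parameter update."""
    options = options or LossOptions()
    trial = params.with_updates(free_params)
    blocks = _residual_blocks(trial, dataset, options)
    return float(sum((r**2).sum() for r, _ in blocks.values()))


def fit(
    dataset: FociDataset,
    free_param_names: list[str],
    bounds: dict[str, tuple[float, float]],
    params: ModelParameters,
    n_starts: int = 3,
    seed: int = 0,
    options: LossOptions | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Multistart bounded least squares in log-parameter space.

    ``bounds`` maps each free parameter to a positive (lo, hi) interval.
    Start 0 is the geometric mid-point of the bounds; further starts are
    drawn log-uniformly with the seeded generator.  Raises ``RuntimeError``
    if every start fails.
    """
    options = options or LossOptions()
    for name in free_param_names:
        params.value(name)  # raises ConfigurationError for unknown names
        lo, hi = bounds[name]
        if not (0 < lo < hi):
            raise ValueError(f"bounds for {name!r} must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    log_lo = np.log([bounds[n][0] for n in free_param_names])
    log_hi = np.log([bounds[n][1] for n in free_param_names])

    def residual(theta: np.ndarray) -> np.ndarray:
        values = dict(zip(free_param_names, np.exp(theta)))
        blocks = _residual_blocks(params.with_updates(values), dataset, options)
        return np.concatenate([r for r, _ in blocks.values()])

    starts = [0.5 * (log_lo + log_hi)]
    for _ in range(n_starts - 1):
        starts.append(log_lo + rng.random(len(free_param_names)) * (log_hi - log_lo))

    results, diagnostics = [], []
    for k, theta0 in enumerate(starts):
        try:
            res = least_squares(
                residual,
                theta0,
                bounds=(log_lo, log_hi),
                method="trf",
                x_scale="jac",
                max_nfev=max_nfev,
            )
            results.append(res)
            diagnostics.append(
                {"start": k, "cost": float(res.cost), "status": int(res.status)}
            )
        except Exception as exc:  # noqa: BLE001
            diagnostics.append({"start": k, "error": str(exc)})
    if not results:
        raise RuntimeError(f"all fit starts failed: {diagnostics}")

    best = min(results, key=lambda r: r.cost)
    values = dict(zip(free_param_names, np.exp(best.x)))
    blocks = _residual_blocks(params.with_updates(values), dataset, options)
    per_dose = {d: float((r**2).sum()) for d, (r, _) in blocks.items()}
    tol = 1e-8
    at_bounds = {
        n: bool(
            abs(best.x[i] - log_lo[i]) < tol or abs(best.x[i] - log_hi[i]) < tol
        )
        for i, n in enumerate(free_param_names)
    }
    return FitResult(
        values=values,
        loss=float(2.0 * best.cost),
        per_dose_loss=per_dose,
        converged=bool(best.status > 0),
        at_bounds=at_bounds,
        n_starts=len(starts),
        seed=seed,
        starts=diagnostics,
    )


def recovery_report(
    true_params: dict[str, float] | ModelParameters,
    fitted: FitResult,
) -> pd.DataFrame:
    """Relative error |fitted - true| / true per shared parameter."""
    rows = []
    for name, est in fitted.values.items():
        truth = (
            true_params[name]
            if isinstance(true_params, dict)
            else true_params.value(name)
        )
        rows.append((name, float(truth), float(est), abs(est - truth) / abs(truth)))
    return pd.DataFrame(rows, columns=["parameter", "true", "fitted", "rel_error"])
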