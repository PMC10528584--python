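"""Synthetic foci datasets emulating the study design.

Per-cell gamma-H2AX and Rad51 counts are drawn around the kinetic model's
population-mean readout (Poisson by default — foci are counts — with a
negative-binomial option for cell-to-cell overdispersion), for the design
doses {20, 40, 80, 160, 250, 500, 1000} mGy, sampling times 0.25–24 h,
200 cells per point and three independent replicates.  The CENPF channel
emulates the S/G2-phase cell fraction: a near-exponential decrease with
dose, an optional (statistically insignificant) low-dose bump, and binomial
counting noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import PER_CELL_COLUMNS, SUMMARY_COLUMNS, FociDataset, summarize
from .model import RepairModel
from .parameters import ModelParameters
from .simulate import ExposureProtocol, foci_readout, run_protocol

DEFAULT_DOSES_MGY = (20.0, 40.0, 80.0, 160.0, 250.0, 500.0, 1000.0)
DEFAULT_TIMEPOINTS_H = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 16.0, 24.0)

#: Dose (mGy) at which the optional CENPF low-dose bump peaks.
CENPF_BUMP_DOSE_MGY = 80.0


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Design and noise settings for the synthetic generator."""

    doses_mgy: tuple = DEFAULT_DOSES_MGY
    timepoints_h: tuple = DEFAULT_TIMEPOINTS_H
    n_cells: int = 200
    n_replicates: int = 3
    noise: str = "poisson"  # or "negative_binomial"
    dispersion: float = 10.0  # NB shape; larger = closer to Poisson
    cenpf_baseline_fraction: float = 0.30
    cenpf_decay_per_mgy: float = 0.0019345  # ln(6.93)/1000: 6.93-fold at 1 Gy
    cenpf_bump_amplitude: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_replicates < 1:
            raise GeneratorConfigError("n_cells and n_replicates must be >= 1")
        doses = np.asarray(self.doses_mgy, dtype=float)
        times = np.asarray(self.timepoints_h, dtype=float)
        if (doses <= 0).any() or len(set(doses)) != len(doses):
            raise GeneratorConfigError("doses must be positive and unique")
        if (times <= 0).any() or len(set(times)) != len(times):
            raise GeneratorConfigError("timepoints must be positive and unique")
        if self.noise not in ("poisson", "negative_binomial"):
            raise GeneratorConfigError(f"unknown noise model {self.noise!r}")
        if self.noise == "negative_binomial" and self.dispersion <= 0:
            raise GeneratorConfigError("dispersion must be > 0")
        if not 0.0 < self.cenpf_baseline_fraction < 1.0:
            raise GeneratorConfigError("cenpf baseline fraction must be in (0,1)")


def _draw_counts(rng: np.random.Generator, mean: float, n: int, cfg: GeneratorConfig):
    if mean <= 0:
        return np.zeros(n, dtype=int)
    if cfg.noise == "poisson":
        return rng.poisson(mean, size=n)
    theta = cfg.dispersion
    return rng.negative_binomial(theta, theta / (theta + mean), size=n)


def model_means(params: ModelParameters, cfg: GeneratorConfig,
                model: RepairModel | None = None) -> pd.DataFrame:
    """Population-mean foci counts (readout + background) per design point."""
    if model is None:
        model = RepairModel(params)
    times = np.asarray(sorted(cfg.timepoints_h), dtype=float)
    rows = []
    for dose in cfg.doses_mgy:
        traj = run_protocol(ExposureProtocol.from_mgy(dose), params, times, model=model)
        tc = foci_readout(traj, params)
        for t, g, r in zip(tc.times, tc.gamma_h2ax, tc.rad51):
            rows.append((dose, t, "gammaH2AX", g))
            rows.append((dose, t, "Rad51", r))
    return pd.DataFrame(rows, columns=["dose_mGy", "time_h", "channel", "mean"])


def generate_foci_dataset(
    params: ModelParameters,
    cfg: GeneratorConfig,
    model: RepairModel | None = None,
) -> tuple[FociDataset, pd.DataFrame]:
    """Synthetic per-cell foci counts and their summary.

    Fully reproducible from ``cfg.seed``: returns ``(summary, per_cell)``.
    """
    rng = np.random.default_rng(cfg.seed)
    means = model_means(params, cfg, model=model)
    recs = []
    for row in means.itertuples(index=False):
        for rep in range(1, cfg.n_replicates + 1):
            counts = _draw_counts(rng, row.mean, cfg.n_cells, cfg)
            recs.append(
                pd.DataFrame(
                    {
                        "dose_mGy": row.dose_mGy,
                        "time_h": row.time_h,
                        "replicate": rep,
                        "cell_id": np.arange(1, cfg.n_cells + 1),
                        "channel": row.channel,
                        "count": counts,
                    }
                )
            )
    per_cell = pd.concat(recs, ignore_index=True)[PER_CELL_COLUMNS]
    dataset = summarize(per_cell)
    dataset.metadata.update(
        {
            "source": "synthetic",
            "noise": cfg.noise,
            "seed": cfg.seed,
            "n_cells": cfg.n_cells,
            "n_replicates": cfg.n_replicates,
        }
    )
    return dataset, per_cell


def cenpf_true_fraction(dose_mgy: float, cfg: GeneratorConfig) -> float:
    """Near-exponential decay of the S/G2 fraction with an optional bump."""
    d = float(dose_mgy)
    base = cfg.cenpf_baseline_fraction * np.exp(-cfg.cenpf_decay_per_mgy * d)
    bump = cfg.cenpf_bump_amplitude * (d / CENPF_BUMP_DOSE_MGY) * np.exp(
        1.0 - d / CENPF_BUMP_DOSE_MGY
    )
    p = base + bump
    if not 0.0 < p < 1.0:
        raise GeneratorConfigError(
            f"CENPF fraction {p:.4g} at {dose_mgy} mGy outside (0, 1)"
        )
    return float(p)


def generate_cenpf_dataset(cfg: GeneratorConfig, time_h: float = 24.0) -> FociDataset:
    """CENPF-positive cell fractions (binomial noise, per replicate)."""
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    doses = (0.0,) + tuple(cfg.doses_mgy)
    for dose in doses:
        p = cenpf_true_fraction(dose, cfg)
        fracs = rng.binomial(cfg.n_cells, p, size=cfg.n_replicates) / cfg.n_cells
        mean = float(fracs.mean())
        if cfg.n_replicates > 1:
            se = float(fracs.std(ddof=1) / np.sqrt(cfg.n_replicates))
            kind = "across_replicates"
        else:
            se, kind = 0.0, "within_replicate"
        rows.append(
            (dose, time_h, "CENPF", mean, se, cfg.n_cells, cfg.n_replicates, kind)
        )
    return FociDataset(
        pd.DataFrame(rows, columns=SUMMARY_COLUMNS),
        metadata={"source": "synthetic", "channel": "CENPF", "seed": cfg.seed},
    )
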