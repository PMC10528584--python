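"""Foci time-course datasets: summary tables and per-cell counts.

A :class:`FociDataset` holds one summary row per (dose, time, channel):
the mean foci count (or positive-cell fraction for CENPF), its standard
error, the number of cells scored and the number of replicate experiments.
The emulated design follows the study layout: >=200 cells per point, means
of three independent experiments +/- SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("gammaH2AX", "Rad51", "CENPF")

SUMMARY_COLUMNS = [
    "dose_mGy",
    "time_h",
    "channel",
    "mean",
    "se",
    "n_cells",
    "n_replicates",
    "se_kind",
]

PER_CELL_COLUMNS = ["dose_mGy", "time_h", "replicate", "cell_id", "channel", "count"]


@dataclass
class FociDataset:
    """Summary foci table plus free-form metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS[:5] if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary table lacks columns {missing}")
        bad = set(self.df["channel"]) - set(CHANNELS)
        if bad:
            raise ValueError(f"unknown channels {sorted(bad)}")
        if (self.df["se"] < 0).any():
            raise ValueError("SE must be >= 0")
        if (self.df["time_h"] < 0).any() or (self.df["dose_mGy"] < 0).any():
            raise ValueError("doses and times must be >= 0")
        if "n_cells" in self.df and (self.df["n_cells"] < 1).any():
            raise ValueError("n_cells must be >= 1")
        keys = self.df[["dose_mGy", "time_h", "channel"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (dose, time, channel) keys")

    # -- access ---------------------------------------------------------
    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.df["dose_mGy"].unique())

    def select(self, dose_mgy: float, channel: str) -> pd.DataFrame:
        sub = self.df[
            (self.df["dose_mGy"] == dose_mgy) & (self.df["channel"] == channel)
        ]
        return sub.sort_values("time_h")

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "FociDataset":
        return cls(pd.read_csv(path), metadata=metadata)


def summarize(per_cell: pd.DataFrame) -> FociDataset:
    """Summarize a per-cell count table.

    Replicate means are computed first; the reported mean and SE are then
    taken across replicates (SE = sd / sqrt(n_replicates), the convention of
    a three-independent-experiments design).  With a single replicate the SE
    falls back to the within-replicate standard error of the mean and is
    flagged via ``se_kind``.
    """
    missing = [c for c in PER_CELL_COLUMNS if c not in per_cell.columns]
    if missing:
        raise ValueError(f"per-cell table lacks columns {missing}")
    rows = []
    grouped = per_cell.groupby(["dose_mGy", "time_h", "channel"], sort=True)
    for (dose, time, channel), sub in grouped:
        rep_means = sub.groupby("replicate")["count"].mean()
        n_rep = len(rep_means)
        n_cells = int(sub.groupby("replicate")["cell_id"].count().min())
        if n_rep > 1:
            mean = float(rep_means.mean())
            se = float(rep_means.std(ddof=1) / np.sqrt(n_rep))
            kind = "across_replicates"
        else:
            mean = float(sub["count"].mean())
            sd = float(sub["count"].std(ddof=1)) if len(sub) > 1 else 0.0
            se = sd / np.sqrt(len(sub))
            kind = "within_replicate"
        rows.append((dose, time, channel, mean, se, n_cells, n_rep, kind))
    return FociDataset(pd.DataFrame(rows, columns=SUMMARY_COLUMNS))


def dataset_from_model(params, doses_mgy, times_h, model=None) -> FociDataset:
    """Noise-free dataset whose means are exactly the model readout.

    Useful as a self-consistency input for the calibration loss; SE is set
    to 0 (unit weights).
    """
    from .simulate import ExposureProtocol, foci_readout, run_protocol

    times_h = np.asarray(sorted(times_h), dtype=float)
    rows = []
    for dose in doses_mgy:
        traj = run_protocol(
            ExposureProtocol.from_mgy(dose), params, times_h, model=model
        )
        tc = foci_readout(traj, params)
        for t, g, r in zip(tc.times, tc.gamma_h2ax, tc.rad51):
            rows.append((dose, t, "gammaH2AX", g, 0.0, 1, 1, "exact"))
            rows.append((dose, t, "Rad51", r, 0.0, 1, 1, "exact"))
    return FociDataset(
        pd.DataFrame(rows, columns=SUMMARY_COLUMNS),
        metadata={"source": "model", "noise": "none"},
    )
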