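"""Simulate gamma-H2AX and Rad51 foci time-courses for the design doses.

Runs the kinetic repair model for X-ray doses of 20-1000 mGy delivered at
40 mGy/min, writes the raw and max-normalized foci time-courses, and prints
the peak times and 24-h residual levels that summarize the fast-NHEJ /
slow-HR kinetics.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dsbrepair import (
    ExposureProtocol,
    RepairModel,
    default_parameters,
    foci_readout,
    normalize_to_max,
    peak_time,
    residual_fraction,
    run_protocol,
)
from dsbrepair.synthetic import DEFAULT_DOSES_MGY

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = default_parameters()
    model = RepairModel(params)
    frames, norm_frames, rows = [], [], []
    for dose in DEFAULT_DOSES_MGY:
        traj = run_protocol(ExposureProtocol.from_mgy(dose), params, model=model)
        tc = foci_readout(traj, params)
        ntc = normalize_to_max(tc)
        frames.append(traj.to_frame())
        norm_frames.append(
            pd.DataFrame(
                {
                    "dose_mGy": dose,
                    "time_h": np.tile(ntc.times, 2),
                    "channel": ["gammaH2AX"] * len(ntc.times) + ["Rad51"] * len(ntc.times),
                    "normalized": np.concatenate([ntc.gamma_h2ax, ntc.rad51]),
                }
            )
        )
        rows.append(
            {
                "dose_mGy": dose,
                "gh2ax_peak_h": peak_time(tc, "gammaH2AX"),
                "rad51_peak_h": peak_time(tc, "rad51"),
                "gh2ax_peak_foci": float(tc.gamma_h2ax.max()),
                "rad51_peak_foci": float(tc.rad51.max()),
                "gh2ax_residual_24h_over_bg": residual_fraction(
                    tc, 24.0, params.readout["gamma_h2ax_background"]
                ),
            }
        )
    pd.concat(frames).to_csv(RESULTS / "timecourses.csv", index=False)
    pd.concat(norm_frames).to_csv(RESULTS / "timecourses_normalized.csv", index=False)
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "timecourse_summary.csv", index=False)

    print("Foci time-course summary (baseline parameters):")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(
        "\ngamma-H2AX peaks within the first hour after moderate doses and"
        " within two hours after low doses; Rad51 peaks hours later,"
        " reflecting the slow HR kinetics. The 24-h gamma-H2AX level stays"
        " above background at low doses (unresolved and irreparable breaks)."
    )


if __name__ == "__main__":
    main()
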