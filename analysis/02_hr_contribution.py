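"""Dose dependence of the homologous-recombination contribution P_HR(D).

Scans P_HR = 100 * mean24h(Rad51) / mean24h(gamma-H2AX) over 20-1000 mGy
(10 mGy desk-scale step; pass --full for the 0.1 mGy scan, ~10,001 runs),
fits the near-exponential decay, and writes the curve and fit parameters.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from dsbrepair import default_parameters, phr_dose_scan

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--step-mgy", type=float, default=10.0)
    ap.add_argument("--full", action="store_true",
                    help="0.1 mGy resolution (long-running mode)")
    args = ap.parse_args()
    step = 0.1 if args.full else args.step_mgy

    RESULTS.mkdir(exist_ok=True)
    params = default_parameters()
    curve = phr_dose_scan(params, 20.0, 1000.0, step)
    curve.to_frame().to_csv(RESULTS / "phr_curve.csv", index=False)
    with open(RESULTS / "phr_decay_fit.json", "w") as fh:
        json.dump(curve.decay, fh, indent=2, sort_keys=True)

    dec = curve.decay
    span = curve.phr_percent.max() - curve.phr_percent.min()
    print(f"P_HR scanned over [20, 1000] mGy at {step} mGy steps"
          f" ({len(curve.dose_mgy)} simulations).")
    print(f"P_HR falls from {curve.phr_percent[0]:.1f}% at 20 mGy to"
          f" {curve.phr_percent[-1]:.1f}% at 1000 mGy"
          f" ({curve.phr_percent[0] / curve.phr_percent[-1]:.1f}-fold),"
          f" strictly decreasing: {bool((np.diff(curve.phr_percent) < 0).all())}.")
    print(f"Near-exponential decay fit: asymptote {dec['asymptote']:.2f}%,"
          f" amplitude {dec['amplitude']:.2f}%,"
          f" rate {dec['rate_per_mgy']:.4g} /mGy;"
          f" RMS residual {dec['rms_residual']:.3f} ="
          f" {100 * dec['rms_residual'] / span:.2f}% of the curve range.")
    print("The declining curve reflects saturation of the resection-limited"
          " HR machinery while total break processing keeps growing with dose.")


if __name__ == "__main__":
    main()
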