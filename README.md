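# dsbrepair

Kinetic modelling of radiation-induced DNA double-strand-break (DSB) repair
in human fibroblasts, and of the dose-dependent shift in the contribution of
homologous recombination (HR) to that repair.

## The problem

After low-LET X-ray exposure, a cell channels each DSB into one of several
competing repair routes: fast, homology-independent **NHEJ**; slow,
error-free **HR** (active in S/G2); **SSA** and its microhomology subclass
**micro-SSA**; and Ku-independent **Alt-EJ**. Experimentally the repair
burden is read out as γ-H2AX foci per cell (one focus ≈ one repair site) and
active HR as Rad51 foci. The scientific question this package addresses
quantitatively: *how does the relative weight of error-free HR change as the
dose rises from 20 to 1000 mGy?*

## The model

A deterministic mass-action network of ~45 molecular species. Breaks are
induced at rate α·dD/dt (α ≈ 35 DSB Gy⁻¹ cell⁻¹, exposure at 40 mGy/min);
a fraction f_ir is permanently irreparable. Each pathway is a chain of
elementary binding/catalysis steps (Ku → DNA-PKcs/Artemis → end bridging →
LigIV-XRCC4-XLF/PNKP/polymerase for NHEJ; MRN-CtIP-ExoI-Dna2 + ATM-driven
resection → RPA → Rad51 filament → D-loop for HR; Rad52/ERCC1-XPF/LigIII for
SSA; PARP1/Pol/LigI for Alt-EJ). H2AX phosphorylation is driven by the
active DNA-PKcs/ATM complexes engaged at break sites,

    V⁺ = K9 · [Sum] · [H2AX] / (K10 + [Sum]),
    V⁻ = K11 · (repair flux) + K12 · [γ-H2AX],

and the HR contribution at dose D is the ratio of 24-h time-averaged foci
counts,

    P_HR(D) = 100 · mean₂₄ₕ(Rad51) / mean₂₄ₕ(γ-H2AX),

scanned over a dose grid and summarized by a near-exponential decay
`P_HR(D) ≈ a + b·exp(−k·D)`.

The package also ships a synthetic-data generator emulating the study
design (7 doses × 8 timepoints × 200 cells × 3 replicates, Poisson per-cell
counts, CENPF-positive S/G2 fractions with binomial noise) and a calibration
module that refits selected rate constants from foci tables.

## Worked example

```python
import dsbrepair as d

params = d.default_parameters()
traj = d.run_protocol(d.ExposureProtocol.from_mgy(1000), params)
tc = d.foci_readout(traj, params)
print(f"gamma-H2AX peak {d.peak_time(tc, 'gammaH2AX'):.2f} h, "
      f"Rad51 peak {d.peak_time(tc, 'rad51'):.2f} h")
print(f"P_HR(1000 mGy) = {d.phr(traj, params):.1f} %")
```

prints

```
gamma-H2AX peak 0.85 h, Rad51 peak 5.25 h
P_HR(1000 mGy) = 6.3 %
```

— after 1000 mGy the γ-H2AX focus count peaks within the first hour
(fast NHEJ engagement) while Rad51 foci peak hours later (slow HR), and HR
accounts for ~6% of the 24-h repair readout at 1 Gy versus ~28% at 20 mGy
(`d.phr_dose_scan(params, 20, 1000, 10)` gives the full declining curve).

The numbered drivers under `analysis/` run the same stages as scripts:
`01_simulate_timecourses.py`, `02_hr_contribution.py`,
`03_generate_synthetic_data.py`, `04_calibrate.py`, writing tables under
`results/`. A `dsbrepair` CLI (`simulate | scan-phr | generate | fit |
recover`) wraps the same library functions with manifest-stamped outputs.

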