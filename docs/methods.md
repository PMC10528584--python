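# Methods

## Model structure

The repair network is a deterministic mass-action ODE system over ~45
species (counts per cell, time in hours, dose in Gy). Breaks are induced at
rate α·dD/dt during exposure (constant dose rate, default 2.4 Gy/h =
40 mGy/min); a fraction `f_ir` enters a permanently irreparable pool that
drives γ-H2AX but no repair pathway, the rest enters the repairable DSB
pool. Four pathways compete for that pool:

* **NHEJ** — Ku binding (K1/Km1), DNA-PKcs/Artemis recruitment (K2/Km2),
  autophosphorylation (K3), bimolecular end bridging of two phosphorylated
  constructs (K4/Km4), sequential LigIV-XRCC4-XLF, PNKP and polymerase
  assembly (K5–K7 with reverses), terminal ligation (K8) releasing all
  enzymes. Because a bridge joins two broken-end constructs, bridge-family
  species carry two DSB-equivalents and two copies each of Ku and DNA-PKcs,
  and the terminal step repairs two DSB-equivalents.
* **HR** — MRN-CtIP-ExoI-Dna2 binding (P1/Pm1), one-way ATM activation
  (P2), activated-ATM joining (P3/Pm3), resection to ssDNA (P4), RPA
  coating (P5/Pm5), Rad51-complex loading (P6/Pm6) and filament maturation
  (P7), synapsis with the incoming duplex (P8/Pm8), D-loop formation (P9),
  then either the double-Holliday-junction route (P10, P11) or direct
  dissolution (P12).
* **SSA** — Rad52 loading on RPA-coated ssDNA (Q1/Qm1), annealing of two
  Rad52-bound ends into a flap (Q2, releasing both RPA), ERCC1-XPF flap
  cutting (Q3/Qm3, Q4, releasing both Rad52), LigIII ligation (Q5/Qm5, Q6).
  The flap chain carries two DSB-equivalents.
* **Alt-EJ** — shares the HR initiation/resection steps, then PARP1
  recruitment (R1/Rm1), polymerase hand-off (R2), microhomology production
  (R3) and LigI ligation (R4/Rm4, R5).

**micro-SSA** is bookkept as a fraction `f_micro` of the terminal SSA
repair flux credited to a separate ledger. A dynamically distinct parallel
chain would be indistinguishable from rescaling the Rad52-loading constant,
so the routing fraction lives at the ledger level; `f_micro` does not alter
the kinetics.

**γ-H2AX kinetics.** Phosphorylation is a saturating drive by the active
DNA-PKcs/ATM complexes engaged at break sites: V⁺ = K9·u·[H2AX]/(K10+u),
where u is the six-term sum of those complexes plus the irreparable pool
(irreparable breaks keep signalling, which is what produces the residual
24-h foci). Decay is V⁻ = K11·(instantaneous total repair flux) +
K12·[γ-H2AX]; coupling K11 to the accumulated repaired stock instead is
available by config switch but makes the sink grow without bound. The K11
term carries a smooth positivity guard γ/(γ+0.01) — dephosphorylation can
only remove foci that exist; the factor is within 1% of unity once γ-H2AX
exceeds one focus and prevents the state from crossing zero when repair
completes faster than phosphorylation (e.g. with phosphorylation disabled).
Dephosphorylated histone returns to the H2AX pool, so total histone is
conserved and testable.

**Readouts.** γ-H2AX foci = the γ-H2AX state (×scale + additive
background); Rad51 foci = Rad51 filament + its synaptic complex (×scale +
background). Backgrounds are additive constants, not modelled
mechanistically. The HR contribution is
P_HR = 100 · mean₂₄ₕ(Rad51)/mean₂₄ₕ(γ-H2AX) with trapezoidal time-averages
on a dense grid (step 0.05 h); a sampled-timepoint mean is available for
comparison with figure-derived estimates. P_HR uses the model readouts
without background (the ratio is defined on model variables), so dose 0 is
skipped in scans by default.

## Parameters

All rate constants, pools, α, `f_ir` and `f_micro` are shipped in
`src/dsbrepair/data/default_params.yaml`, every value marked `fallback`:
they are the package's own calibration, chosen once so the simulated
kinetics show the qualitative behaviour of X-irradiated human fibroblasts —
γ-H2AX peaking at 0.25–1 h after 500–1000 mGy and 0.25–2 h after 20–250 mGy,
Rad51 peaking near 6 h, a 24-h γ-H2AX level above background after tens of
mGy, and a strictly decreasing, near-exponential P_HR(D). Key choices:

* α = 35 Gy⁻¹ cell⁻¹ — the conventional low-LET DSB yield.
* `f_ir` = 0.05, `f_micro` = 0.10.
* Ku binding (K1·[Ku] ≈ 4 h⁻¹) is the rate-limiting NHEJ initiation step,
  slow enough to be visible in the 0.25–1 h rise of the γ-H2AX curve; this
  makes K1 statistically identifiable from sampled time-courses.
* The MRN pool (1 per cell, with resection at 0.5 h⁻¹) is the capacity
  bottleneck of HR: at low doses nearly every MRN encounter converts, while
  at higher doses the occupied pool saturates. This saturation — breaks
  keep growing linearly with dose while HR throughput cannot — is what
  produces the declining P_HR(D); its low-dose slope also keeps the curve
  strictly decreasing from 20 mGy on.
* Solver defaults: LSODA with the analytic Jacobian, rtol 1e-8, atol 1e-10.
  The calibration path uses rtol 1e-6 for speed; the conservation and
  ledger suites run at the strict defaults.

Time origin: t = 0 at the end of exposure (measurement times are
post-irradiation); the exposure phase runs on negative times with repair
active by default, or frozen (`repair_during_exposure=False`) to mimic
irradiation on ice.

## Synthetic data

The generator emulates the study design, not its raw images: doses
{20, 40, 80, 160, 250, 500, 1000} mGy, times {0.25, 0.5, 1, 2, 4, 6, 16,
24} h, 200 cells per point, 3 independent replicates. Per-cell counts are
Poisson around the model's population-mean readout (foci are counts); a
negative-binomial option adds cell-to-cell overdispersion. Cell-to-cell
kinetic heterogeneity is represented only through the noise model — no
per-cell parameter randomization. Summaries take replicate means first,
then mean ± SE across replicates (SE = sd/√n); a single-replicate table
falls back to the within-replicate standard error and is flagged.

The CENPF channel (S/G2-phase marker) is emulated statistically: a pure
exponential decay of the positive fraction (default rate chosen to give a
6.93-fold decrease at 1000 mGy) plus an optional small low-dose bump
peaking at 80 mGy, with binomial counting noise. Because the model admits
no asymptote term, the intermediate-dose fold-decreases (1.6× at 250 mGy,
2.6× at 500 mGy) undershoot a curve that flattens faster; the channel is a
statistical stand-in, not a mechanistic cell-cycle model. Passing tests on
synthetic data therefore demonstrate the pipeline's statistical machinery,
not biological validity of any particular rate constant.

## Calibration

The default objective mirrors the per-dose presentation convention:
model and data curves are normalized to their own 24-h maximum per channel
per dose and compared by weighted least squares. When a curve is divided by
its maximum, its SE is divided by the same maximum before forming the
1/SE² weights; with raw-SE weights the low-dose, noise-dominated curves
dominate the objective. Fitting runs in log-parameter space (positivity for
free), bounded, multistart (start 0 at the geometric mid-point of the
bounds, further starts log-uniform from the seeded generator), and is
deterministic given the seed. The full model (~50 constants, 2 channels)
is not identifiable; the interface requires an explicit free-parameter
subset.

Per-curve max-normalization deliberately discards amplitude information.
That is the right convention for comparing shapes against data of unknown
absolute scale, but it removes most of what identifies the DSB yield α and
the HR initiation constant P1. The parameter-recovery experiment — where
the generating scale and backgrounds are known exactly — therefore fits the
unnormalized counts (weights 1/SE²). At the design scale this recovers
α and P1 within a few percent and K1 within ~20%; under the normalized
objective the same experiment leaves α and P1 essentially unconstrained
(errors of 30–60% across noise realizations), which is a property of the
objective, not of the optimizer.

## Numerical choices and edge cases

* Dose grids for P_HR scans are rounded to 1 µGy during construction so
  grids of different steps agree bitwise at shared doses (each dose is an
  independent simulation, so shared-dose values are then identical).
* The desk-scale scan step is 10 mGy (99 simulations over 20–1000 mGy);
  the 0.1 mGy step of the full-resolution procedure (10,001 simulations)
  is available via `--full` / `--step-mGy 0.1` as a long-running mode.
  The test suites use the desk scale and a 0.1 mGy window of 20–60 mGy.
* Peak times are read off the dense 0.05 h grid; ties break to the
  earliest time.
* `normalize_to_max` requires a positive maximum and is idempotent; the
  recorded constant always maps the normalized series back to the raw one.
* The exponential-decay fit `a + b·exp(−kD)` uses bounded least squares
  (b, k ≥ 0) with tolerances 1e-12 and reports the RMS residual alongside a
  straight-line RMS for comparison.
* Negative abundances beyond −1e-9 (relative to the state scale) at solver
  output points raise an integration-state error rather than being clipped.

## Known limitations

* All parameters are fallback calibrations; absolute foci magnitudes are
  order-of-magnitude realistic but not fitted to any particular cell line.
* ATM activation is one-way and DSB-independent as modelled; only the
  total over free, activated and complex-bound ATM is conserved, and the
  free-ATM pool drains on a fixed timescale regardless of dose.
* The repairable pool is single-compartment: the complex/non-complex break
  split is not kinetically resolved (no separate slow pool beyond the HR
  route itself).
* The observed below-background 24-h γ-H2AX after ≥160 mGy seen in
  measured data is not reproduced: the model's background is an additive
  constant, so simulated residuals approach background from above.
* No spatial, stochastic (per-cell trajectory) or cell-cycle-compartment
  dynamics; dose–response of the S/G2 fraction is emulated only in the
  synthetic CENPF channel.
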