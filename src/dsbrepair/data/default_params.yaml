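# Baseline model parameters for the DSB-repair kinetic model.
#
# Units: abundances in counts per cell, time in hours, dose in Gy.
# Second-order rate constants are per-(count*hour), first-order per hour.
# Reverse constants are written with an "m" infix (Km1 is the reverse of K1).
#
# provenance: every value below is marked "fallback" — chosen by the package
# authors so that the simulated kinetics reproduce the qualitative behaviour
# of X-irradiated human fibroblasts (fast NHEJ completing within ~2 h, slow
# HR with Rad51 foci peaking near 6 h, residual gamma-H2AX at 24 h after tens
# of mGy, and a dose-dependent decline of the HR contribution).

induction:
  alpha: 35.0      # DSB yield slope, Gy^-1 per cell (fallback)
  f_ir: 0.05       # irreparable DSB fraction, dimensionless (fallback)
  f_micro: 0.10    # fraction of SSA-repaired output ledgered as micro-SSA (fallback)

nhej:
  K1: 0.01         # Ku binding to DSB (fallback)
  Km1: 1.0
  K2: 0.1          # DNA-PKcs/Artemis recruitment (fallback)
  Km2: 1.0
  K3: 12.0         # DNA-PKcs autophosphorylation (fallback)
  K4: 200.0        # end bridging of two phosphorylated constructs (fallback)
  Km4: 0.1
  K5: 0.1          # LigIV-XRCC4-XLF recruitment (fallback)
  Km5: 0.5
  K6: 0.1          # PNKP recruitment (fallback)
  Km6: 0.5
  K7: 0.1          # polymerase recruitment (fallback)
  Km7: 0.5
  K8: 8.0          # gap filling + ligation, complex dissolution (fallback)

hr:
  P1: 1.0          # MRN-CtIP-ExoI-Dna2 binding to DSB (fallback)
  Pm1: 0.2
  P2: 2.0          # ATM activation (fallback)
  P3: 0.05         # activated ATM joining the resection complex (fallback)
  Pm3: 0.1
  P4: 0.5          # end resection releasing ssDNA (fallback)
  P5: 0.5          # RPA coating of ssDNA (fallback)
  Pm5: 1.0
  P6: 0.1          # Rad51-Rad51par-BRCA2 loading (fallback)
  Pm6: 0.5
  P7: 0.7          # Rad51 filament maturation, RPA displacement (fallback)
  P8: 0.02         # homology search / synapsis with incoming duplex (fallback)
  Pm8: 0.1
  P9: 1.0          # D-loop formation, Rad51 complex release (fallback)
  P10: 0.5         # D-loop -> double Holliday junction (fallback)
  P11: 1.0         # dHJ resolution to repaired duplex (fallback)
  P12: 0.5         # D-loop dissolution to repaired duplex (fallback)

ssa:
  Q1: 0.02         # Rad52 loading on RPA-coated ssDNA (fallback)
  Qm1: 0.5
  Q2: 1.0          # annealing of two Rad52-bound ends into a flap (fallback)
  Q3: 0.05         # ERCC1-XPF engagement of the flap (fallback)
  Qm3: 0.2
  Q4: 1.0          # flap cutting (fallback)
  Q5: 0.05         # LigIII engagement of the nicked duplex (fallback)
  Qm5: 0.2
  Q6: 2.0          # final ligation (fallback)

altej:
  R1: 0.02         # PARP1 recruitment to ssDNA (fallback)
  Rm1: 0.5
  R2: 0.01         # polymerase hand-off from PARP1 (fallback)
  R3: 1.0          # microhomology production (fallback)
  R4: 0.05         # LigI engagement (fallback)
  Rm4: 0.2
  R5: 2.0          # final ligation (fallback)

gammah2ax:
  K9: 0.6          # phosphorylation capacity (fallback)
  K10: 150.0       # half-saturation of the active-complex drive (fallback)
  K11: 0.01        # dephosphorylation coupling to repair completion (fallback)
  K12: 1.1         # spontaneous focus decay (fallback)
  dephospho_coupling: flux   # 'flux' (d[dsDNA]/dt) or 'stock' ([dsDNA])

pools:             # initial free-enzyme / histone abundances, counts per cell
  Ku: 400.0                      # (fallback)
  DNA-PKcs: 400.0                # (fallback)
  LigIV-XRCC4-XLF: 100.0         # (fallback)
  PNKP: 100.0                    # (fallback)
  Pol: 100.0                     # (fallback)
  MRN-CtIP-ExoI-Dna2: 1.0        # (fallback)
  ATM: 100.0                     # (fallback)
  RPA: 200.0                     # (fallback)
  Rad51-Rad51par-BRCA2: 8.0      # (fallback)
  DNA_inc: 50.0                  # (fallback)
  Rad52: 10.0                    # (fallback)
  ERCC1-XPF: 50.0                # (fallback)
  LigIII: 50.0                   # (fallback)
  PARP1: 50.0                    # (fallback)
  LigI: 50.0                     # (fallback)
  H2AX: 200.0                    # (fallback)

readout:
  gamma_h2ax_scale: 1.0          # foci per gamma-H2AX state unit
  rad51_scale: 1.0               # foci per Rad51-marker state unit
  gamma_h2ax_background: 0.5     # unirradiated foci per cell (fallback)
  rad51_background: 0.3          # unirradiated foci per cell (fallback)

solver:
  method: LSODA
  rtol: 1.0e-8
  atol: 1.0e-10
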