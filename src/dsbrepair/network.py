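"""Reaction network of the DSB repair pathways.

The network covers four competing repair routes for a radiation-induced
double-strand break:

* **NHEJ** — Ku binding, DNA-PKcs/Artemis recruitment and autophosphorylation,
  bridging of two broken-end constructs, LigIV-XRCC4-XLF / PNKP / polymerase
  assembly and final ligation;
* **HR** — MRN-CtIP-ExoI-Dna2 resection assisted by activated ATM, RPA
  coating, Rad51 filament formation, synapsis with the incoming duplex,
  D-loop formation and two resolution routes (via a double Holliday junction
  or direct dissolution);
* **SSA** — Rad52 loading on resected ends, annealing into a flapped
  structure, ERCC1-XPF flap cutting and LigIII ligation (with a micro-SSA
  fraction ledgered separately at the terminal step);
* **Alt-EJ** — shares the HR initiation (resection) steps, then PARP1
  recruitment, polymerase-generated microhomology and LigI ligation.

Each reaction is elementary mass action.  H2AX phosphorylation/decay and the
dose-dependent DSB induction term are *not* mass-action reactions; they are
applied by :mod:`dsbrepair.model` on top of this network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import registry as R
from .parameters import ConfigurationError, ModelParameters
from .registry import SpeciesRegistry, default_registry

RATE_LAWS = ("mass_action", "saturating", "custom")


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction (reversible if ``reverse_constant`` is set)."""

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    forward_constant: str
    reverse_constant: str | None = None
    rate_law: str = "mass_action"

    def __post_init__(self) -> None:
        if self.rate_law not in RATE_LAWS:
            raise ValueError(f"unknown rate law {self.rate_law!r}")
        for side in (self.reactants, self.products):
            for sp, coef in side.items():
                if not (isinstance(coef, int) and coef > 0):
                    raise ValueError(
                        f"stoichiometric coefficient for {sp!r} in {self.name!r}"
                        " must be a positive integer"
                    )

    @property
    def reversible(self) -> bool:
        return self.reverse_constant is not None


class SchemaError(ValueError):
    """A reaction references an unregistered species."""


class ReactionNetwork:
    """Species registry plus an ordered list of reactions."""

    def __init__(self, species: SpeciesRegistry, reactions: list[Reaction]):
        self.species = species
        self.reactions = list(reactions)
        for rxn in self.reactions:
            for sp in list(rxn.reactants) + list(rxn.products):
                if sp not in species:
                    raise SchemaError(
                        f"reaction {rxn.name!r} references unregistered species {sp!r}"
                    )

    def __len__(self) -> int:
        return len(self.reactions)

    def require_constants(self, params: ModelParameters) -> None:
        for rxn in self.reactions:
            names = [rxn.forward_constant]
            if rxn.reverse_constant:
                names.append(rxn.reverse_constant)
            for name in names:
                if not params.has_rate(name):
                    raise ConfigurationError(
                        f"missing rate constant {name!r} required by reaction"
                        f" {rxn.name!r}"
                    )

    def export_text(self) -> str:
        """Human-auditable listing, one reaction per line."""
        lines = []
        for rxn in self.reactions:
            lhs = " + ".join(
                (f"{c} " if c > 1 else "") + s for s, c in rxn.reactants.items()
            )
            rhs = " + ".join(
                (f"{c} " if c > 1 else "") + s for s, c in rxn.products.items()
            )
            arrow = "<->" if rxn.reversible else "->"
            rates = f"kf={rxn.forward_constant}"
            if rxn.reversible:
                rates += f" kr={rxn.reverse_constant}"
            lines.append(f"{lhs} {arrow} {rhs} ; {rates}")
        return "\n".join(lines) + "\n"


def build_network(params: ModelParameters | None = None) -> ReactionNetwork:
    """Construct the full repair network.

    Every printed reaction arrow is one entry: reversible binding steps carry
    both a forward and a reverse constant; catalytic/terminal steps are
    irreversible.  Terminal steps release their enzymes with conserving
    stoichiometry (the bridged NHEJ complex returns 2 Ku and 2 DNA-PKcs; the
    SSA flap chain returns 2 RPA on annealing and 2 Rad52 on flap cutting).

    Raises :class:`ConfigurationError` if ``params`` is given and lacks a
    required constant.
    """
    reg = default_registry()
    rxns = [
        # --- NHEJ ------------------------------------------------------
        Reaction("nhej_ku_binding", {R.DSB: 1, R.KU: 1}, {R.DSB_KU: 1}, "K1", "Km1"),
        Reaction(
            "nhej_dnapk_recruitment",
            {R.DSB_KU: 1, R.DNAPKCS: 1},
            {R.DSB_DNAPK_ART: 1},
            "K2",
            "Km2",
        ),
        Reaction(
            "nhej_autophosphorylation",
            {R.DSB_DNAPK_ART: 1},
            {R.DSB_DNAPK_ARTP: 1},
            "K3",
        ),
        Reaction(
            "nhej_end_bridging", {R.DSB_DNAPK_ARTP: 2}, {R.BRIDGE: 1}, "K4", "Km4"
        ),
        Reaction(
            "nhej_ligiv_recruitment",
            {R.BRIDGE: 1, R.LIGIV: 1},
            {R.BRIDGE_LIGIV: 1},
            "K5",
            "Km5",
        ),
        Reaction(
            "nhej_pnkp_recruitment",
            {R.BRIDGE_LIGIV: 1, R.PNKP: 1},
            {R.BRIDGE_LIGIV_PNKP: 1},
            "K6",
            "Km6",
        ),
        Reaction(
            "nhej_pol_recruitment",
            {R.BRIDGE_LIGIV_PNKP: 1, R.POL: 1},
            {R.BRIDGE_LIGIV_PNKP_POL: 1},
            "K7",
            "Km7",
        ),
        Reaction(
            "nhej_ligation",
            {R.BRIDGE_LIGIV_PNKP_POL: 1},
            {
                R.DSDNA: 2,
                R.LIGIV: 1,
                R.POL: 1,
                R.PNKP: 1,
                R.DNAPKCS: 2,
                R.KU: 2,
            },
            "K8",
        ),
        # --- HR (initiation shared with Alt-EJ) ------------------------
        Reaction(
            "hr_mrn_binding", {R.DSB: 1, R.MRN: 1}, {R.DSB_MRN: 1}, "P1", "Pm1"
        ),
        Reaction("hr_atm_activation", {R.ATM: 1}, {R.ATMP: 1}, "P2"),
        Reaction(
            "hr_atm_joining",
            {R.DSB_MRN: 1, R.ATMP: 1},
            {R.DSB_MRN_ATMP: 1},
            "P3",
            "Pm3",
        ),
        Reaction(
            "hr_resection",
            {R.DSB_MRN_ATMP: 1},
            {R.SSDNA: 1, R.MRN: 1, R.ATMP: 1},
            "P4",
        ),
        Reaction(
            "hr_rpa_coating", {R.SSDNA: 1, R.RPA: 1}, {R.SSDNA_RPA: 1}, "P5", "Pm5"
        ),
        Reaction(
            "hr_rad51_loading",
            {R.SSDNA_RPA: 1, R.RAD51C: 1},
            {R.SSDNA_RPA_RAD51C: 1},
            "P6",
            "Pm6",
        ),
        Reaction(
            "hr_filament_maturation",
            {R.SSDNA_RPA_RAD51C: 1},
            {R.RAD51_FIL: 1, R.RPA: 1},
            "P7",
        ),
        Reaction(
            "hr_synapsis",
            {R.RAD51_FIL: 1, R.DNA_INC: 1},
            {R.RAD51_FIL_DNAINC: 1},
            "P8",
            "Pm8",
        ),
        Reaction(
            "hr_dloop_formation",
            {R.RAD51_FIL_DNAINC: 1},
            {R.DLOOP: 1, R.RAD51C: 1},
            "P9",
        ),
        Reaction("hr_dhj_formation", {R.DLOOP: 1}, {R.DHJ: 1}, "P10"),
        Reaction(
            "hr_dhj_resolution", {R.DHJ: 1}, {R.DSDNA: 1, R.DNA_INC: 1}, "P11"
        ),
        Reaction(
            "hr_dloop_dissolution", {R.DLOOP: 1}, {R.DSDNA: 1, R.DNA_INC: 1}, "P12"
        ),
        # --- SSA --------------------------------------------------------
        Reaction(
            "ssa_rad52_loading",
            {R.SSDNA_RPA: 1, R.RAD52: 1},
            {R.SSDNA_RPA_RAD52: 1},
            "Q1",
            "Qm1",
        ),
        Reaction(
            "ssa_annealing", {R.SSDNA_RPA_RAD52: 2}, {R.FLAP: 1, R.RPA: 2}, "Q2"
        ),
        Reaction(
            "ssa_flap_engagement",
            {R.FLAP: 1, R.ERCC1_XPF: 1},
            {R.FLAP_ERCC1: 1},
            "Q3",
            "Qm3",
        ),
        Reaction(
            "ssa_flap_cutting",
            {R.FLAP_ERCC1: 1},
            {R.DSDNA_NICKS: 1, R.RAD52: 2, R.ERCC1_XPF: 1},
            "Q4",
        ),
        Reaction(
            "ssa_ligiii_engagement",
            {R.DSDNA_NICKS: 1, R.LIGIII: 1},
            {R.DSDNA_NICKS_LIGIII: 1},
            "Q5",
            "Qm5",
        ),
        Reaction(
            "ssa_ligation",
            {R.DSDNA_NICKS_LIGIII: 1},
            {R.DSDNA: 2, R.LIGIII: 1},
            "Q6",
        ),
        # --- Alt-EJ -----------------------------------------------------
        Reaction(
            "altej_parp1_recruitment",
            {R.SSDNA: 1, R.PARP1: 1},
            {R.SSDNA_PARP1: 1},
            "R1",
            "Rm1",
        ),
        Reaction(
            "altej_pol_handoff",
            {R.SSDNA_PARP1: 1, R.POL: 1},
            {R.SSDNA_POL: 1, R.PARP1: 1},
            "R2",
        ),
        Reaction(
            "altej_microhomology",
            {R.SSDNA_POL: 1},
            {R.MICROHOMOL: 1, R.POL: 1},
            "R3",
        ),
        Reaction(
            "altej_ligi_engagement",
            {R.MICROHOMOL: 1, R.LIGI: 1},
            {R.MICROHOMOL_LIGI: 1},
            "R4",
            "Rm4",
        ),
        Reaction(
            "altej_ligation",
            {R.MICROHOMOL_LIGI: 1},
            {R.DSDNA: 1, R.LIGI: 1},
            "R5",
        ),
    ]
    net = ReactionNetwork(reg, rxns)
    if params is not None:
        params.validate()
        net.require_constants(params)
    return net


#: Reactions whose terminal flux repairs DSBs, with the pathway credited and
#: the number of DSB-equivalents repaired per reaction event.
TERMINAL_REPAIR = {
    "nhej_ligation": ("nhej", 2),
    "hr_dhj_resolution": ("hr", 1),
    "hr_dloop_dissolution": ("hr", 1),
    "ssa_ligation": ("ssa", 2),
    "altej_ligation": ("altej", 1),
}


def stoichiometry_matrix(network: ReactionNetwork) -> np.ndarray:
    """Net stoichiometry, species x reactions (one signed column per entry)."""
    n_sp, n_rx = len(network.species), len(network.reactions)
    S = np.zeros((n_sp, n_rx))
    for j, rxn in enumerate(network.reactions):
        for sp, coef in rxn.reactants.items():
            S[network.species.index(sp), j] -= coef
        for sp, coef in rxn.products.items():
            S[network.species.index(sp), j] += coef
    return S


# Conserved units and their member species with multiplicities.  A bridged
# NHEJ complex contains two Ku and two DNA-PKcs (it joins two broken-end
# constructs); the SSA flap chain retains two Rad52.  ATM is conserved only
# as the total over its free, activated and complex-bound forms (activation
# is one-way).  The histone total is closed by the model's convention that
# dephosphorylation returns gamma-H2AX to the H2AX pool.
_BRIDGE_FAMILY = (R.BRIDGE, R.BRIDGE_LIGIV, R.BRIDGE_LIGIV_PNKP, R.BRIDGE_LIGIV_PNKP_POL)

MOIETY_MEMBERS: dict[str, dict[str, int]] = {
    "Ku": {R.KU: 1, R.DSB_KU: 1, R.DSB_DNAPK_ART: 1, R.DSB_DNAPK_ARTP: 1,
           **{sp: 2 for sp in _BRIDGE_FAMILY}},
    "DNA-PKcs": {R.DNAPKCS: 1, R.DSB_DNAPK_ART: 1, R.DSB_DNAPK_ARTP: 1,
                 **{sp: 2 for sp in _BRIDGE_FAMILY}},
    "LigIV-XRCC4-XLF": {R.LIGIV: 1, R.BRIDGE_LIGIV: 1, R.BRIDGE_LIGIV_PNKP: 1,
                        R.BRIDGE_LIGIV_PNKP_POL: 1},
    "PNKP": {R.PNKP: 1, R.BRIDGE_LIGIV_PNKP: 1, R.BRIDGE_LIGIV_PNKP_POL: 1},
    "Pol": {R.POL: 1, R.BRIDGE_LIGIV_PNKP_POL: 1, R.SSDNA_POL: 1},
    "MRN-CtIP-ExoI-Dna2": {R.MRN: 1, R.DSB_MRN: 1, R.DSB_MRN_ATMP: 1},
    "ATM(total)": {R.ATM: 1, R.ATMP: 1, R.DSB_MRN_ATMP: 1},
    "RPA": {R.RPA: 1, R.SSDNA_RPA: 1, R.SSDNA_RPA_RAD51C: 1, R.SSDNA_RPA_RAD52: 1},
    "Rad51-Rad51par-BRCA2": {R.RAD51C: 1, R.SSDNA_RPA_RAD51C: 1, R.RAD51_FIL: 1,
                             R.RAD51_FIL_DNAINC: 1},
    "DNA_inc": {R.DNA_INC: 1, R.RAD51_FIL_DNAINC: 1, R.DLOOP: 1, R.DHJ: 1},
    "Rad52": {R.RAD52: 1, R.SSDNA_RPA_RAD52: 1, R.FLAP: 2, R.FLAP_ERCC1: 2},
    "ERCC1-XPF": {R.ERCC1_XPF: 1, R.FLAP_ERCC1: 1},
    "LigIII": {R.LIGIII: 1, R.DSDNA_NICKS_LIGIII: 1},
    "PARP1": {R.PARP1: 1, R.SSDNA_PARP1: 1},
    "LigI": {R.LIGI: 1, R.MICROHOMOL_LIGI: 1},
    "histone": {R.H2AX: 1, R.GH2AX: 1},
}


def conserved_moieties(network: ReactionNetwork) -> dict[str, np.ndarray]:
    """Named non-negative integer moiety vectors, each in the left null space.

    Every returned vector ``v`` satisfies ``v @ S == 0`` for the mass-action
    stoichiometric matrix; the histone vector additionally relies on the
    phosphorylation/dephosphorylation terms exchanging H2AX and gamma-H2AX
    one-for-one.  A vector failing the null-space check raises
    :class:`SchemaError` (it would indicate an inconsistent network).
    """
    S = stoichiometry_matrix(network)
    out: dict[str, np.ndarray] = {}
    for name, members in MOIETY_MEMBERS.items():
        v = np.zeros(len(network.species))
        for sp, w in members.items():
            v[network.species.index(sp)] = w
        resid = np.abs(v @ S).max()
        if resid > 1e-12:
            raise SchemaError(f"moiety {name!r} is not conserved (|vS|={resid:g})")
        out[name] = v
    return out
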