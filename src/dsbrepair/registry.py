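"""Molecular species of the double-strand-break repair network.

Every species tracked by the kinetic model is registered here with three
pieces of bookkeeping that the rest of the package relies on:

* a ``role`` tag (substrate / free enzyme / intermediate / product / histone),
* its ``dsb_content`` — how many DSB-equivalents the species carries (a
  bridged NHEJ complex joins two broken ends and therefore carries 2),
* a ``rad51_marker`` flag marking the species whose abundance is scored as a
  Rad51 focus (the Rad51 nucleoprotein filament and its synaptic complex).

The registry fixes the state-vector ordering used by the integrator, the
stoichiometric matrix and the conserved-moiety analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ROLES = ("substrate", "free_enzyme", "intermediate", "product", "histone")


@dataclass(frozen=True)
class Species:
    """One molecular species (counts per cell, dimensionless)."""

    name: str
    role: str
    dsb_content: int = 0
    rad51_marker: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for species {self.name!r}")
        if self.dsb_content < 0:
            raise ValueError(f"dsb_content must be >= 0 for species {self.name!r}")


class SpeciesRegistry:
    """Ordered, unique collection of :class:`Species`.

    Provides name→index lookup for building state vectors and stoichiometric
    matrices.
    """

    def __init__(self, species: list[Species] | None = None):
        self._species: list[Species] = []
        self._index: dict[str, int] = {}
        for sp in species or []:
            self.add(sp)

    def add(self, sp: Species) -> None:
        if sp.name in self._index:
            raise ValueError(f"duplicate species identifier {sp.name!r}")
        self._index[sp.name] = len(self._species)
        self._species.append(sp)

    def __len__(self) -> int:
        return len(self._species)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self):
        return iter(self._species)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"species {name!r} is not registered") from None

    def get(self, name: str) -> Species:
        return self._species[self.index(name)]

    @property
    def names(self) -> list[str]:
        return [sp.name for sp in self._species]

    def dsb_content_vector(self):
        import numpy as np

        return np.array([sp.dsb_content for sp in self._species], dtype=float)

    def rad51_marker_indices(self) -> list[int]:
        return [i for i, sp in enumerate(self._species) if sp.rad51_marker]


# Canonical species names used throughout the package.  Complexes are written
# with "." as the association separator (e.g. "DSB.Ku").
DSB = "DSB"
KU = "Ku"
DSB_KU = "DSB.Ku"
DNAPKCS = "DNA-PKcs"
DSB_DNAPK_ART = "DSB.DNA-PK_Art"
DSB_DNAPK_ARTP = "DSB.DNA-PK_Art^P"
BRIDGE = "Bridge"
LIGIV = "LigIV-XRCC4-XLF"
BRIDGE_LIGIV = "Bridge.LigIV-XRCC4-XLF"
PNKP = "PNKP"
BRIDGE_LIGIV_PNKP = "Bridge.LigIV-XRCC4-XLF.PNKP"
POL = "Pol"
BRIDGE_LIGIV_PNKP_POL = "Bridge.LigIV-XRCC4-XLF.PNKP.Pol"
DSDNA = "dsDNA"
MRN = "MRN-CtIP-ExoI-Dna2"
ATM = "ATM"
ATMP = "ATM^P"
DSB_MRN = "DSB.MRN-CtIP-ExoI-Dna2"
DSB_MRN_ATMP = "DSB.MRN-CtIP-ExoI-Dna2.ATM^P"
SSDNA = "ssDNA"
RPA = "RPA"
SSDNA_RPA = "ssDNA.RPA"
RAD51C = "Rad51-Rad51par-BRCA2"
SSDNA_RPA_RAD51C = "ssDNA.RPA.Rad51-Rad51par-BRCA2"
RAD51_FIL = "Rad51 filament"
DNA_INC = "DNA_inc"
RAD51_FIL_DNAINC = "Rad51 filament.DNA_inc"
DLOOP = "D-loop"
DHJ = "dHJ"
RAD52 = "Rad52"
SSDNA_RPA_RAD52 = "ssDNA.RPA.Rad52"
FLAP = "Flap"
ERCC1_XPF = "ERCC1-XPF"
FLAP_ERCC1 = "Flap.ERCC1-XPF"
DSDNA_NICKS = "dsDNA_nicks"
LIGIII = "LigIII"
DSDNA_NICKS_LIGIII = "dsDNA_nicks.LigIII"
PARP1 = "PARP1"
SSDNA_PARP1 = "ssDNA.PARP1"
SSDNA_POL = "ssDNA.Pol"
MICROHOMOL = "MicroHomol"
LIGI = "LigI"
MICROHOMOL_LIGI = "MicroHomol.LigI"
H2AX = "H2AX"
GH2AX = "gamma-H2AX"
N_IR = "N_ir"

#: The six intermediates whose sum drives H2AX phosphorylation (active forms
#: of DNA-PKcs and ATM engaged at break sites).
SUM_ACTIVE_SPECIES = (
    DSB_DNAPK_ARTP,
    BRIDGE,
    BRIDGE_LIGIV,
    BRIDGE_LIGIV_PNKP,
    BRIDGE_LIGIV_PNKP_POL,
    DSB_MRN_ATMP,
)


def default_registry() -> SpeciesRegistry:
    """Registry of the full repair network (NHEJ, HR, SSA, Alt-EJ, histone).

    Bridge-derived species join two broken ends and carry 2 DSB-equivalents;
    the SSA flap chain anneals two resected ends and likewise carries 2.
    ``dsDNA`` is the repaired-DNA ledger (its production stoichiometry counts
    repaired DSB-equivalents), so it carries 0 in-process equivalents.
    """
    reg = SpeciesRegistry()
    add = reg.add
    # NHEJ
    add(Species(DSB, "substrate", dsb_content=1))
    add(Species(KU, "free_enzyme"))
    add(Species(DSB_KU, "intermediate", dsb_content=1))
    add(Species(DNAPKCS, "free_enzyme"))
    add(Species(DSB_DNAPK_ART, "intermediate", dsb_content=1))
    add(Species(DSB_DNAPK_ARTP, "intermediate", dsb_content=1))
    add(Species(BRIDGE, "intermediate", dsb_content=2))
    add(Species(LIGIV, "free_enzyme"))
    add(Species(BRIDGE_LIGIV, "intermediate", dsb_content=2))
    add(Species(PNKP, "free_enzyme"))
    add(Species(BRIDGE_LIGIV_PNKP, "intermediate", dsb_content=2))
    add(Species(POL, "free_enzyme"))
    add(Species(BRIDGE_LIGIV_PNKP_POL, "intermediate", dsb_content=2))
    add(Species(DSDNA, "product"))
    # HR
    add(Species(MRN, "free_enzyme"))
    add(Species(ATM, "free_enzyme"))
    add(Species(ATMP, "free_enzyme"))
    add(Species(DSB_MRN, "intermediate", dsb_content=1))
    add(Species(DSB_MRN_ATMP, "intermediate", dsb_content=1))
    add(Species(SSDNA, "intermediate", dsb_content=1))
    add(Species(RPA, "free_enzyme"))
    add(Species(SSDNA_RPA, "intermediate", dsb_content=1))
    add(Species(RAD51C, "free_enzyme"))
    add(Species(SSDNA_RPA_RAD51C, "intermediate", dsb_content=1))
    add(Species(RAD51_FIL, "intermediate", dsb_content=1, rad51_marker=True))
    add(Species(DNA_INC, "free_enzyme"))
    add(Species(RAD51_FIL_DNAINC, "intermediate", dsb_content=1, rad51_marker=True))
    add(Species(DLOOP, "intermediate", dsb_content=1))
    add(Species(DHJ, "intermediate", dsb_content=1))
    # SSA
    add(Species(RAD52, "free_enzyme"))
    add(Species(SSDNA_RPA_RAD52, "intermediate", dsb_content=1))
    add(Species(FLAP, "intermediate", dsb_content=2))
    add(Species(ERCC1_XPF, "free_enzyme"))
    add(Species(FLAP_ERCC1, "intermediate", dsb_content=2))
    add(Species(DSDNA_NICKS, "intermediate", dsb_content=2))
    add(Species(LIGIII, "free_enzyme"))
    add(Species(DSDNA_NICKS_LIGIII, "intermediate", dsb_content=2))
    # Alt-EJ
    add(Species(PARP1, "free_enzyme"))
    add(Species(SSDNA_PARP1, "intermediate", dsb_content=1))
    add(Species(SSDNA_POL, "intermediate", dsb_content=1))
    add(Species(MICROHOMOL, "intermediate", dsb_content=1))
    add(Species(LIGI, "free_enzyme"))
    add(Species(MICROHOMOL_LIGI, "intermediate", dsb_content=1))
    # Histone readout
    add(Species(H2AX, "histone"))
    add(Species(GH2AX, "histone"))
    # Irreparable break pool: drives gamma-H2AX but enters no repair pathway.
    add(Species(N_IR, "substrate", dsb_content=1))
    return reg
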