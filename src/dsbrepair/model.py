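"""Right-hand side of the repair ODE system.

The state vector is the species block (in registry order) followed by a
cumulative ledger block::

    [species..., induced, repaired_nhej, repaired_hr, repaired_ssa,
     repaired_micro_ssa, repaired_altej]

Mass-action fluxes come from the compiled reaction network.  On top of them
the model applies three non-mass-action terms:

* **DSB induction** — breaks appear at a rate ``alpha * dose_rate``; a
  fraction ``1 - f_ir`` enters the repairable DSB pool, the remainder a
  permanently irreparable pool (``N_ir``) that drives gamma-H2AX but enters
  no repair pathway.
* **H2AX phosphorylation** — a saturating drive by the active DNA-PKcs/ATM
  complexes engaged at break sites (plus the irreparable pool),
  ``V+ = K9 * u * [H2AX] / (K10 + u)`` with ``u = [Sum] + N_ir``.
* **gamma-H2AX decay** — ``V- = K11 * (repair completion) + K12 * [gH2AX]``,
  where the K11 term couples by default to the instantaneous repair flux
  ``d[dsDNA]/dt`` (a config switch selects the accumulated-stock coupling
  instead).  The K11 term carries a smooth positivity guard
  ``g/(g + eps)`` (eps = 0.01 foci) so dephosphorylation can only remove
  foci that exist; without it the state goes negative whenever repair
  completes faster than phosphorylation.  Dephosphorylated histone returns
  to the H2AX pool, so the histone total is conserved.

The micro-SSA route is ledgered as a fraction ``f_micro`` of the terminal
SSA repair flux; its dynamics ride on the SSA chain.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import registry as R
from .network import ReactionNetwork, build_network, stoichiometry_matrix
from .parameters import ModelParameters
from .registry import SUM_ACTIVE_SPECIES

LEDGER_FIELDS = (
    "induced",
    "repaired_nhej",
    "repaired_hr",
    "repaired_ssa",
    "repaired_micro_ssa",
    "repaired_altej",
)


class IntegrationStateError(RuntimeError):
    """A state violated the non-negativity tolerance during integration."""


#: Softness scale (foci) of the positivity guard on flux-coupled
#: dephosphorylation; negligible once gamma-H2AX exceeds ~0.1 foci.
DEPHOSPHO_GUARD_EPS = 0.01


class MassActionKinetics:
    """Compiled mass-action rate evaluator for an arbitrary network.

    Handles elementary reactions with at most two reactant factors (a
    stoichiometry-2 reactant counts as the same factor twice) and reversible
    steps with a single product complex — the forms that occur in this model.
    """

    def __init__(self, network: ReactionNetwork, rate_of: Callable[[str], float]):
        self.network = network
        n_rx = len(network.reactions)
        n_sp = len(network.species)
        self.n_species = n_sp
        self.S = stoichiometry_matrix(network)
        self.kf = np.zeros(n_rx)
        self.kr = np.zeros(n_rx)
        # factor slots; sentinel n_sp points at a constant 1.0
        self._f1 = np.full(n_rx, n_sp, dtype=int)
        self._f2 = np.full(n_rx, n_sp, dtype=int)
        self._r1 = np.full(n_rx, n_sp, dtype=int)
        self._r2 = np.full(n_rx, n_sp, dtype=int)
        for j, rxn in enumerate(network.reactions):
            self.kf[j] = rate_of(rxn.forward_constant)
            if rxn.reverse_constant is not None:
                self.kr[j] = rate_of(rxn.reverse_constant)
            self._assign_slots(j, rxn.reactants, self._f1, self._f2, network)
            if rxn.reverse_constant is not None:
                self._assign_slots(j, rxn.products, self._r1, self._r2, network)

    @staticmethod
    def _assign_slots(j, side, slot1, slot2, network):
        factors: list[int] = []
        for sp, coef in side.items():
            factors.extend([network.species.index(sp)] * coef)
        if len(factors) > 2:
            raise ValueError("more than two reactant factors are not supported")
        if factors:
            slot1[j] = factors[0]
        if len(factors) > 1:
            slot2[j] = factors[1]

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Net reaction rates (forward minus reverse) at state ``x``."""
        xe = np.append(x, 1.0)
        v = self.kf * xe[self._f1] * xe[self._f2]
        rev = self.kr != 0
        if rev.any():
            v = v - self.kr * xe[self._r1] * xe[self._r2]
        return v

    def rates_jacobian(self, x: np.ndarray) -> np.ndarray:
        """d(rates)/d(species), shape (n_reactions, n_species)."""
        n_rx = len(self.kf)
        xe = np.append(x, 1.0)
        J = np.zeros((n_rx, self.n_species + 1))
        rows = np.arange(n_rx)
        np.add.at(J, (rows, self._f1), self.kf * xe[self._f2])
        np.add.at(J, (rows, self._f2), self.kf * xe[self._f1])
        np.add.at(J, (rows, self._r1), -self.kr * xe[self._r2])
        np.add.at(J, (rows, self._r2), -self.kr * xe[self._r1])
        return J[:, : self.n_species]

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(x)

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.S @ self.rates_jacobian(x)


class RepairModel:
    """Full kinetic model: network fluxes + induction + H2AX kinetics."""

    def __init__(self, params: ModelParameters, network: ReactionNetwork | None = None):
        params.validate()
        self.params = params
        self.network = network if network is not None else build_network(params)
        self.network.require_constants(params)
        self.kinetics = MassActionKinetics(self.network, params.rate)
        reg = self.network.species
        self.n_species = len(reg)
        self.n_state = self.n_species + len(LEDGER_FIELDS)
        self.species_names = reg.names
        self.state_names = reg.names + list(LEDGER_FIELDS)

        self.i_dsb = reg.index(R.DSB)
        self.i_nir = reg.index(R.N_IR)
        self.i_h2ax = reg.index(R.H2AX)
        self.i_gh2ax = reg.index(R.GH2AX)
        self.i_dsdna = reg.index(R.DSDNA)
        self.sum_idx = np.array([reg.index(s) for s in SUM_ACTIVE_SPECIES])
        self.rad51_idx = np.array(reg.rad51_marker_indices())
        self.dsb_content = reg.dsb_content_vector()
        self.ledger_index = {
            name: self.n_species + k for k, name in enumerate(LEDGER_FIELDS)
        }
        # repaired DSB-equivalents produced per unit reaction flux
        self._repair_row = self.kinetics.S[self.i_dsdna].copy()
        rxnames = [r.name for r in self.network.reactions]
        self._j_nhej = rxnames.index("nhej_ligation")
        self._j_hr = [rxnames.index("hr_dhj_resolution"),
                      rxnames.index("hr_dloop_dissolution")]
        self._j_ssa = rxnames.index("ssa_ligation")
        self._j_altej = rxnames.index("altej_ligation")

        gh = params.gammah2ax
        self.K9 = float(gh["K9"])
        self.K10 = float(gh["K10"])
        self.K11 = float(gh["K11"])
        self.K12 = float(gh["K12"])
        self.couple_flux = params.dephospho_coupling == "flux"

    # -- state construction --------------------------------------------
    def initial_state(self) -> np.ndarray:
        x = np.zeros(self.n_state)
        for sp, value in self.params.pools.items():
            x[self.network.species.index(sp)] = float(value)
        return x

    # -- readout helpers ------------------------------------------------
    def sum_active(self, x: np.ndarray) -> float:
        """Six-term sum of the active DNA-PKcs/ATM complexes (the H2AX drive
        excluding the irreparable pool)."""
        return float(x[..., self.sum_idx].sum(axis=-1))

    def gamma_h2ax(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[..., self.i_gh2ax]

    def rad51(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[..., self.rad51_idx].sum(axis=-1)

    def ledger(self, x: np.ndarray, field: str) -> np.ndarray:
        return np.asarray(x)[..., self.ledger_index[field]]

    def dsb_closure_error(self, x: np.ndarray) -> np.ndarray:
        """Relative DSB ledger error: induced vs in-process + repaired.

        ``induced = sum(dsb_content * species) + sum(pathway repaired)``;
        the irreparable pool carries dsb_content 1 and is counted in the
        species term.  Returns 0 where nothing has been induced.
        """
        x = np.atleast_2d(np.asarray(x))
        induced = x[:, self.ledger_index["induced"]]
        inprocess = x[:, : self.n_species] @ self.dsb_content
        repaired = x[:, self.n_species + 1 :].sum(axis=1)
        err = np.zeros_like(induced)
        nz = induced > 0
        err[nz] = np.abs(inprocess[nz] + repaired[nz] - induced[nz]) / induced[nz]
        return err

    # -- dynamics -------------------------------------------------------
    def _h2ax_terms(self, x: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
        u = x[self.sum_idx].sum() + x[self.i_nir]
        h = x[self.i_h2ax]
        g = x[self.i_gh2ax]
        vplus = self.K9 * u * h / (self.K10 + u)
        repair = self._repair_row @ v if self.couple_flux else x[self.i_dsdna]
        guard = g / (g + DEPHOSPHO_GUARD_EPS) if g > 0 else 0.0
        vminus = self.K11 * repair * guard + self.K12 * g
        return vplus, vminus, u

    def rhs(self, t: float, x: np.ndarray, dose_rate: float | Callable[[float], float]) -> np.ndarray:
        r = dose_rate(t) if callable(dose_rate) else dose_rate
        p = self.params
        xs = x[: self.n_species]
        v = self.kinetics.rates(xs)
        dx = np.zeros(self.n_state)
        dx[: self.n_species] = self.kinetics.S @ v
        # induction split between repairable and irreparable pools
        induction = p.alpha * r
        dx[self.i_dsb] += induction * (1.0 - p.f_ir)
        dx[self.i_nir] += induction * p.f_ir
        # H2AX phosphorylation / decay
        vplus, vminus, _ = self._h2ax_terms(xs, v)
        dx[self.i_gh2ax] += vplus - vminus
        dx[self.i_h2ax] += vminus - vplus
        # ledger
        li = self.ledger_index
        dx[li["induced"]] = induction
        dx[li["repaired_nhej"]] = 2.0 * v[self._j_nhej]
        hr_flux = v[self._j_hr[0]] + v[self._j_hr[1]]
        dx[li["repaired_hr"]] = hr_flux
        ssa_flux = 2.0 * v[self._j_ssa]
        dx[li["repaired_ssa"]] = (1.0 - p.f_micro) * ssa_flux
        dx[li["repaired_micro_ssa"]] = p.f_micro * ssa_flux
        dx[li["repaired_altej"]] = v[self._j_altej]
        return dx

    def jac(self, t: float, x: np.ndarray, dose_rate: float | Callable[[float], float]) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` (induction is state-independent)."""
        p = self.params
        xs = x[: self.n_species]
        Jv = self.kinetics.rates_jacobian(xs)  # (n_rx, n_species)
        J = np.zeros((self.n_state, self.n_state))
        J[: self.n_species, : self.n_species] = self.kinetics.S @ Jv
        # H2AX terms
        u = xs[self.sum_idx].sum() + xs[self.i_nir]
        h = xs[self.i_h2ax]
        g = xs[self.i_gh2ax]
        denom = self.K10 + u
        dvp_du = self.K9 * h * self.K10 / denom**2
        dvp_dh = self.K9 * u / denom
        u_idx = list(self.sum_idx) + [self.i_nir]
        if g > 0:
            guard = g / (g + DEPHOSPHO_GUARD_EPS)
            dguard = DEPHOSPHO_GUARD_EPS / (g + DEPHOSPHO_GUARD_EPS) ** 2
        else:
            guard = dguard = 0.0
        if self.couple_flux:
            v = self.kinetics.rates(xs)
            repair = self._repair_row @ v
            drepair = self._repair_row @ Jv  # row over species
        else:
            repair = xs[self.i_dsdna]
            drepair = np.zeros(self.n_species)
            drepair[self.i_dsdna] = 1.0
        for ig, sgn in ((self.i_gh2ax, 1.0), (self.i_h2ax, -1.0)):
            for iu in u_idx:
                J[ig, iu] += sgn * dvp_du
            J[ig, self.i_h2ax] += sgn * dvp_dh
            # decay terms enter with opposite sign
            J[ig, self.i_gh2ax] += -sgn * (self.K12 + self.K11 * repair * dguard)
            J[ig, : self.n_species] += -sgn * self.K11 * guard * drepair
        # ledger rows
        li = self.ledger_index
        J[li["repaired_nhej"], : self.n_species] = 2.0 * Jv[self._j_nhej]
        J[li["repaired_hr"], : self.n_species] = Jv[self._j_hr[0]] + Jv[self._j_hr[1]]
        ssa_row = 2.0 * Jv[self._j_ssa]
        J[li["repaired_ssa"], : self.n_species] = (1.0 - p.f_micro) * ssa_row
        J[li["repaired_micro_ssa"], : self.n_species] = p.f_micro * ssa_row
        J[li["repaired_altej"], : self.n_species] = Jv[self._j_altej]
        return J


def rhs(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    dose_rate_fn: Callable[[float], float] | float,
    model: RepairModel | None = None,
) -> np.ndarray:
    """Derivative of the full state vector at time ``t`` (hours).

    Convenience wrapper around :class:`RepairModel`; pass ``model`` to avoid
    recompiling the network on every call.
    """
    if model is None:
        model = RepairModel(params)
    state = np.asarray(state, dtype=float)
    if (state[: model.n_species] < -1e-6).any():
        bad = np.argmin(state[: model.n_species])
        raise IntegrationStateError(
            f"negative abundance for {model.species_names[bad]}: {state[bad]:g}"
        )
    return model.rhs(t, state, dose_rate_fn)
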