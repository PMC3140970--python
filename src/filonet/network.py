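"""Mass-action reaction network for the Eps8/IRSp53/VASP/Abi/CP module.

The network couples two sub-modules that compete for shared components:

* a *capping* module — capping protein (CP) and the Eps8:Abi complex bind
  free barbed ends (B) and block elongation;
* a *bundling* module — the mutually exclusive SH3 complexes Eps8:IRSp53
  and VASP:IRSp53 decorate filamentous actin (Fa), forming the
  membrane-anchored "filopodia initiation complexes" Eps8:IRSp53:Fa and
  VASP:IRSp53:Fa.

Actin polymerizes at free barbed ends from a clamped G-actin pool (Ga),
monomers dissociate from barbed ends, and bulk F-actin turns over with a
first-order rate; turnover is the only irreversible reaction.  All binding
steps follow simple mass-action kinetics.  Concentrations are in nM, time
in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .params import CellParameterSet

#: conserved moieties, in the order used by the conservation matrix rows
MOIETIES: tuple[str, ...] = ("Eps8", "Abi", "IRSp53", "VASP", "CP", "B")

#: map moiety -> the free species carrying it
FREE_SPECIES_OF_MOIETY: dict[str, str] = {
    "Eps8": "E",
    "Abi": "A",
    "IRSp53": "I",
    "VASP": "V",
    "CP": "CP",
    "B": "B",
}

ROLES = frozenset({"free-protein", "complex", "actin-pool", "barbed-end-state"})


@dataclass(frozen=True)
class Species:
    """One chemical species: a free protein, complex, actin pool or end state.

    ``composition`` lists the conserved moieties the species carries (used to
    build the conservation matrix); the bulk actin pools Ga and Fa carry none
    because polymerized actin is deliberately non-conserved.
    """

    name: str
    role: str
    composition: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown species role {self.role!r}")

    def moiety_count(self, moiety: str) -> int:
        for m, c in self.composition:
            if m == moiety:
                return c
        return 0


@dataclass(frozen=True)
class Reaction:
    """One reaction of the network.

    ``kind`` selects the rate law:

    * ``binding``        — reversible mass action,
      net flux = k_on * prod(substrates) - k_off * prod(products);
    * ``polymerization`` — Ga -> Fa catalysed by free barbed ends,
      net flux = k_pol * [Ga] * [B] - k_depol * [B]  (monomer dissociation
      from barbed ends is proportional to the ends, not to bulk Fa);
    * ``turnover``       — irreversible Fa -> 0, flux = k_turn * [Fa].
    """

    rid: int
    label: str
    kind: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool

    def __post_init__(self) -> None:
        if self.kind not in ("binding", "polymerization", "turnover"):
            raise ValueError(f"unknown reaction kind {self.kind!r}")


def _canonical_species() -> tuple[Species, ...]:
    S = Species
    return (
        S("E", "free-protein", (("Eps8", 1),)),
        S("A", "free-protein", (("Abi", 1),)),
        S("I", "free-protein", (("IRSp53", 1),)),
        S("V", "free-protein", (("VASP", 1),)),
        S("CP", "free-protein", (("CP", 1),)),
        S("B", "barbed-end-state", (("B", 1),)),
        S("Ga", "actin-pool"),
        S("Fa", "actin-pool"),
        S("EA", "complex", (("Eps8", 1), ("Abi", 1))),
        S("EAB", "barbed-end-state", (("Eps8", 1), ("Abi", 1), ("B", 1))),
        S("CPB", "barbed-end-state", (("CP", 1), ("B", 1))),
        S("EI", "complex", (("Eps8", 1), ("IRSp53", 1))),
        S("EIFa", "complex", (("Eps8", 1), ("IRSp53", 1))),
        S("VI", "complex", (("VASP", 1), ("IRSp53", 1))),
        S("VIFa", "complex", (("VASP", 1), ("IRSp53", 1))),
    )


def _canonical_reactions() -> tuple[Reaction, ...]:
    R = Reaction
    return (
        R(1, "CP capping", "binding", ("CP", "B"), ("CPB",), True),
        R(2, "Eps8:Abi formation", "binding", ("E", "A"), ("EA",), True),
        R(3, "Eps8:Abi capping", "binding", ("EA", "B"), ("EAB",), True),
        R(4, "Eps8:IRSp53 formation", "binding", ("E", "I"), ("EI",), True),
        R(5, "Eps8:IRSp53 on F-actin", "binding", ("EI", "Fa"), ("EIFa",), True),
        R(6, "VASP:IRSp53 formation", "binding", ("V", "I"), ("VI",), True),
        R(7, "VASP:IRSp53 on F-actin", "binding", ("VI", "Fa"), ("VIFa",), True),
        R(8, "polymerization at free ends", "polymerization", ("Ga",), ("Fa",), True),
        R(9, "F-actin turnover", "turnover", ("Fa",), (), False),
    )


class NetworkModel:
    """Species registry, reactions, stoichiometry and conservation structure."""

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        clamped: Iterable[str] = ("Ga",),
    ) -> None:
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        self.clamped: frozenset[str] = frozenset(clamped)
        unknown = self.clamped - set(names)
        if unknown:
            raise ValueError(f"clamped species not in model: {sorted(unknown)}")
        self.stoichiometry = self._build_stoichiometry()
        self.conservation = self._build_conservation()
        self._clamped_idx = np.array(
            sorted(self.index[n] for n in self.clamped), dtype=int
        )

    # -- structure -----------------------------------------------------

    def _build_stoichiometry(self) -> np.ndarray:
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for name in rxn.substrates:
                S[self.index[name], j] -= 1.0
            for name in rxn.products:
                S[self.index[name], j] += 1.0
        return S

    def _build_conservation(self) -> np.ndarray:
        C = np.zeros((len(MOIETIES), len(self.species)))
        for i, moiety in enumerate(MOIETIES):
            for j, sp in enumerate(self.species):
                C[i, j] = sp.moiety_count(moiety)
        return C

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def reaction_count(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def has_species_combining(self, moiety_a: str, moiety_b: str) -> bool:
        """True iff some species carries both moieties (e.g. a triple complex)."""
        return any(
            sp.moiety_count(moiety_a) > 0 and sp.moiety_count(moiety_b) > 0
            for sp in self.species
        )

    def with_clamped(self, extra: Iterable[str]) -> "NetworkModel":
        """Copy of the model with additional species held constant."""
        return NetworkModel(self.species, self.reactions, self.clamped | set(extra))

    # -- state helpers -------------------------------------------------

    def state_vector(self, concentrations: Mapping[str, float]) -> np.ndarray:
        x = np.zeros(self.n_species)
        for name, value in concentrations.items():
            x[self.index[name]] = value
        return x

    def state_dict(self, x: np.ndarray) -> dict[str, float]:
        return {s.name: float(x[i]) for i, s in enumerate(self.species)}

    # -- kinetics ------------------------------------------------------

    def _fluxes_unchecked(self, state: np.ndarray, params: CellParameterSet) -> np.ndarray:
        idx = self.index
        flux = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            if rxn.kind == "binding":
                k_on, k_off = params.kinetics[rxn.rid]
                fwd = k_on
                for name in rxn.substrates:
                    fwd *= state[idx[name]]
                rev = k_off
                for name in rxn.products:
                    rev *= state[idx[name]]
                flux[j] = fwd - rev
            elif rxn.kind == "polymerization":
                k_pol, k_depol = params.kinetics[rxn.rid]
                b_free = state[idx["B"]]
                flux[j] = k_pol * state[idx["Ga"]] * b_free - k_depol * b_free
            else:  # turnover
                flux[j] = params.k_turn * state[idx["Fa"]]
        return flux

    def mass_action_fluxes(
        self, state: np.ndarray, params: CellParameterSet
    ) -> np.ndarray:
        """Net per-reaction fluxes (nM/s) at ``state``.

        Rejects states with negative concentrations (beyond numerical dust).
        """
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise ValueError(
                f"state has shape {state.shape}, expected ({self.n_species},)"
            )
        if np.any(state < -1e-9):
            raise ValueError("negative concentration in state")
        return self._fluxes_unchecked(state, params)

    def ode_rhs(self, state: np.ndarray, params: CellParameterSet) -> np.ndarray:
        """Time derivative dX/dt = S·flux with clamped species forced to zero."""
        flux = self.mass_action_fluxes(state, params)
        rhs = self.stoichiometry @ flux
        rhs[self._clamped_idx] = 0.0
        return rhs

    def _rhs_unchecked(self, state: np.ndarray, params: CellParameterSet) -> np.ndarray:
        # integrator-facing variant: tolerates the tiny negative excursions
        # adaptive steppers probe; rate laws are smooth polynomials anyway
        rhs = self.stoichiometry @ self._fluxes_unchecked(state, params)
        rhs[self._clamped_idx] = 0.0
        return rhs

    def flux_jacobian(self, state: np.ndarray, params: CellParameterSet) -> np.ndarray:
        """d(flux)/d(state), analytically (reactions x species)."""
        idx = self.index
        J = np.zeros((len(self.reactions), self.n_species))
        for j, rxn in enumerate(self.reactions):
            if rxn.kind == "binding":
                k_on, k_off = params.kinetics[rxn.rid]
                subs = [idx[n] for n in rxn.substrates]
                prods = [idx[n] for n in rxn.products]
                for i in subs:
                    others = k_on
                    for i2 in subs:
                        if i2 != i:
                            others *= state[i2]
                    J[j, i] += others
                for i in prods:
                    others = k_off
                    for i2 in prods:
                        if i2 != i:
                            others *= state[i2]
                    J[j, i] -= others
            elif rxn.kind == "polymerization":
                k_pol, k_depol = params.kinetics[rxn.rid]
                J[j, idx["B"]] = k_pol * state[idx["Ga"]] - k_depol
                J[j, idx["Ga"]] = k_pol * state[idx["B"]]
            else:  # turnover
                J[j, idx["Fa"]] = params.k_turn
        return J

    def rhs_jacobian(self, state: np.ndarray, params: CellParameterSet) -> np.ndarray:
        """Analytic Jacobian of the clamped right-hand side."""
        J = self.stoichiometry @ self.flux_jacobian(state, params)
        J[self._clamped_idx, :] = 0.0
        return J

    def residual_norm(self, state: np.ndarray, params: CellParameterSet) -> float:
        """max |dX/dt| over non-clamped species."""
        rhs = self._rhs_unchecked(np.asarray(state, dtype=float), params)
        return float(np.max(np.abs(rhs)))


def build_network() -> NetworkModel:
    """The canonical nine-reaction capping/bundling network.

    R1: CP + B <-> CPB          R2: E + A <-> EA
    R3: EA + B <-> EAB          R4: E + I <-> EI
    R5: EI + Fa <-> EIFa        R6: V + I <-> VI
    R7: VI + Fa <-> VIFa        R8: Ga + B <-> Fa + B (Ga clamped)
    R9: Fa -> 0 (irreversible turnover)

    Eps8 binds IRSp53 or Abi in competition; no Abi/IRSp53 triple complex
    exists.  Six moieties (Eps8, Abi, IRSp53, VASP, CP, barbed ends) are
    conserved; Fa is not, because of the polymerization source and the
    turnover sink.
    """
    return NetworkModel(_canonical_species(), _canonical_reactions())
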