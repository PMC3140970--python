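"""Parameter sets: total concentrations and kinetic constants per cell context.

Units are nM for concentrations, s for time; bimolecular on-rates are
nM^-1 s^-1 and off-rates s^-1.  The G-actin pool available for
polymerization is buffered by the cell and treated as a fixed 10 uM
(10,000 nM) parameter.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

PROTEINS: tuple[str, ...] = ("Eps8", "Abi", "IRSp53", "VASP", "CP")

#: reaction ids carrying (k_on, k_off) pairs; 8 holds (k_pol, k_depol)
KINETIC_RIDS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)


@dataclass
class CellParameterSet:
    """Totals plus kinetics for one cell context / genotype.

    ``kinetics`` maps reaction id -> (k_on, k_off); entry 8 is the
    polymerization pair (k_pol, k_depol).  ``k_turn`` is the first-order
    F-actin turnover rate of the single irreversible reaction.
    """

    totals: dict[str, float]
    b_total: float
    kinetics: dict[int, tuple[float, float]]
    k_turn: float
    ga: float = 10000.0
    context_label: str = "custom"

    def __post_init__(self) -> None:
        for name in PROTEINS:
            if name not in self.totals:
                raise ValueError(f"missing total concentration for {name}")
            if self.totals[name] < 0:
                raise ValueError(f"negative total for {name}")
        if self.b_total < 0 or self.ga < 0:
            raise ValueError("negative pool size")
        for rid in KINETIC_RIDS:
            if rid not in self.kinetics:
                raise ValueError(f"missing kinetics for reaction {rid}")
            k_on, k_off = self.kinetics[rid]
            if k_on < 0 or k_off < 0:
                raise ValueError(f"negative rate constant in reaction {rid}")
        if self.k_turn < 0:
            raise ValueError("negative turnover rate")

    # -- derived quantities -------------------------------------------

    def kd(self, rid: int) -> float:
        """Equilibrium dissociation constant k_off/k_on of a binding reaction."""
        k_on, k_off = self.kinetics[rid]
        if k_on == 0:
            return float("inf")
        return k_off / k_on

    def moiety_totals(self) -> np.ndarray:
        """Conserved totals in the conservation-matrix row order."""
        return np.array(
            [
                self.totals["Eps8"],
                self.totals["Abi"],
                self.totals["IRSp53"],
                self.totals["VASP"],
                self.totals["CP"],
                self.b_total,
            ]
        )

    def copy(self) -> "CellParameterSet":
        return CellParameterSet(
            totals=dict(self.totals),
            b_total=self.b_total,
            kinetics={rid: tuple(kk) for rid, kk in self.kinetics.items()},
            k_turn=self.k_turn,
            ga=self.ga,
            context_label=self.context_label,
        )

    # -- flat parameter addressing (used by the sensitivity scan) ------

    def parameter_names(self) -> list[str]:
        names: list[str] = []
        for rid in range(1, 8):
            names.append(f"k_on_R{rid}")
            names.append(f"k_off_R{rid}")
        names += ["k_pol", "k_depol", "k_turn"]
        names += [f"{p}_total" for p in PROTEINS]
        names += ["B_total", "Ga"]
        return names

    def get_parameter(self, name: str) -> float:
        if name.startswith("k_on_R"):
            return self.kinetics[int(name[6:])][0]
        if name.startswith("k_off_R"):
            return self.kinetics[int(name[7:])][1]
        if name == "k_pol":
            return self.kinetics[8][0]
        if name == "k_depol":
            return self.kinetics[8][1]
        if name == "k_turn":
            return self.k_turn
        if name.endswith("_total"):
            prot = name[: -len("_total")]
            if prot == "B":
                return self.b_total
            return self.totals[prot]
        if name == "Ga":
            return self.ga
        raise KeyError(f"unknown parameter {name!r}")

    def with_parameter(self, name: str, value: float) -> "CellParameterSet":
        out = self.copy()
        if name.startswith("k_on_R"):
            rid = int(name[6:])
            out.kinetics[rid] = (value, out.kinetics[rid][1])
        elif name.startswith("k_off_R"):
            rid = int(name[7:])
            out.kinetics[rid] = (out.kinetics[rid][0], value)
        elif name == "k_pol":
            out.kinetics[8] = (value, out.kinetics[8][1])
        elif name == "k_depol":
            out.kinetics[8] = (out.kinetics[8][0], value)
        elif name == "k_turn":
            out.k_turn = value
        elif name == "B_total":
            out.b_total = value
        elif name == "Ga":
            out.ga = value
        elif name.endswith("_total"):
            prot = name[: -len("_total")]
            if prot not in out.totals:
                raise KeyError(f"unknown parameter {name!r}")
            out.totals[prot] = value
        else:
            raise KeyError(f"unknown parameter {name!r}")
        return out

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "totals_nM": dict(self.totals),
            "b_total_nM": self.b_total,
            "g_actin_nM": self.ga,
            "kinetics": {
                f"R{rid}": {"k_on": kk[0], "k_off": kk[1]}
                for rid, kk in sorted(self.kinetics.items())
            },
            "k_turn_per_s": self.k_turn,
            "context_label": self.context_label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CellParameterSet":
        kinetics = {
            int(key[1:]): (float(val["k_on"]), float(val["k_off"]))
            for key, val in d["kinetics"].items()
        }
        return cls(
            totals={k: float(v) for k, v in d["totals_nM"].items()},
            b_total=float(d["b_total_nM"]),
            kinetics=kinetics,
            k_turn=float(d["k_turn_per_s"]),
            ga=float(d.get("g_actin_nM", 10000.0)),
            context_label=str(d.get("context_label", "custom")),
        )
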