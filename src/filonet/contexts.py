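"""Cell contexts (HeLa, hippocampal neuron, MVD7 fibroblast) and genotypes.

A context scales the endogenous totals: the HeLa and MVD7 "wild type"
includes 10x IRSp53 over-expression (filopodia were counted in
IRSp53-transfected cells), neurons use endogenous IRSp53 but five-fold
more Abi (for Abi-2) and VASP-family protein, and MVD7 cells carry no
VASP-family protein at all.  Genotypes are multiplicative perturbations
of single totals: x10 over-expression, x0.1 RNAi knockdown or
dominant-negative interference, x0 genetic knockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import default_config, endogenous_params
from .params import PROTEINS, CellParameterSet

CONTEXTS: tuple[str, ...] = ("hela", "neuron", "mvd7")

#: canonical perturbation factors
KNOCKOUT = 0.0
KNOCKDOWN = 0.1
OVEREXPRESSION = 10.0
_CANONICAL_FACTORS = frozenset({KNOCKOUT, KNOCKDOWN, OVEREXPRESSION})


@dataclass(frozen=True)
class GenotypeSpec:
    """A labelled list of (protein, factor) total-concentration scalings."""

    label: str
    perturbations: tuple[tuple[str, float], ...] = ()
    allow_custom_factors: bool = False

    def __post_init__(self) -> None:
        for protein, factor in self.perturbations:
            if protein not in PROTEINS:
                raise ValueError(f"unknown protein {protein!r}")
            if factor not in _CANONICAL_FACTORS and not self.allow_custom_factors:
                raise ValueError(
                    f"factor {factor} for {protein} is not a canonical "
                    "knockout (0), knockdown (0.1) or over-expression (10) "
                    "factor; pass allow_custom_factors=True to override"
                )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "perturbations": [[p, f] for p, f in self.perturbations],
            "allow_custom_factors": self.allow_custom_factors,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenotypeSpec":
        return cls(
            label=str(d["label"]),
            perturbations=tuple((p, float(f)) for p, f in d.get("perturbations", [])),
            allow_custom_factors=bool(d.get("allow_custom_factors", False)),
        )


WT = GenotypeSpec("WT")


def cell_context(name: str, config: Mapping | None = None) -> CellParameterSet:
    """Wild-type parameter set for one of the three cell contexts."""
    cfg = config if config is not None else default_config()
    if name not in cfg["contexts"]:
        raise ValueError(f"unknown cell context {name!r}; known: {sorted(cfg['contexts'])}")
    params = endogenous_params(cfg)
    spec = cfg["contexts"][name]
    for protein, factor in spec.get("factors", {}).items():
        params.totals[protein] = params.totals[protein] * float(factor)
    for key, value in spec.items():
        if key.endswith("_nM"):  # absolute override, e.g. Eps8_nM
            params.totals[key[:-3]] = float(value)
    params.context_label = f"{name}:WT"
    return params


def apply_genotype(base: CellParameterSet, genotype: GenotypeSpec) -> CellParameterSet:
    """Scale the perturbed totals; kinetics are untouched."""
    out = base.copy()
    for protein, factor in genotype.perturbations:
        if protein not in out.totals:
            raise ValueError(f"unknown protein {protein!r}")
        out.totals[protein] = out.totals[protein] * factor
    context = base.context_label.split(":", 1)[0]
    out.context_label = f"{context}:{genotype.label}"
    return out


def genotype_library() -> list[tuple[str, GenotypeSpec]]:
    """The genotype panels simulated for each cell context."""
    G = GenotypeSpec
    return [
        ("hela", WT),
        ("hela", G("Eps8 KD", (("Eps8", KNOCKDOWN),))),
        ("hela", G("Abi KD", (("Abi", KNOCKDOWN),))),
        ("hela", G("VASP interference", (("VASP", KNOCKDOWN),))),
        ("hela", G("Eps8+VASP KD", (("Eps8", KNOCKDOWN), ("VASP", KNOCKDOWN)))),
        ("hela", G("CP KD", (("CP", KNOCKDOWN),))),
        ("neuron", WT),
        ("neuron", G("Eps8 KO", (("Eps8", KNOCKOUT),))),
        ("neuron", G("VASP DN", (("VASP", KNOCKDOWN),))),
        ("neuron", G("Eps8 KO + VASP DN", (("Eps8", KNOCKOUT), ("VASP", KNOCKDOWN)))),
        ("mvd7", WT),
        ("mvd7", G("CP KD", (("CP", KNOCKDOWN),))),
    ]
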