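"""Panel orchestration: genotype sweeps, composition and FII/RFI tables.

Runs every genotype of the library per cell context, checks convergence
and stability, and emits three deterministic tables:

* composition — each protein's distribution across its complexes, as a
  percentage of that protein's wild-type total (the WT rows of a protein
  sum to 100 by conservation);
* fii — initiator concentrations, FII and the predicted RFI from the
  Gaussian-threshold population layer;
* sensitivity — optional +/-1% scan per context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import contexts as ctx
from .config import default_config
from .filopodia import (
    compute_fii,
    default_population,
    initiator_concentration,
    predict_rfi,
)
from .network import build_network
from .params import PROTEINS
from .sensitivity import sensitivity_scan
from .steady import SteadyState, solve_steady

#: species that contain each protein moiety, for the composition table
_PROTEIN_SPECIES = {
    "Eps8": ("E", "EA", "EAB", "EI", "EIFa"),
    "Abi": ("A", "EA", "EAB"),
    "IRSp53": ("I", "EI", "EIFa", "VI", "VIFa"),
    "VASP": ("V", "VI", "VIFa"),
    "CP": ("CP", "CPB"),
}

_CSV_FLOAT_FORMAT = "%.12g"


@dataclass
class PanelResult:
    composition: pd.DataFrame
    fii: pd.DataFrame
    sensitivity: pd.DataFrame | None
    steady_states: dict[tuple[str, str], SteadyState]
    log: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("composition.csv", self.composition),
            ("fii.csv", self.fii),
            ("sensitivity.csv", self.sensitivity),
        ):
            if frame is None:
                continue
            path = out / name
            frame.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
            written.append(path)
        (out / "panel.log").write_text("\n".join(self.log) + "\n")
        written.append(out / "panel.log")
        return written


def run_panel(
    config: Mapping | None = None,
    include_sensitivity: bool = False,
) -> PanelResult:
    """Simulate the full genotype library under one configuration."""
    cfg = config if config is not None else default_config()
    model = build_network()
    pop_cfg = cfg.get("population", {})
    sigma_over_mu = float(pop_cfg.get("sigma_over_mu", 0.25))
    fi_crit_over_mu = float(pop_cfg.get("fi_crit_over_mu", 1.0))

    steadies: dict[tuple[str, str], SteadyState] = {}
    log: list[str] = []
    wt_params: dict[str, object] = {}
    for context, genotype in ctx.genotype_library():
        base = ctx.cell_context(context, cfg)
        wt_params.setdefault(context, base)
        params = ctx.apply_genotype(base, genotype)
        ss = solve_steady(model, params)
        log.append(
            f"{params.context_label}: residual={ss.residual_norm:.3e} "
            f"max_re_eig={ss.max_re_eigenvalue:.3e} converged={ss.converged}"
        )
        if not ss.converged:
            raise RuntimeError(f"steady state failed to converge: {params.context_label}")
        steadies[(context, genotype.label)] = ss

    comp_rows = []
    fii_rows = []
    for context, genotype in ctx.genotype_library():
        ss = steadies[(context, genotype.label)]
        wt = steadies[(context, "WT")]
        base = wt_params[context]
        for protein in PROTEINS:
            wt_total = base.totals[protein]
            for species in _PROTEIN_SPECIES[protein]:
                percent = (
                    100.0 * ss.concentrations[species] / wt_total
                    if wt_total > 0
                    else 0.0
                )
                comp_rows.append(
                    {
                        "context": context,
                        "genotype": genotype.label,
                        "protein": protein,
                        "species": species,
                        "percent_of_wt_total": percent,
                    }
                )
        fii_res = compute_fii(ss, wt)
        pop = default_population(fii_res.fic_wt, sigma_over_mu, fi_crit_over_mu)
        rfi = predict_rfi(fii_res.fii, pop)
        fii_rows.append(
            {
                "context": context,
                "genotype": genotype.label,
                "fic_wt": fii_res.fic_wt,
                "fic_genotype": fii_res.fic_genotype,
                "fii": fii_res.fii,
                "predicted_rfi": rfi.predicted_rfi,
                "linear_regime": rfi.linear_regime,
            }
        )

    sens_frame = None
    if include_sensitivity:
        frames = []
        for context in ctx.CONTEXTS:
            scan = sensitivity_scan(ctx.cell_context(context, cfg), model)
            frames.append(scan.to_frame())
            log.append(
                f"sensitivity {context}: max|sigma|={scan.max_abs_sigma():.4g} "
                f"sensitive={sorted(scan.sensitive_parameters)}"
            )
        sens_frame = pd.concat(frames, ignore_index=True)

    return PanelResult(
        composition=pd.DataFrame(comp_rows),
        fii=pd.DataFrame(fii_rows),
        sensitivity=sens_frame,
        steady_states=steadies,
        log=log,
    )


def simulate_single(
    context: str,
    genotype_label: str = "WT",
    config: Mapping | None = None,
) -> SteadyState:
    """Steady state of one context+genotype from the library (or plain WT)."""
    cfg = config if config is not None else default_config()
    model = build_network()
    base = ctx.cell_context(context, cfg)
    genotype = ctx.WT
    if genotype_label != "WT":
        matches = [
            g
            for c, g in ctx.genotype_library()
            if c == context and g.label == genotype_label
        ]
        if not matches:
            raise ValueError(
                f"unknown genotype {genotype_label!r} for context {context!r}"
            )
        genotype = matches[0]
    params = ctx.apply_genotype(base, genotype)
    ss = solve_steady(model, params)
    if not ss.converged:
        raise RuntimeError(f"steady state failed to converge: {params.context_label}")
    return ss
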