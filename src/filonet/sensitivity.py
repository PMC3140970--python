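"""Local parameter sensitivity of the wild-type initiator concentration.

Every kinetic constant and total concentration is perturbed by plus and
minus one percent, the steady state is re-solved, and the dimensionless
coefficient

    sigma = [(y(k*) - y(k)) / y(k)] / [(k_j* - k_j) / k_j]

is recorded, where y is the WT concentration of filopodia initiation
complexes.  |sigma| > 1 for a 1% perturbation marks a sensitive
parameter; robustness means everything outside the capping-protein /
barbed-end balance stays below that bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .filopodia import initiator_concentration
from .network import NetworkModel, build_network
from .params import CellParameterSet
from .steady import solve_steady

#: parameters that set the capping-protein-to-barbed-ends balance
CAPPING_BALANCE_PARAMS = frozenset({"CP_total", "B_total", "k_on_R1", "k_off_R1"})

#: |sigma| above this for a 1% perturbation flags a sensitive parameter
SENSITIVE_THRESHOLD = 1.0


@dataclass(frozen=True)
class SensitivityRecord:
    context: str
    parameter: str
    direction: str  # "+1%" or "-1%"
    sigma: float
    sensitive: bool
    converged: bool


@dataclass
class SensitivityScan:
    context: str
    records: list[SensitivityRecord]
    failures: list[str]

    @property
    def sensitive_parameters(self) -> set[str]:
        return {r.parameter for r in self.records if r.sensitive}

    def max_abs_sigma(self, exclude: Sequence[str] = ()) -> float:
        vals = [
            abs(r.sigma)
            for r in self.records
            if r.parameter not in set(exclude) and r.converged
        ]
        return max(vals) if vals else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "context": r.context,
                    "parameter": r.parameter,
                    "direction": r.direction,
                    "sigma": r.sigma,
                    "sensitive": r.sensitive,
                    "converged": r.converged,
                }
                for r in self.records
            ]
        )


def _default_observable(model: NetworkModel):
    def observable(params: CellParameterSet, guess=None) -> tuple[float, bool, object]:
        ss = solve_steady(model, params, guess=guess)
        return initiator_concentration(ss), ss.converged, ss

    return observable


def sensitivity_coefficient(
    model: NetworkModel,
    params: CellParameterSet,
    parameter: str,
    delta: float = 0.01,
    observable: Callable[[CellParameterSet], float] | None = None,
) -> SensitivityRecord:
    """Normalized finite-difference sensitivity of one parameter.

    ``delta`` is the relative perturbation (sign included).  A parameter
    whose value is exactly zero cannot be perturbed multiplicatively and
    is reported with sigma = 0.  ``observable`` may override the default
    WT initiator concentration (it receives a parameter set and returns a
    number), which is mainly useful for testing.
    """
    direction = f"{'+' if delta > 0 else '-'}{abs(delta) * 100:g}%"
    k = params.get_parameter(parameter)
    if k == 0.0:
        return SensitivityRecord(
            params.context_label, parameter, direction, 0.0, False, True
        )
    if observable is not None:
        y0 = observable(params)
        y1 = observable(params.with_parameter(parameter, k * (1.0 + delta)))
        converged = True
    else:
        obs = _default_observable(model)
        y0, conv0, ss0 = obs(params)
        guess = model.state_vector(ss0.concentrations)
        y1, conv1, _ = obs(params.with_parameter(parameter, k * (1.0 + delta)), guess)
        converged = conv0 and conv1
    if y0 == 0.0:
        sigma = float("nan")
    else:
        sigma = ((y1 - y0) / y0) / delta
    sensitive = converged and np.isfinite(sigma) and abs(sigma) > SENSITIVE_THRESHOLD
    return SensitivityRecord(
        params.context_label, parameter, direction, float(sigma), sensitive, converged
    )


def sensitivity_scan(
    params: CellParameterSet,
    model: NetworkModel | None = None,
    deltas: Sequence[float] = (0.01, -0.01),
) -> SensitivityScan:
    """Scan every kinetic constant and total concentration in both directions.

    The base steady state is solved once and reused as a warm start for all
    perturbed systems, so a structurally inactive parameter (zero-flux
    reaction) yields sigma = 0 exactly and the scan is fully deterministic.
    """
    model = model if model is not None else build_network()
    base = solve_steady(model, params)
    if not base.converged:
        raise RuntimeError(f"base steady state failed to converge for {params.context_label}")
    y0 = initiator_concentration(base)
    guess = model.state_vector(base.concentrations)

    records: list[SensitivityRecord] = []
    failures: list[str] = []
    for name in params.parameter_names():
        k = params.get_parameter(name)
        for delta in deltas:
            direction = f"{'+' if delta > 0 else '-'}{abs(delta) * 100:g}%"
            if k == 0.0:
                records.append(
                    SensitivityRecord(
                        params.context_label, name, direction, 0.0, False, True
                    )
                )
                continue
            ss = solve_steady(
                model, params.with_parameter(name, k * (1.0 + delta)), guess=guess
            )
            y1 = initiator_concentration(ss)
            sigma = ((y1 - y0) / y0) / delta if y0 > 0 else float("nan")
            sensitive = (
                ss.converged and np.isfinite(sigma) and abs(sigma) > SENSITIVE_THRESHOLD
            )
            records.append(
                SensitivityRecord(
                    params.context_label,
                    name,
                    direction,
                    float(sigma),
                    sensitive,
                    ss.converged,
                )
            )
            if not ss.converged:
                failures.append(f"{name} {direction}")
    return SensitivityScan(
        context=params.context_label, records=records, failures=failures
    )
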