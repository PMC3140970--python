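import numpy as np
import pytest
from hypothesis import settings

import filonet as fn
from filonet.params import CellParameterSet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return fn.build_network()


@pytest.fixture(scope="session")
def hela():
    return fn.cell_context("hela")


@pytest.fixture(scope="session")
def neuron():
    return fn.cell_context("neuron")


@pytest.fixture(scope="session")
def mvd7():
    return fn.cell_context("mvd7")


def random_params(rng: np.random.Generator) -> CellParameterSet:
    """A random but physically plausible parameter set.

    Totals and dissociation constants are drawn log-uniformly around the
    defaults; capping protein stays in excess of the barbed ends (the
    regime the model operates in) and net polymerization is positive.
    """

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    kd_ranges = {
        1: (0.01, 1.0),
        2: (10.0, 1000.0),
        3: (0.003, 1.0),
        4: (1.0, 100.0),
        5: (100.0, 5000.0),
        6: (1.0, 100.0),
        7: (1.0, 100.0),
    }
    kinetics = {}
    for rid, (lo, hi) in kd_ranges.items():
        k_off = lu(0.03, 0.3)
        kinetics[rid] = (k_off / lu(lo, hi), k_off)
    kinetics[8] = (lu(5e-3, 2e-2), lu(0.5, 2.0))  # k_pol * Ga >> k_depol
    b_total = lu(10.0, 300.0)
    return CellParameterSet(
        totals={
            "Eps8": lu(20.0, 2000.0),
            "Abi": lu(20.0, 2000.0),
            "IRSp53": lu(20.0, 3000.0),
            "VASP": lu(20.0, 2000.0),
            "CP": lu(2.0 * b_total, 20.0 * b_total),
        },
        b_total=b_total,
        kinetics=kinetics,
        k_turn=lu(3e-3, 3e-2),
        context_label="random",
    )


def random_state(model, rng: np.random.Generator) -> np.ndarray:
    """A random non-negative full state (no conservation constraint)."""
    x = rng.uniform(0.0, 500.0, size=model.n_species)
    x[model.index["Ga"]] = 10000.0
    return x


def max_species_rel_diff(a: fn.SteadyState, b: fn.SteadyState) -> float:
    diffs = []
    for name in a.concentrations:
        if name == "Ga":
            continue
        x, y = a.concentrations[name], b.concentrations[name]
        denom = max(abs(x), abs(y))
        if denom > 1e-9:  # below the residual tolerance both count as zero
            diffs.append(abs(x - y) / denom)
    return max(diffs)
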