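"""Synthetic single-cell populations and pseudo-experimental RFI counts.

Emulates the statistical structure the analysis assumes: each cell draws
its initiator concentration from a Gaussian centred on the deterministic
steady-state value (truncated at zero, since concentrations cannot be
negative), forms filopodia when the draw exceeds FI_crit, and the
observed fraction of forming cells carries binomial counting noise.
The inverse fit recovers (FI_crit, sigma) from such fraction curves,
closing the loop on the population layer without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .filopodia import PopulationModel, fraction_forming


@dataclass(frozen=True)
class SyntheticExperiment:
    context: str
    genotype: str
    n_cells: int
    seed: int
    mu: float
    cell_initiators: np.ndarray
    n_forming: int
    observed_fraction: float


@dataclass(frozen=True)
class ThresholdFit:
    fi_crit: float
    sigma: float
    residuals: np.ndarray
    n_points: int


def sample_population(
    mu: float, sigma: float, n: int, seed: int
) -> np.ndarray:
    """n initiator concentrations ~ Normal(mu, sigma) truncated at zero.

    Deterministic for a given seed; the sigma -> 0 limit returns mu exactly.
    """
    if n < 1:
        raise ValueError("need at least one cell")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return np.full(n, float(mu))
    rng = np.random.default_rng(seed)
    a = (0.0 - mu) / sigma  # truncation at zero concentration
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def truncated_fraction_forming(pop: PopulationModel) -> float:
    """Forming fraction under the zero-truncated sampling distribution."""
    if pop.fi_crit <= 0:
        return 1.0
    z_crit = (pop.fi_crit - pop.mu) / pop.sigma
    z_zero = (0.0 - pop.mu) / pop.sigma
    upper = stats.norm.sf(z_crit)
    mass = stats.norm.sf(z_zero)
    return float(upper / mass) if mass > 0 else 0.0


def simulate_rfi_experiment(
    fii_table: pd.DataFrame,
    pop_wt: PopulationModel,
    n_cells: int,
    seed: int,
) -> pd.DataFrame:
    """Pseudo-experimental RFI measurements for a panel of genotypes.

    ``fii_table`` needs columns ``context``, ``genotype`` and ``fii`` and
    one ``WT`` row per context (the deterministic layer supplies it).  Each
    genotype's population mean is fii * mu_wt; cells above fi_crit count as
    forming, and RFI_obs is the forming fraction over the WT one.
    """
    required = {"context", "genotype", "fii"}
    if not required.issubset(fii_table.columns):
        raise ValueError(f"fii_table needs columns {sorted(required)}")
    rng_seed = np.random.SeedSequence(seed)
    rows = []
    for offset, (_, row) in enumerate(fii_table.iterrows()):
        cell_seed = int(np.random.default_rng([seed, offset]).integers(2**31))
        mu_g = float(row["fii"]) * pop_wt.mu
        cells = sample_population(mu_g, pop_wt.sigma, n_cells, cell_seed)
        n_forming = int(np.sum(cells > pop_wt.fi_crit))
        rows.append(
            {
                "context": row["context"],
                "genotype": row["genotype"],
                "n_cells": n_cells,
                "seed": cell_seed,
                "mu": mu_g,
                "n_forming": n_forming,
                "observed_fraction": n_forming / n_cells,
            }
        )
    out = pd.DataFrame(rows)
    rfi = np.full(len(out), np.nan)
    for context, sub in out.groupby("context"):
        wt = sub[sub["genotype"] == "WT"]
        if len(wt) != 1:
            raise ValueError(f"context {context!r} needs exactly one WT row")
        frac_wt = float(wt["observed_fraction"].iloc[0])
        if frac_wt == 0.0:
            raise ValueError(f"no forming cells in the WT population of {context!r}")
        rfi[sub.index] = sub["observed_fraction"] / frac_wt
    out["rfi_obs"] = rfi
    return out


def recover_threshold(experiments: pd.DataFrame) -> ThresholdFit:
    """Least-squares fit of the Erf-tail model to observed forming fractions.

    Requires columns ``mu`` and ``observed_fraction`` with at least three
    distinct population means; a two-point design is under-determined for
    the (fi_crit, sigma) pair and rejected.
    """
    mu = np.asarray(experiments["mu"], dtype=float)
    frac = np.asarray(experiments["observed_fraction"], dtype=float)
    if len(np.unique(mu)) < 3:
        raise ValueError(
            "under-determined design: need >= 3 genotypes with distinct means "
            "to fit (fi_crit, sigma)"
        )

    def tail(mu_vec: np.ndarray, fi_crit: float, sigma: float) -> np.ndarray:
        return 0.5 * special.erfc((fi_crit - mu_vec) / (sigma * np.sqrt(2.0)))

    def loss(theta: np.ndarray) -> np.ndarray:
        return tail(mu, theta[0], theta[1]) - frac

    mu_span = np.ptp(mu) if np.ptp(mu) > 0 else np.mean(mu)
    x0 = np.array([np.median(mu), 0.25 * mu_span])
    sol = optimize.least_squares(
        loss, x0, bounds=([0.0, 1e-9], [np.inf, np.inf]), xtol=1e-15, ftol=1e-15
    )
    return ThresholdFit(
        fi_crit=float(sol.x[0]),
        sigma=float(sol.x[1]),
        residuals=sol.fun,
        n_points=len(mu),
    )
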