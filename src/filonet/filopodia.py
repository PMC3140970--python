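"""Filopodia initiation index (FII) and the Gaussian-threshold population map.

The deterministic model yields the summed steady-state concentration of
the two membrane-anchored filopodia initiation complexes (FIC),
[Eps8:IRSp53:Fa] + [VASP:IRSp53:Fa].  The FII of a genotype is that sum
normalized by its wild-type value.

Cell-to-cell variability is modelled by a Gaussian distribution of the
initiator concentration across the population; a cell forms filopodia
when its initiator level exceeds the critical concentration FI_crit that
triggers the membrane-curvature positive feedback loop.  The fraction of
forming cells is then the upper tail of the Gaussian (an Erf law), and
the predicted relative filopodia index (RFI) of a genotype is the ratio
of that fraction to the wild-type fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .steady import SteadyState

#: species summed into the initiator observable
INITIATOR_SPECIES = ("EIFa", "VIFa")


@dataclass(frozen=True)
class PopulationModel:
    """Gaussian population of initiator concentrations with a hard threshold.

    mu and sigma are the mean and standard deviation of the initiator
    concentration (nM) across cells; fi_crit (nM) is the concentration
    needed to ignite the positive feedback loop.
    """

    mu: float
    sigma: float
    fi_crit: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.fi_crit <= 0:
            raise ValueError("fi_crit must be positive")


@dataclass(frozen=True)
class FIIResult:
    """FII of one genotype, optionally mapped to a predicted RFI."""

    fic_wt: float
    fic_genotype: float
    fii: float
    predicted_rfi: float | None = None
    linear_regime: bool | None = None


def initiator_concentration(steady: SteadyState) -> float:
    """[Eps8:IRSp53:Fa] + [VASP:IRSp53:Fa] at a steady state (nM)."""
    return sum(steady.concentrations[s] for s in INITIATOR_SPECIES)


def compute_fii(steady_g: SteadyState, steady_wt: SteadyState) -> FIIResult:
    """FII = initiator concentration of the genotype over the wild type."""
    for s in (steady_g, steady_wt):
        if not s.converged:
            raise ValueError(f"steady state {s.context_label!r} did not converge")
    ctx_g = steady_g.context_label.split(":", 1)[0]
    ctx_wt = steady_wt.context_label.split(":", 1)[0]
    if ctx_g != ctx_wt:
        raise ValueError(
            f"FII compares genotypes within one context, got {ctx_g!r} vs {ctx_wt!r}"
        )
    fic_wt = initiator_concentration(steady_wt)
    fic_g = initiator_concentration(steady_g)
    if fic_wt <= 0:
        raise ValueError("wild-type initiator concentration is zero; FII undefined")
    return FIIResult(fic_wt=fic_wt, fic_genotype=fic_g, fii=fic_g / fic_wt)


def fraction_forming(pop: PopulationModel) -> float:
    """Upper-tail mass of Normal(mu, sigma) above fi_crit.

    Integrating the Gaussian from FI_crit to infinity gives
    0.5 * erfc((fi_crit - mu) / (sigma * sqrt(2))).
    """
    z = (pop.fi_crit - pop.mu) / (pop.sigma * np.sqrt(2.0))
    return float(0.5 * erfc(z))


def default_population(
    mu_wt: float, sigma_over_mu: float = 0.25, fi_crit_over_mu: float = 1.0
) -> PopulationModel:
    """Population model anchored at the WT steady state.

    By default the threshold sits at the WT mean (cells are poised at the
    filopodia-formation threshold) with a quarter-of-the-mean spread.
    """
    return PopulationModel(
        mu=mu_wt, sigma=sigma_over_mu * mu_wt, fi_crit=fi_crit_over_mu * mu_wt
    )


def predict_rfi(
    fii_g: float, pop_wt: PopulationModel, linear_bound: float = 0.5
) -> FIIResult:
    """Predicted RFI for a genotype with the given FII.

    The genotype population keeps the WT sigma and fi_crit but shifts its
    mean to fii * mu_wt; the RFI is the ratio of forming fractions.  The
    result also reports whether both operating points sit within
    ``linear_bound`` standard deviations of the threshold — the regime
    where the Erf tail is approximately linear in the mean.
    """
    if fii_g < 0:
        raise ValueError("FII must be non-negative")
    frac_wt = fraction_forming(pop_wt)
    if frac_wt <= 0:
        raise ValueError("wild-type forming fraction is zero; RFI undefined")
    pop_g = PopulationModel(
        mu=fii_g * pop_wt.mu, sigma=pop_wt.sigma, fi_crit=pop_wt.fi_crit
    )
    frac_g = fraction_forming(pop_g)
    z_wt = abs(pop_wt.mu - pop_wt.fi_crit) / pop_wt.sigma
    z_g = abs(pop_g.mu - pop_g.fi_crit) / pop_g.sigma
    return FIIResult(
        fic_wt=pop_wt.mu,
        fic_genotype=pop_g.mu,
        fii=fii_g,
        predicted_rfi=frac_g / frac_wt,
        linear_regime=bool(max(z_wt, z_g) <= linear_bound),
    )
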