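"""The Gaussian-threshold population layer, forward and inverse.

Forward: map the deterministic initiator concentration to the fraction
of filopodia-forming cells via the Erf tail, and compare with a
synthetic single-cell population (Gaussian draws truncated at zero,
binomial counting).  Inverse: recover the threshold FI_crit and the
population width sigma from noisy synthetic fraction curves.
"""

import numpy as np
import pandas as pd

import filonet as fn
from filonet.filopodia import PopulationModel, fraction_forming

pop = PopulationModel(mu=100.0, sigma=25.0, fi_crit=100.0)
print(f"analytic forming fraction at mu = fi_crit: {fraction_forming(pop):.3f}")

cells = fn.sample_population(pop.mu, pop.sigma, n=20_000, seed=7)
print(f"Monte-Carlo fraction (20k cells):          {np.mean(cells > pop.fi_crit):.3f}")

table = pd.DataFrame(
    {
        "context": ["demo"] * 6,
        "genotype": ["WT", "g1", "g2", "g3", "g4", "g5"],
        "fii": [1.0, 0.2, 0.6, 0.9, 1.2, 1.6],
    }
)
experiments = fn.simulate_rfi_experiment(table, pop, n_cells=10_000, seed=7)
fit = fn.recover_threshold(experiments)
print(f"\ntrue (fi_crit, sigma) = (100, 25); recovered = "
      f"({fit.fi_crit:.1f}, {fit.sigma:.1f}) from {fit.n_points} genotypes")
print(
    "\nThe recovered pair matches the generating values to a few percent:"
    "\nthe Erf-tail model is identifiable from fraction curves alone."
)
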