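"""Solve one steady state two independent ways and inspect the complexes.

Solves the wild-type HeLa network by relaxation (ODE integration) and by
root-finding in conservation-reduced coordinates, prints the species
concentrations and the diagnostics that certify the state: the flux
residual, the largest real part of the reduced Jacobian spectrum
(negative = locally stable), and the agreement between the two solvers.
"""

import filonet as fn

model = fn.build_network()
params = fn.cell_context("hela")

relaxed = fn.relax_to_steady(model, params)
rooted = fn.solve_steady(model, params)

print("wild-type HeLa steady state (nM):")
for name, value in rooted.concentrations.items():
    print(f"  {name:5s} {value:12.4f}")
print(f"\nresidual max|dX/dt|: {rooted.residual_norm:.2e} nM/s")
print(f"max Re(eigenvalue):  {rooted.max_re_eigenvalue:.3e} 1/s -> stable={rooted.stable}")

worst = max(
    abs(relaxed.concentrations[k] - rooted.concentrations[k])
    / max(rooted.concentrations[k], 1e-9)
    for k in rooted.concentrations
)
print(f"relaxation vs root-finding, worst relative difference: {worst:.1e}")
print(
    "\nMost Eps8 sits in Eps8:IRSp53(:Fa) and nearly all VASP in"
    " VASP:IRSp53:Fa —\nin IRSp53-over-expressing HeLa cells both proteins"
    " act as bundlers, not cappers."
)
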