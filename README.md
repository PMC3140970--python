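# filonet

Deterministic mass-action modelling of the protein network that decides
whether a cell initiates filopodia — the Eps8/IRSp53/VASP/Abi/CP
capping–bundling module — with steady-state analysis across cell
contexts and genotypes, a Gaussian-threshold population layer, and local
parameter-sensitivity analysis.

## The problem

Filopodia are finger-like actin protrusions built on bundled parallel
filaments. Their initiation is controlled by a small competitive binding
network: capping protein (CP) and the Eps8:Abi complex block barbed ends
(limiting elongation), while the mutually exclusive SH3 complexes
Eps8:IRSp53 and VASP:IRSp53 decorate F-actin to form membrane-anchored
*filopodia initiation complexes* (FIC). The same protein — Eps8 — acts
as a capper when bound to Abi and as a bundler when bound to IRSp53, so
removing it can either suppress filopodia (epithelial cells, where it
mostly bundles) or enhance them (neurons, where it mostly caps). This
package is for quantitative cell biologists and systems modellers who
want to simulate, perturb and extend that switch.

## The model

Nine reactions over fifteen species, simple mass action, concentrations
in nM:

    R1: CP + B  ⇌ CPB        R2: E + A  ⇌ EA       R3: EA + B ⇌ EAB
    R4: E + I   ⇌ EI         R5: EI + Fa ⇌ EIFa    R6: V + I  ⇌ VI
    R7: VI + Fa ⇌ VIFa       R8: Ga →(B) Fa        R9: Fa → ∅

Polymerization (R8) converts a clamped 10 µM G-actin pool into bulk
F-actin at free barbed ends; turnover (R9) is the single irreversible
reaction. Six moieties (Eps8, Abi, IRSp53, VASP, CP, barbed ends) are
conserved. Steady states are found two independent ways — stiff ODE
relaxation and root-finding in conservation-reduced coordinates — and
certified stable through the Jacobian spectrum of the reduced system.

The model's observable is the **filopodia initiation index**

    FII = ([EIFa] + [VIFa])_genotype / ([EIFa] + [VIFa])_WT ,

and a population layer maps it to the measured **relative filopodia
index**: cells draw their initiator concentration from
Normal(μ, σ), form filopodia above a threshold FI_crit, so the forming
fraction is the Erf tail ½·erfc((FI_crit−μ)/(σ√2)) and
RFI = fraction(genotype)/fraction(WT).

## Worked example

```
python examples/genotype_panel.py
```

prints the full genotype panel (excerpt):

```
context  genotype                  FII  predicted RFI
hela     WT                      1.000          1.000
hela     Eps8 KD                 0.641          0.151
hela     Abi KD                  1.015          1.049
hela     Eps8+VASP KD            0.101          0.000
hela     CP KD                   1.191          1.556
neuron   Eps8 KO                 1.076          1.238
neuron   Eps8 KO + VASP DN       0.538          0.064
mvd7     CP KD                   1.474          1.942
```

Reading it: knocking down Eps8 in HeLa cells depletes initiators
(FII 0.64 < 1, fewer filopodia-forming cells), while knocking it out in
neurons enriches them (FII 1.08 > 1) because the freed IRSp53 is taken
over by VASP and the lost Eps8:Abi capping liberates barbed ends — the
paradoxical context dependence the model was built to explain. Removing
CP raises FII everywhere, including VASP-deficient MVD7 fibroblasts
where only the Eps8:IRSp53 arm can respond. The other examples inspect a
single steady state, run the sensitivity scan, and exercise the
population layer's forward map and inverse fit.

A thin CLI wraps the same calls:
`filonet panel`, `filonet simulate --context hela --genotype "Eps8 KD"`,
`filonet sensitivity --context neuron`, `filonet synthetic`,
`filonet export-sbml`.

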