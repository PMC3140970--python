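# Default model configuration (single versioned source of all defaults).
#
# Units: concentrations in nM, time in s; bimolecular k_on in nM^-1 s^-1.
#
# Measured/literature-anchored values: the clamped G-actin pool (10 uM),
# K_D(Eps8:IRSp53) = 10 nM, K_D(VASP:IRSp53) = 12.5 nM, and the 100-fold
# higher affinity of VASP:IRSp53 for F-actin relative to Eps8:IRSp53.
# The remaining rate constants and the endogenous totals are calibrated
# placeholders (see docs/methods.md): all binding off-rates are fixed at
# 0.1 s^-1 and on-rates derived from the dissociation constants noted on
# each line; totals are chosen so that most barbed ends are capped in the
# wild type.  Every entry may be overridden by a user config file.

endogenous_totals_nM:
  Eps8: 200.0
  Abi: 200.0      # pools Abi-1 and Abi-2
  IRSp53: 200.0
  VASP: 200.0     # pools all VASP-family members (VASP, Mena, EVL)
  CP: 150.0
b_total_nM: 100.0 # fixed total number of barbed ends (nucleation/depolymerization balance)
g_actin_nM: 10000.0

kinetics:         # K_D = k_off/k_on noted per reaction
  R1: {k_on: 1.0,     k_off: 0.1}  # CP + B,   K_D = 0.1 nM (tight capper)
  R2: {k_on: 2.0e-4,  k_off: 0.1}  # E + A,    K_D = 500 nM
  R3: {k_on: 10.0,    k_off: 0.1}  # EA + B,   K_D = 0.01 nM (Eps8:Abi is a high-affinity capper)
  R4: {k_on: 1.0e-2,  k_off: 0.1}  # E + I,    K_D = 10 nM   (measured)
  R5: {k_on: 1.0e-4,  k_off: 0.1}  # EI + Fa,  K_D = 1000 nM (low-speed centrifugation estimate; placeholder)
  R6: {k_on: 8.0e-3,  k_off: 0.1}  # V + I,    K_D = 12.5 nM (measured)
  R7: {k_on: 1.0e-2,  k_off: 0.1}  # VI + Fa,  K_D = 10 nM   (100x the EI:Fa affinity)
  R8: {k_on: 1.16e-2, k_off: 1.4}  # polymerization k_pol per end; monomer off-rate k_depol
k_turn_per_s: 0.01                 # bulk F-actin turnover

# Cell contexts as multiplicative factors on the endogenous totals (or
# absolute overrides via *_nM keys).  The "WT" of HeLa and MVD7 includes
# 10x IRSp53 over-expression because filopodia counting was done in
# IRSp53-transfected cells; neurons use endogenous IRSp53.
contexts:
  hela:
    factors: {IRSp53: 10.0}
  neuron:
    factors: {Abi: 5.0, VASP: 5.0}
  mvd7:
    # fibroblasts genetically devoid of VASP-family proteins; relative
    # Eps8/Abi levels vs HeLa are calibrated placeholders
    factors: {Eps8: 2.0, Abi: 0.5, VASP: 0.0, IRSp53: 10.0}

population:
  sigma_over_mu: 0.25   # population spread of initiator concentration
  fi_crit_over_mu: 1.0  # WT mean sits at the filopodia-formation threshold

perturbation_factors:
  over_expression: 10.0
  knockdown: 0.1
  knockout: 0.0
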