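# Methods

## Model

The network couples a *capping module* (CP and Eps8:Abi binding free
barbed ends B) to a *bundling module* (Eps8:IRSp53 and VASP:IRSp53
binding bulk F-actin, Fa) through three shared resources: Eps8, which
partitions between Abi (capping branch) and IRSp53 (bundling branch);
IRSp53, for whose SH3 domain Eps8 and VASP compete; and actin itself,
because the number of uncapped ends sets the polymerized pool that the
bundling complexes decorate. All binding steps are reversible mass
action. There is no Abi:IRSp53:Eps8 triple complex: the two Eps8
interactions are mutually exclusive.

Actin is treated as two well-stirred pools. G-actin (Ga) is clamped at
10 µM — cells buffer their monomer pool, and the analysis targets steady
states, not transients. Polymerization occurs at free barbed ends only,
with net rate (k_pol·Ga − k_depol)·[B]; capped ends (CPB, EAB) are
inert. Bulk F-actin turns over with first-order rate k_turn, the
single irreversible reaction. Pointed-end dynamics are absent — their
net effect is folded into the turnover term. Filament identity, length
distributions, space and membrane mechanics are all outside the model.

Bookkeeping choices that the biology does not dictate, fixed here once:
Fa counts bundler binding sites in nM; forming EIFa/VIFa consumes one Fa
unit stoichiometrically, and turnover acts on free Fa only. Barbed ends
are catalytic in R8 (polymerization does not consume B), consistent with
a fixed total number of ends maintained by the nucleation/
depolymerization balance. Reaction numbering R1–R9 is an internal
convention.

Six totals are conserved (Eps8, Abi, IRSp53, VASP, CP, B); Fa is
deliberately not, having a source and a sink. The VASP species pools all
VASP-family members (VASP, Mena, EVL), and Abi pools Abi-1/Abi-2.

## Parameters

Measured anchors, hard-wired into the default configuration
(`src/filonet/data/default_config.yaml`, the single versioned source of
defaults; any entry can be overridden by a user YAML):

* Ga = 10 µM;
* K_D(Eps8:IRSp53) = 10 nM and K_D(VASP:IRSp53) = 12.5 nM;
* the VASP:IRSp53 complex binds F-actin with 100-fold higher affinity
  than Eps8:IRSp53 (robustness of all qualitative results to making this
  1000-fold is part of the acceptance suite);
* over-expression multiplies a total by 10, RNAi knockdown and
  dominant-negative interference by 0.1, genetic knockout by 0.

Everything else is a calibrated placeholder, documented as such: all
binding off-rates are fixed at 0.1 s⁻¹ with on-rates derived from the
dissociation constants noted in the config (K_D(Eps8:Abi) = 500 nM,
K_D(EA:B) = 0.01 nM — Eps8:Abi is a high-affinity capper —
K_D(CP:B) = 0.1 nM, K_D(EI:Fa) = 1000 nM from low-speed-centrifugation
scale estimates); actin rates k_pol = 1.16×10⁻² nM⁻¹s⁻¹,
k_depol = 1.4 s⁻¹, k_turn = 10⁻² s⁻¹; endogenous totals 200 nM for
Eps8/Abi/IRSp53/VASP, 150 nM CP against 100 nM barbed ends, so that at
wild type ≈99.8% of ends are capped — the regime the model assumes.
These choices were made once, before the validation suites were run,
to satisfy the two structural requirements stated above (capped-end
regime; both bundler arms active in HeLa).

Cell contexts scale the endogenous totals. HeLa "WT" carries 10×
IRSp53 (filopodia were scored in IRSp53-transfected cells); neurons use
endogenous IRSp53 with Abi and VASP ×5; MVD7 fibroblasts have no VASP
family at all, with Eps8 ×2 and Abi ×0.5 relative to HeLa (relative
immunoblot levels, quantified here as order-of-magnitude placeholders)
and 10× IRSp53 for their "WT". The dominant-negative efficiency of VASP
interference is not separately known and mirrors the RNAi factor 0.1;
it is configurable.

## Steady states

Solved in reduced coordinates — the seven complexes plus Fa — with the
six free species eliminated through the conserved totals, so
conservation holds to machine precision by construction. Two routes:

* **relaxation**: BDF integration with the analytic Jacobian (the
  binding layer spans rates from ~10⁻³ to ~10³ s⁻¹ and is stiff), from
  an initial condition with each moiety fully in its free species, in
  windows growing tenfold up to t_max = 10⁶ s;
* **root-finding**: bounded trust-region least squares started from a
  damped fixed-point iteration of the binding equilibria (at steady
  state every reversible reaction individually carries zero net flux in
  this network, and Fa balances polymerization against turnover).

Both routes end with a damped Newton polish on the reduced residual;
without it, pure integration plateaus at the double-precision
flux-cancellation floor (~10⁻¹¹ nM/s), which would leave the smallest
species (free barbed ends sit at ~10⁻³ nM) accurate to only ~10⁻⁵
relative. The independence of the cross-check lies in how the two
routes *locate* the state (trajectory vs algebraic guess); the polish
only sharpens it. Convergence is declared at max|dX/dt| ≤ 10⁻⁹ nM/s
(far below nM-per-minute signal scales); non-convergence is flagged on
the returned object, never silent. Local stability is certified by the
eigenvalues of the analytic reduced Jacobian; every default context and
genotype is stable, and 20-fold random re-initialization finds no
multistability under the default parameters.

## Population layer

Across a cell population the initiator concentration is modelled as
Normal(μ, σ) with a hard threshold FI_crit above which the
membrane-curvature positive feedback ignites; the forming fraction is
the untruncated Gaussian upper tail. Defaults anchor the layer to the
deterministic wild type: FI_crit = μ_wt (cells poised at the threshold,
which is what makes small network perturbations consequential) and
σ = μ_wt/4. The synthetic sampler truncates draws at zero
concentration; at the default width the truncated-vs-analytic
discrepancy is below 10⁻³ and is asserted in the tests.

One coupling worth noting: the RFI-vs-FII slope at the threshold is
2φ(0)·μ/σ, so predicted RFI tracks FII one-to-one only when
σ ≈ 0.80·μ. An observed quantitative agreement between measured RFI and
computed FII therefore implicitly constrains the population width; the
near-linearity test uses that slope-matched width, while the default σ
remains μ/4.

The synthetic-data generator emulates exactly two noise sources: the
Gaussian cell-to-cell spread of initiator concentration and binomial
counting of forming cells (default fixture sizes 10³–10⁵ cells). It
does not emulate imaging noise, segmentation error, transfection
heterogeneity or day effects — so passing recovery tests shows the
Erf-tail analysis is self-consistent and identifiable, not that real
measurements carry no other error.

## Sensitivity

Finite differences, matching the original procedure: each rate constant
and total is multiplied by 1 ± 0.01, the steady state re-solved (warm
started from the base state, so structurally inactive parameters give
exactly zero), and σ = (Δy/y)/(Δk/k) recorded for y = WT initiator
concentration. |σ| > 1 flags a sensitive parameter. The capping
balance group is defined as {CP_total, B_total, k_on(R1), k_off(R1)} —
the parameters that directly set the capped fraction of ends. Under the
defaults the maximum |σ| outside that group is ≈0.999 (IRSp53 total in
neurons, where initiators are IRSp53-limited and the response is
asymptotically linear, hence bounded by 1); everything else sits well
below.

## Numerical choices and degenerate inputs

Zero totals are legal (MVD7 has VASP = 0); the corresponding complexes
are exactly zero and zero-capacity coordinates get negligible (10⁻¹²)
box slack in the bounded solver. A parameter whose value is zero cannot
be perturbed multiplicatively and is reported with σ = 0. Comparisons
between solvers treat species below 10⁻⁹ nM (the residual tolerance
scale) as zero. The pure-binding limit (R8/R9 off, Fa clamped) is
supported for testing equilibrium relations exactly. CSV outputs use a
fixed 12-significant-digit float format so repeated runs are
byte-identical.

## Limitations

No spatial structure, stochastic kinetics, filament-length resolution,
VASP anti-capping/processive elongation, or feedback-loop mechanics
(the threshold is taken as given, not derived); transient dynamics are
integrated only as a means to the steady state. Absolute concentrations
and several rate constants are placeholders — conclusions should be
read at the level the sensitivity analysis certifies: steady-state
ratios (FII) robust to parameter detail, with the capping-protein-to-
barbed-ends balance as the one genuine control knob.
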