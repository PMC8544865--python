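# Methods

## The modelling framework

`bondbio` represents a biochemical network as a bond graph: a graph whose
edges (bonds) each carry a chemical potential μ [J/mol] and a molar flux v
[mol/s], so every connection transfers both mass and energy (power P = μ·v).
Three component types carry all the physics:

* **Species** store chemical energy. In a dilute, isothermal, isobaric
  system the potential of a species with amount x is μ = RT ln(Kx), where
  the thermodynamic constant K encodes the standard free energy
  (K = exp(μ⁰/RT)/(c⁰V) for standard potential μ⁰ at reference
  concentration c⁰ in compartment volume V).
* **Reactions** dissipate energy. Their flux is a function of the forward
  and reverse affinities A_f, A_r (the summed potentials of reactants and
  products) through a thermodynamically consistent rate law (below).
* **Junctions** route energy losslessly. A 0-junction (common potential)
  forces all attached bonds to one potential while their flows sum to zero
  — the mass-balance/Kirchhoff-current analogue. A 1-junction (common
  flow) forces one flow while potentials sum to zero — the
  affinity-summation/Kirchhoff-voltage analogue.

Because the driving force of every reaction is built from species
potentials, the second law holds structurally: each reaction's dissipation
A·v is non-negative at every state, the total free energy
G = Σ μ_s x_s of a closed model can only fall, and detailed balance at
equilibrium is automatic. Equivalently, the Wegscheider conditions (cycle
products of equilibrium constants equal one) are satisfied for *any*
positive choice of (K, κ) — the thermodynamic parameters are free where
kinetic parameters (k⁺, k⁻) are constrained.

### Rate laws

All laws are evaluated in "amount space": exp(μ/RT) equals the
dimensionless activity a = K·x, and exp(A_f/RT) is the product of site
activities. This avoids logarithms of zero at empty pools and mirrors the
fact that mass-action bond-graph models reduce to polynomial ODEs.

* Mass action (Marcelin–de Donder): v = κ(e^{A_f/RT} − e^{A_r/RT}).
* Reversible Michaelis–Menten:
  v = κ̄e₀(a_S − a_P)/(1 + a_S/R_b0 + a_P/R_b1), with rate constant κ̄
  [1/s], enzyme total e₀ and dimensionless binding constants R_b. Our
  implementation lumps multi-species sides into the product of their
  activities; this is exact for one-substrate/one-product reactions and is
  how clamped co-substrates are folded in when a detailed law is
  simplified.
* Generalised kinetics: v = κ̄e₀(Πa_s − Πa_p)/(−1 + Π(1+a_s/R_b,s) +
  Π(1+a_p/R_b,p)), one binding constant per *site* (a species with
  stoichiometry n contributes n sites). With unit stoichiometries this is
  convenience kinetics; with one site per side it reduces algebraically to
  the Michaelis–Menten form.

### Composition and equation derivation

Models are built hierarchically from `CompositeModule` templates with
labelled exposed ports, addressed by dot-separated instance paths
(`cascade.L2.kinase.E`). `flatten` replaces modules by their contents;
equation assembly then traces each reaction port through the junction
network to the species whose potentials it sees (0-junction groups carry
exactly one species' potential; 1-junctions sum their branches, one binding
site per branch; parallel bonds encode stoichiometry > 1). The result is
the stoichiometric matrix N, a flux function v(x), and dx/dt = N·v(x) with
chemostat rows zeroed.

Chemostats — species held at fixed concentration to model exchange with
the environment — are implemented by zeroing rows of N rather than
removing species, so their potentials still drive fluxes. Conserved
moieties (left null space of the internal rows of N) and steady-state
pathway vectors (right null space of the internal submatrix) are computed
over the rationals with sympy and scaled to minimal integer vectors with a
canonical sign, so there is no floating-point rank ambiguity.

Kinetic→thermodynamic conversion solves the log-linear system
ln k± = ln κ + Σ ln K by least squares after checking the Wegscheider
conditions on an exact integer cycle basis (relative cycle-product
deviation ≤ 1e-6 passes; violations raise an error naming a violating
cycle and its mismatch ratio). The map has one gauge freedom per conserved
moiety of the full network; by default the first species of each moiety
basis vector is pinned to K = 1, and callers may pin any spanning set.

### Simulation and the perturbation protocol

Integration uses LSODA with rtol 1e-8 / atol 1e-12 by default; the enzyme
systems here put rate constants of 1e9 /M/s next to sub-nanomolar
concentrations and are stiff. Steady states are found by integrating over
doubling horizons until max_s |dx_s/dt|/max(x_s, floor) < 1e-9 (configurable),
followed by a log-space least-squares polish that respects conserved-moiety
totals.

Perturbations follow a fixed protocol: from a reference steady state one
species is scaled by a factor (default 1.3); the deviation
d(t) = √Σ_{s∈S_i}(x_s − x_{s,ss})² is tracked over a designated internal
set S_i, and the *response time* is the last instant d(t) is at or above
5% of its maximum (linearly interpolated, hence invariant under rescaling
d). The horizon doubles adaptively until d falls below 1% of its maximum.
For chemostat (prolonged) perturbations the clamp itself changes: the run
reports the Euclidean steady-state shift relative to the reference and
measures the response time as settling toward the *new* state, since the
system never returns to the old one.

## The MAPK cascade model

Three levels of phosphorylation cycles (MAP4K → MAP3K → MAP2K → MAPK, the
second and third doubly and distributively phosphorylated) built from
generic two-state kinase (E + X + ATP ⇌ C ⇌ E + XP + ADP) and phosphatase
(E + XP ⇌ C ⇌ E + X + Pi) modules, combined into a cycle template and
instantiated five times; ATP, ADP and Pi are shared through one global
chemostatted junction each. Feedback variants add a sixth cycle converting
the input between active and inactive forms with the output MAPKPP as its
kinase; positive versus negative feedback differs *only* in which cycle
port (phosphorylated or unphosphorylated) the active input occupies.

The published parameter supplement for the original reformulation is not
redistributable, so the package ships a synthetic, seed-free parameter set
chosen from the classic Huang–Ferrell operating regime and mapped into
thermodynamic space:

* kinetic targets per enzymatic step: effective on-rate a = 1e9 /M/s,
  complex dissociation d = 150 /s, catalytic step k = 150 /s (K_m =
  300 nM);
* each attached phosphate multiplies the substrate's K by 1e4, and the
  cofactor clamp contributes an activity ratio a_ATP/(a_ADP·a_Pi) = 1e8,
  so the ~47 kJ/mol hydrolysis affinity (RT ln 1e8 at 310 K) is split
  evenly between the kinase and phosphatase legs of every cycle;
* concentrations: MAP3K 3 nM, MAP2K and MAPK 1.2 μM, phosphatases
  0.3 nM / 0.3 nM / 0.12 μM, input MAP4K around 0.03 nM (varied in
  sweeps); the feedback cycle reuses the level-1 kinetics with a 0.3 nM
  phosphatase — a default flagged here because no published value exists,
  overridable through `CascadeConfig`.

Reverse rate constants are never set to zero; they follow from the
thermodynamic parameterisation (e.g. the reverse of the catalytic step is
~1e5 /M/s against 150 /s forward), which is what makes the
reduced-ATP-energy experiment meaningful: `atp_energy_fraction` scales the
clamp μ_ATP − μ_ADP − μ_Pi *to* the given fraction of nominal by moving
only the ATP chemostat concentration, leaving every rate constant
untouched.

With these defaults the model reproduces the expected signalling
phenomenology, which the test suite checks quantitatively: steady-state
activation curves are monotone sigmoids with effective Hill coefficients
(ln 81 / ln(u₉₀/u₁₀)) of ≈1.0, 1.6 and 3.4 for MAP3K, MAP2K and MAPK;
reducing the hydrolysis energy to 80% shifts every half-activation point to
larger inputs; positive feedback is bistable (two-direction sweeps find two
stable states differing by tens of percentage points of activation);
negative feedback lowers the output Hill coefficient.

## The glycolysis model

The ten-reaction pathway from G6P to PYR plus the gluconeogenic enzymes
fbp and pps. Reaction site lists (including cofactor participation: pfk
consumes ATP; gap consumes NAD + Pi and produces NADH + H; pgk and pyk
produce ATP; pps produces AMP + Pi + 2H) are a single machine-readable
table from which N is built. G6P, PYR, NAD, NADH, ATP, ADP, AMP, Pi, H and
H2O are chemostatted; S_i = {F6P, F16P, DHAP, GAP, 13DPG, 3PG, 2PG, PEP}
is the internal set. With fbp and pps absent the internal null space is
one-dimensional with pathway vector (pgi, pfk, fba, tpi, gap, pgk, gpm,
eno, pyk) = (1,1,1,1,2,2,2,2,2) and overall reaction
G6P + 3ADP + 2NAD + 2Pi ⇌ 2PYR + 3ATP + H + 2NADH + 2H2O.

Because the null-space machinery needs that one-dimensional structure, the
default build *omits* fbp and pps; `GlycolysisConfig(gluconeogenic=True)`
includes them with e₀ = 0 (settable), modelling enzyme-level switching of
the futile cycles.

### Synthetic reference parameterisation

The kinetic parameter set behind the original generalised-kinetics model is
not redistributable, so the module constructs a synthetic stand-in
calibrated to that model's published steady-state operating point: the
per-reaction affinity distribution (pgi 43.4, pfk 81.0, fba 14.6, tpi 8.4,
gap 51.5, pgk 23.9, gpm 13.5, eno 45.1, pyk 17.0 kJ/mol; weighted total
449.4). Given fixed boundary potentials the internal potential ladder is
solved exactly from these affinities; species constants follow from
millimolar-scale reference concentrations; every binding site sits at half
saturation; and κ̄ values are set so the reference state carries a pathway
flux of 0.1 mM/s — making it a steady state of the chemostatted network by
construction. Since K's are rebuilt from the same potential targets at any
temperature, the reported affinities are insensitive to the choice of T
(checked at 310.15 K and 298.15 K); concentrations and potentials are
synthetic, so only the affinity structure — not individual μ⁰ values —
should be read as meaningful.

### Calibration of simplified variants

* **Mass action**: per reaction, κ is set so the MA flux equals the
  reference flux at the reference state; species constants (hence all
  equilibrium constants) are untouched, so the reference state remains a
  steady state exactly.
* **Michaelis–Menten**: writing F = Πa_f and R = Πa_r, the binding
  constants are solved in closed form so that ∂v/∂ln x of the internal
  substrate and internal product match the reference law at the reference
  state, then κ̄ matches the flux exactly. fba (two internal products)
  cannot be matched exactly — the mean sensitivity is used and the
  reaction flagged in the calibration report; reaction sides with no
  internal species default to half saturation. For a one-substrate/
  one-product generalised-kinetics reaction this procedure recovers the
  original parameters exactly.

All three variants share N, moieties, pathway vector and the unperturbed
steady state; they differ only in flux response away from it. The
benchmark (+30% bumps of each internal species; prolonged +30% bumps of
each boundary species) reproduces the expected ordering: mass action,
lacking saturation, responds uniformly faster than generalised kinetics
and overshoots the downstream readout (PEP) more for upstream
perturbations, while Michaelis–Menten tracks generalised kinetics closely
for internal perturbations and drifts for boundary ones.

## Fixtures and serialisation

Random toy networks (chains, cycles, random pairings) are drawn directly
in thermodynamic parameter space (K, κ log-uniform), so they satisfy
detailed balance by construction regardless of topology; generation is
fully determined by the seed. Models serialise to a JSON dialect that
mirrors the in-memory structure (modules, children, bonds as port-path
pairs, exposed ports) and round-trips losslessly; validation errors carry
JSON-pointer locations.

## Numerical choices, problem sizes and limitations

* Default temperature T = 310.15 K (RT ≈ 2.579 kJ/mol); state is stored
  as concentration [M] with a 1 L compartment, so K carries M⁻¹; c⁰ = 1 M.
* Detailed-balance tolerance for kinetic sets: relative cycle-product
  deviation 1e-6. Steady-state residual criterion 1e-9 (relative);
  pathway-energetics steady-state guard 1e-6.
* Equilibrium at x = 1/K is exact up to one rounding of K·x (~1e-16
  relative), so "exact zero flux" assertions use absolute bounds of that
  order.
* Test problem sizes were chosen to probe the claims at modest cost:
  cascade input sweeps use 11–12 point logarithmic grids; bistability is
  probed at a single input inside the hysteresis window from both
  branches; the glycolysis benchmark covers all 8 internal species for all
  three rate-law variants. Larger grids sharpen the Hill-coefficient
  estimates but do not change any ordering.
* The synthetic data (fixtures and both exemplar parameter sets) capture
  thermodynamic structure, saturation and time-scale separation, but not
  measured kinetics: passing tests demonstrate the framework's internal
  consistency and the qualitative phenomenology, not quantitative
  agreement with experimental trajectories.
* Known limitations: no allosteric regulation (enzyme totals e₀ are the
  only regulatory handle); distributive double phosphorylation only; no
  scaffolds or receptor modules; single compartment; deterministic ODEs
  only; no SBML/CellML import or export (the JSON dialect documents its
  mapping to bond-graph concepts so exporters can be added).
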