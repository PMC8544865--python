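# bondbio

Modular, thermodynamically consistent biochemical modelling with bond
graphs.

Kinetic models assembled from published rate laws routinely violate the
second law: irreversible steps, rate constants that break detailed balance
around cycles, free energy appearing from nowhere. `bondbio` is for
modellers who want to compose reaction-network models from reusable parts
*without* being able to make that mistake. It represents a network as a
bond graph — a graph whose edges carry both a chemical potential μ [J/mol]
and a molar flux v [mol/s], so every connection transfers energy as well as
mass — and derives the ODEs from the network structure.

The core ideas:

* **Species** carry μ = RT ln(Kx): one thermodynamic constant K per
  species replaces paired forward/reverse rate constants, and any positive
  choice of parameters satisfies detailed balance automatically
  (Wegscheider conditions hold by construction).
* **Reactions** are driven by affinities A_f, A_r (summed reactant/product
  potentials) through interchangeable thermodynamically consistent rate
  laws — mass action v = κ(e^{A_f/RT} − e^{A_r/RT}), reversible
  Michaelis–Menten, or generalised (convenience-type) kinetics with one
  binding constant per site. Swapping a law never changes the
  stoichiometry.
* **Junctions** (common-potential ●, common-flow ▼) encode mass balance
  and affinity summation losslessly, so dissipation Σ A_j v_j ≥ 0 at every
  state.
* **Modules** with labelled exposed ports are composed hierarchically,
  instantiated repeatedly, and flattened to a single network from which
  the stoichiometric matrix, conserved moieties, ODEs and pathway
  energetics are derived.

Two worked model families ship with the package: a Mos/MAPK
phosphorylation cascade (five phosphorylation-cycle module instances plus
optional positive/negative feedback, with explicit ATP energetics) and a
glycolysis network with per-enzyme swappable rate laws, calibration of
simplified variants against a generalised-kinetics reference, a
perturbation benchmark, and steady-state pathway energetics. See
`docs/methods.md` for the science and the parameter provenance (both
parameter sets are synthetic, documented stand-ins).

## A worked example

Steady-state energetics of the glycolysis model (generalised kinetics,
gluconeogenic enzymes off):

```python
from bondbio import glycolysis

g = glycolysis.build_glycolysis()
rep = glycolysis.energetics_report(g)
print(rep.to_frame())
print(f"total (weighted sum) : {rep.total_weighted:.1f} kJ/mol")
print(f"total (chemostats)   : {rep.total_chemostat:.1f} kJ/mol")
```

prints

```
     weight  affinity_kJ_per_mol  contribution_kJ_per_mol
pgi       1                 43.4                     43.4
pfk       1                 81.0                     81.0
fba       1                 14.6                     14.6
tpi       1                  8.4                      8.4
gap       2                 51.5                    103.0
pgk       2                 23.9                     47.8
gpm       2                 13.5                     27.0
eno       2                 45.1                     90.2
pyk       2                 17.0                     34.0
total (weighted sum) : 449.4 kJ/mol
total (chemostats)   : 449.4 kJ/mol
```

The `weight` column is the steady-state pathway vector — the
one-dimensional right null space of the internal stoichiometric matrix —
meaning one pathway turn runs gap…pyk twice per pgi…tpi turn (the sugar
splits in two). Each reaction's affinity is its free-energy drop per mole
of flux at steady state; weighting by the pathway vector and summing gives
the total free energy dissipated per G6P consumed, 449.4 kJ/mol, and the
same number falls out of the chemostat potentials of the overall reaction
G6P + 3 ADP + 2 NAD + 2 Pi ⇌ 2 PYR + 3 ATP + H + 2 NADH + 2 H₂O — an
internal consistency check that the junction network loses no energy. The
net ATP row of that overall reaction, +3 per G6P, is the pathway's ATP
yield.

Signal–response analysis of the MAPK cascade:

```python
import numpy as np
from bondbio import mapk

grid = np.geomspace(1e-13, 1e-8, 11)   # input MAP4K concentration [M]
res = mapk.activation_analysis(input_grid=grid)
for level, curve in res["activation_percent"].items():
    print(f"{level}: effective Hill coefficient = "
          f"{mapk.hill_coefficient(grid, curve):.2f}")
```

prints

```
MAP3K: effective Hill coefficient = 1.03
MAP2K: effective Hill coefficient = 1.48
MAPK: effective Hill coefficient = 3.36
```

— the switch-like sharpening of the response down the cascade
(ultrasensitivity). `mapk.activation_analysis(..., atp_energy_fraction=0.8)`
re-runs the sweep with the ATP hydrolysis affinity clamped to 80% of
nominal (curves shift to larger inputs), and
`mapk.build_cascade(feedback="positive")` yields a bistable system whose
two branches are exposed by sweeping from inactive and active initial
states.

## Command line

```sh
bondbio energetics                                  # Table of pathway affinities
bondbio perturb --preset glycolysis-gk --species F6P --factor 1.3
bondbio odes --preset mapk-core                     # species + stoichiometry
bondbio simulate --preset glycolysis-ma --t-end 100 --output traj.tsv
bondbio preset mapk-positive-fb --output mapk.json  # serialise a model
bondbio fixture --seed 7 --output toy.json          # random consistent network
```

Presets: `mapk-core`, `mapk-positive-fb`, `mapk-negative-fb`,
`glycolysis-gk`, `glycolysis-mm`, `glycolysis-ma`. Tables are TSV with
`#key=value` metadata lines; concentrations in M, times in s, affinities
in kJ/mol.

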