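"""From a flattened bond graph to an explicit ODE system.

The central object is :class:`ReactionNetwork`: species (with thermodynamic
constants), reactions (with rate laws and per-site species lists), a
chemostat mask, and the machinery to evaluate fluxes and mass balances.

Equation assembly walks the flat graph: each reaction port is traced through
junctions to the species whose potentials it sees.  A ``"0"`` junction group
carries the potential of the single species attached to it; a ``"1"``
junction sums the potentials of all its other branches, so each branch
contributes one binding site.  Multiple bonds between a ``"1"`` junction and
a species' ``"0"`` junction encode stoichiometries greater than one.

Conserved moieties and steady-state pathway vectors are computed over the
rationals (sympy) and scaled to minimal integer vectors, so there is no
floating-point rank ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np
import sympy as sp

from .core import (
    BondGraphError,
    BondGraphModel,
    CompositeModule,
    Junction,
    Port,
    Reaction,
    Species,
    flatten,
)
from .ratelaws import RT_DEFAULT

__all__ = [
    "FlatReaction",
    "ReactionNetwork",
    "StoichiometricMatrix",
    "ODESystem",
    "PathwayDimensionError",
    "extract_network",
    "network_from_reactions",
    "build_stoichiometry",
    "assemble_odes",
    "conserved_moieties",
    "steady_state_pathway",
]


class PathwayDimensionError(BondGraphError):
    """The internal flux null space is not one-dimensional."""

    def __init__(self, dimension: int):
        self.dimension = dimension
        super().__init__(
            f"steady-state pathway requires a 1-dimensional internal null "
            f"space, got dimension {dimension}"
        )


@dataclass
class FlatReaction:
    """A reaction with resolved binding sites (one species name per site)."""

    name: str
    law: object
    forward: list[str]
    reverse: list[str]


@dataclass
class StoichiometricMatrix:
    """Signed integer incidence of species (rows) and reactions (columns)."""

    N: np.ndarray
    species: list[str]
    reactions: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.N, index=self.species, columns=self.reactions)


class ReactionNetwork:
    """A flat reaction network ready for simulation and analysis."""

    def __init__(
        self,
        species: list[str],
        K: dict[str, float],
        reactions: list[FlatReaction],
        chemostats: dict[str, float] | None = None,
        initial: dict[str, float] | None = None,
        RT: float = RT_DEFAULT,
    ):
        self.species = list(species)
        self.index = {s: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise BondGraphError("duplicate species names")
        self.K = np.array([K[s] for s in self.species], dtype=float)
        self.reactions = list(reactions)
        self.chemostats = dict(chemostats or {})
        for name in self.chemostats:
            if name not in self.index:
                raise BondGraphError(f"unknown chemostat species {name!r}")
            if self.chemostats[name] <= 0:
                raise ValueError(f"chemostat {name!r} must be held positive")
        self.initial = dict(initial or {})
        self.RT = float(RT)

        n_s, n_r = len(self.species), len(self.reactions)
        self.N = np.zeros((n_s, n_r), dtype=int)
        self._f_idx: list[np.ndarray] = []
        self._r_idx: list[np.ndarray] = []
        for j, rxn in enumerate(self.reactions):
            for s in rxn.forward:
                self.N[self.index[s], j] -= 1
            for s in rxn.reverse:
                self.N[self.index[s], j] += 1
            self._f_idx.append(np.array([self.index[s] for s in rxn.forward], dtype=int))
            self._r_idx.append(np.array([self.index[s] for s in rxn.reverse], dtype=int))
            if rxn.law is not None and hasattr(rxn.law, "_check_sites"):
                rxn.law._check_sites(len(rxn.forward), len(rxn.reverse))
        self.chemostat_mask = np.array(
            [s in self.chemostats for s in self.species], dtype=bool
        )

    # -- state helpers -------------------------------------------------

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    @property
    def internal_species(self) -> list[str]:
        return [s for s in self.species if s not in self.chemostats]

    def x0(self) -> np.ndarray:
        """Initial state: ``initial`` entries over chemostat defaults, else 0."""
        x = np.zeros(len(self.species))
        for name, value in self.chemostats.items():
            x[self.index[name]] = value
        for name, value in self.initial.items():
            if name not in self.index:
                raise BondGraphError(f"unknown species {name!r} in initial state")
            x[self.index[name]] = value
        return x

    def activities(self, x: np.ndarray) -> np.ndarray:
        return self.K * np.asarray(x, dtype=float)

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        a = self.activities(x)
        v = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            v[j] = rxn.law.flux(a[self._f_idx[j]], a[self._r_idx[j]])
        return v

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """dx/dt = N v(x) with chemostat rows forced to zero."""
        dx = self.N @ self.fluxes(x)
        dx[self.chemostat_mask] = 0.0
        return dx

    def residual(self, x: np.ndarray, floor: float = 1e-12) -> float:
        """max_s |dx_s/dt| / max(x_s, floor) over non-chemostat species."""
        dx = self.rhs(x)
        scale = np.maximum(np.asarray(x, dtype=float), floor)
        r = np.abs(dx) / scale
        return float(np.max(r[~self.chemostat_mask], initial=0.0))

    # -- structure -----------------------------------------------------

    def stoichiometry(self) -> StoichiometricMatrix:
        return StoichiometricMatrix(self.N.copy(), list(self.species), self.reaction_names)

    def conserved_moieties(self) -> list[np.ndarray]:
        return conserved_moieties(self.N, self.chemostat_mask)

    def steady_state_pathway(self) -> np.ndarray:
        return steady_state_pathway(self.N, self.chemostat_mask)

    def with_laws(self, laws: dict[str, object]) -> "ReactionNetwork":
        """Copy of the network with some rate laws replaced (same structure)."""
        new_reactions = [
            FlatReaction(
                r.name,
                laws.get(r.name, r.law).copy() if hasattr(laws.get(r.name, r.law), "copy")
                else laws.get(r.name, r.law),
                list(r.forward),
                list(r.reverse),
            )
            for r in self.reactions
        ]
        return ReactionNetwork(
            self.species,
            dict(zip(self.species, self.K)),
            new_reactions,
            chemostats=dict(self.chemostats),
            initial=dict(self.initial),
            RT=self.RT,
        )

    def with_chemostats(self, values: dict[str, float]) -> "ReactionNetwork":
        chemo = dict(self.chemostats)
        for name, value in values.items():
            if name not in chemo:
                raise BondGraphError(f"{name!r} is not a chemostat")
            chemo[name] = value
        net = self.with_laws({})
        net.chemostats = chemo
        return net


@dataclass
class ODESystem:
    """Explicit ODE view of a network: dx/dt = M o (N v(x))."""

    network: ReactionNetwork
    species: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.species = list(self.network.species)

    @property
    def N(self) -> np.ndarray:
        return self.network.N

    @property
    def chemostat_mask(self) -> np.ndarray:
        return self.network.chemostat_mask

    def flux(self, x: np.ndarray) -> np.ndarray:
        return self.network.fluxes(x)

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.network.rhs(x)


# -- graph -> network ----------------------------------------------------


class _UnionFind:
    def __init__(self):
        self.parent: dict[int, int] = {}
        self.obj: dict[int, object] = {}

    def add(self, o: object) -> None:
        i = id(o)
        if i not in self.parent:
            self.parent[i] = i
            self.obj[i] = o

    def find(self, o: object) -> int:
        i = id(o)
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: object, b: object) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def extract_network(model: BondGraphModel | CompositeModule) -> ReactionNetwork:
    """Flatten a model and assemble its reaction network."""
    if isinstance(model, BondGraphModel):
        flat = model.flat()
        chemostats = model.chemostats
        initial = model.initial
        RT = model.RT
    else:
        flat = flatten(model)
        chemostats, initial, RT = {}, {}, RT_DEFAULT

    names: dict[int, str] = {id(c): path for path, c in flat.children.items()}
    species = [c for c in flat.children.values() if isinstance(c, Species)]
    reactions = [c for c in flat.children.values() if isinstance(c, Reaction)]

    # group 0-junctions and species into common-potential nodes
    uf = _UnionFind()
    for c in flat.children.values():
        if isinstance(c, Species) or (isinstance(c, Junction) and c.kind == "0"):
            uf.add(c)
    for bond in flat.bonds:
        ca, cb = bond.tail.component, bond.head.component
        mergeable = lambda c: isinstance(c, Species) or (
            isinstance(c, Junction) and c.kind == "0"
        )
        if mergeable(ca) and mergeable(cb):
            uf.union(ca, cb)
    group_species: dict[int, Species] = {}
    for c in flat.children.values():
        if isinstance(c, Species):
            root = uf.find(c)
            if root in group_species and group_species[root] is not c:
                raise BondGraphError(
                    f"species {names[id(group_species[root])]} and {names[id(c)]} "
                    f"share a common-potential node"
                )
            group_species[root] = c

    def sites_from(port: Port, seen: frozenset[int] = frozenset()) -> list[Species]:
        other = port.other_end()
        comp = other.component
        if isinstance(comp, Species):
            return [comp]
        if isinstance(comp, Junction) and comp.kind == "0":
            root = uf.find(comp)
            if root not in group_species:
                raise BondGraphError(
                    f"junction {names[id(comp)]} is not attached to any species"
                )
            return [group_species[root]]
        if isinstance(comp, Junction) and comp.kind == "1":
            if id(comp) in seen:
                raise BondGraphError(f"cycle of 1-junctions at {names[id(comp)]}")
            out: list[Species] = []
            for q in comp.ports.values():
                if q is other:
                    continue
                out.extend(sites_from(q, seen | {id(comp)}))
            return out
        raise BondGraphError(
            f"reaction port wired to unsupported component {names.get(id(comp), '?')}"
        )

    flat_reactions: list[FlatReaction] = []
    for r in reactions:
        f_sites = [names[id(s)] for s in sites_from(r.port("f"))]
        r_sites = [names[id(s)] for s in sites_from(r.port("r"))]
        flat_reactions.append(FlatReaction(names[id(r)], r.law, f_sites, r_sites))

    species_names = [names[id(s)] for s in species]
    K = {names[id(s)]: s.K for s in species}
    return ReactionNetwork(
        species_names, K, flat_reactions, chemostats=chemostats, initial=initial, RT=RT
    )


def network_from_reactions(
    name: str,
    species: dict[str, float],
    reactions: dict[str, tuple],
) -> CompositeModule:
    """Build a single-module bond graph from reaction site lists.

    ``species`` maps names to thermodynamic constants K; ``reactions`` maps
    names to ``(law, forward_sites, reverse_sites)`` with one species name
    per binding site (repeat a name for stoichiometry > 1).  Every species
    gets a common-potential (0) junction; reaction sides with several sites
    get a common-flow (1) junction summing the site potentials.
    """
    mod = CompositeModule(name)
    for sname, Kval in species.items():
        mod.add(Species(sname, K=Kval))
        mod.add(Junction(f"j_{sname}", "0"))
        mod.connect(sname, f"j_{sname}")
    for rname, (law, f_sites, r_sites) in reactions.items():
        rxn = mod.add(Reaction(rname, law))
        for port_label, sites in (("f", f_sites), ("r", r_sites)):
            for s in sites:
                if s not in species:
                    raise BondGraphError(f"reaction {rname}: unknown species {s!r}")
            if len(sites) == 1:
                mod.connect(f"j_{sites[0]}", f"{rname}.{port_label}")
            else:
                j1 = mod.add(Junction(f"j1_{rname}_{port_label}", "1"))
                for s in sites:
                    mod.connect(f"j_{s}", j1.new_port())
                mod.connect(j1.new_port(), f"{rname}.{port_label}")
    return mod


# -- stoichiometric analysis --------------------------------------------


def build_stoichiometry(network: ReactionNetwork) -> StoichiometricMatrix:
    return network.stoichiometry()


def assemble_odes(network: ReactionNetwork) -> ODESystem:
    return ODESystem(network)


def _minimal_integer(vec: list[Fraction]) -> np.ndarray:
    denoms = [f.denominator for f in vec]
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [int(f * lcm) for f in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    for v in ints:
        if v != 0:
            if v < 0:
                ints = [-w for w in ints]
            break
    return np.array(ints, dtype=int)


def _rational_nullspace(M: np.ndarray) -> list[np.ndarray]:
    """Minimal-integer basis of the (right) null space, exact arithmetic."""
    M = np.asarray(M)
    mat = sp.Matrix(M.shape[0], M.shape[1], [int(v) for v in M.flatten()])
    basis = mat.nullspace()
    out = []
    for b in basis:
        fracs = [Fraction(sp.Rational(v).p, sp.Rational(v).q) for v in b]
        out.append(_minimal_integer(fracs))
    return out


def conserved_moieties(N: np.ndarray, chemostat_mask: np.ndarray) -> list[np.ndarray]:
    """Integer basis of the left null space of the non-chemostat rows of N.

    Each vector g satisfies g^T N_internal = 0: the weighted total g^T x over
    internal species is constant along every trajectory.  Vectors are
    ordered canonically (sympy nullspace over rows in declaration order).
    """
    internal = ~np.asarray(chemostat_mask, dtype=bool)
    N_int = np.asarray(N)[internal, :]
    basis = _rational_nullspace(N_int.T)
    full = []
    for g in basis:
        v = np.zeros(N.shape[0], dtype=int)
        v[internal] = g
        full.append(v)
    return full


def steady_state_pathway(N: np.ndarray, chemostat_mask: np.ndarray) -> np.ndarray:
    """Integer flux pattern spanning the internal steady-state null space.

    The non-chemostat rows of N must have a one-dimensional right null
    space; the basis vector is scaled to minimal integers with its first
    nonzero entry (in reaction declaration order) positive.
    """
    internal = ~np.asarray(chemostat_mask, dtype=bool)
    basis = _rational_nullspace(np.asarray(N)[internal, :])
    if len(basis) != 1:
        raise PathwayDimensionError(len(basis))
    return basis[0]
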