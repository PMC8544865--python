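"""Kinetic <-> thermodynamic parameter conversion, affinities and energetics.

A mass-action reaction can be parameterised either kinetically (forward and
reverse rate constants k+, k-) or thermodynamically (one rate constant kappa
per reaction plus one constant K per species, with k+ = kappa * prod_f K_s
and k- = kappa * prod_r K_p).  Thermodynamic parameters can be chosen freely;
kinetic parameters must satisfy the Wegscheider (detailed-balance)
conditions -- the product of equilibrium constants around every reaction
cycle equals one -- before a thermodynamic equivalent exists.

This module also computes per-reaction affinities at a state, steady-state
pathway energetics (total affinity both as a stoichiometry-weighted sum of
member reaction affinities and as a combination of chemostat potentials),
and the instantaneous dissipation sum_j A_j v_j >= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BondGraphError
from .network import ReactionNetwork, _rational_nullspace
from .ratelaws import MassAction

__all__ = [
    "DetailedBalanceError",
    "thermo_to_kinetic",
    "kinetic_to_thermo",
    "reaction_affinities",
    "PathwayEnergetics",
    "pathway_energetics",
    "dissipation",
]


class DetailedBalanceError(BondGraphError):
    """A kinetic parameter set violates the Wegscheider conditions."""

    def __init__(self, cycle: dict[str, int], ratio: float):
        self.cycle = cycle
        self.ratio = ratio
        desc = " ".join(f"{c:+d}*{r}" for r, c in cycle.items())
        super().__init__(
            f"detailed balance violated around cycle [{desc}]: "
            f"equilibrium-constant product is {ratio:.6g}, expected 1"
        )


def thermo_to_kinetic(network: ReactionNetwork) -> pd.DataFrame:
    """Mass-action rate constants induced by the thermodynamic parameters.

    k+_j = kappa_j * prod(forward-site K), k-_j = kappa_j * prod(reverse-site
    K).  The result satisfies detailed balance by construction.  Requires
    every reaction to carry a mass-action law.
    """
    rows = {}
    for j, rxn in enumerate(network.reactions):
        if not isinstance(rxn.law, MassAction):
            raise BondGraphError(
                f"reaction {rxn.name} does not use mass action kinetics"
            )
        kf = rxn.law.kappa * float(np.prod(network.K[network._f_idx[j]]))
        kr = rxn.law.kappa * float(np.prod(network.K[network._r_idx[j]]))
        rows[rxn.name] = (kf, kr)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["k_plus", "k_minus"])


def _wegscheider_check(network: ReactionNetwork, ln_keq: np.ndarray, tol: float) -> None:
    cycles = _rational_nullspace(network.N)
    for c in cycles:
        mismatch = float(c @ ln_keq)
        if abs(mismatch) > tol:
            cycle = {
                network.reactions[j].name: int(c[j]) for j in range(len(c)) if c[j] != 0
            }
            raise DetailedBalanceError(cycle, math.exp(mismatch))


def kinetic_to_thermo(
    k_plus: dict[str, float],
    k_minus: dict[str, float],
    network: ReactionNetwork,
    fix: dict[str, float] | None = None,
    tol: float = 1e-6,
) -> tuple[dict[str, float], dict[str, float]]:
    """Recover (K, kappa) reproducing the given mass-action rate constants.

    Feasible iff ln(k+/k-) lies in the row space of N^T, i.e. the
    Wegscheider conditions hold to within ``tol`` (relative cycle-product
    deviation); otherwise :class:`DetailedBalanceError` reports a violating
    cycle and its mismatch ratio.

    The map has one gauge freedom per conserved moiety of the full network.
    ``fix`` pins designated species constants (``{name: K}``); by default the
    first species of each moiety basis vector is pinned to K = 1.
    """
    names = network.reaction_names
    kf = np.array([k_plus[n] for n in names], dtype=float)
    kr = np.array([k_minus[n] for n in names], dtype=float)
    if np.any(kf <= 0) or np.any(kr <= 0):
        raise ValueError("rate constants must be positive")
    _wegscheider_check(network, np.log(kf / kr), tol)

    n_r, n_s = len(names), len(network.species)
    if fix is None:
        no_chemo = np.zeros(n_s, dtype=bool)  # gauge over the full network
        from .network import conserved_moieties

        fix = {}
        for g in conserved_moieties(network.N, no_chemo):
            pivot = int(np.nonzero(g)[0][0])
            fix[network.species[pivot]] = 1.0

    # unknowns y = [ln kappa (n_r) ; ln K (n_s)]
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for j in range(n_r):
        for idx, k in ((network._f_idx[j], kf[j]), (network._r_idx[j], kr[j])):
            row = np.zeros(n_r + n_s)
            row[j] = 1.0
            for i in idx:
                row[n_r + i] += 1.0
            rows.append(row)
            rhs.append(math.log(k))
    for sname, Kval in fix.items():
        row = np.zeros(n_r + n_s)
        row[n_r + network.index[sname]] = 1.0
        rows.append(row)
        rhs.append(math.log(Kval))
    A = np.vstack(rows)
    b = np.array(rhs)
    y, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.max(np.abs(A @ y - b)) > 1e-8:
        raise BondGraphError(
            "kinetic parameters are inconsistent with the supplied gauge"
        )
    kappa = {n: math.exp(y[j]) for j, n in enumerate(names)}
    K = {s: math.exp(y[n_r + i]) for i, s in enumerate(network.species)}
    return K, kappa


def reaction_affinities(
    network: ReactionNetwork, x: np.ndarray, kJ: bool = False
) -> pd.DataFrame:
    """Forward/reverse/net affinity of every reaction at a positive state.

    Af (Ar) is the sum of reactant (product) chemical potentials; the net
    affinity A = Af - Ar is the thermodynamic driving force.  Units are
    J/mol, or kJ/mol with ``kJ=True``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        bad = [network.species[i] for i in np.nonzero(x <= 0)[0]]
        raise ValueError(f"affinities undefined at nonpositive state for {bad}")
    mu = network.RT * np.log(network.activities(x))
    scale = 1e-3 if kJ else 1.0
    rows = {}
    for j, rxn in enumerate(network.reactions):
        Af = float(np.sum(mu[network._f_idx[j]]))
        Ar = float(np.sum(mu[network._r_idx[j]]))
        rows[rxn.name] = (Af * scale, Ar * scale, (Af - Ar) * scale)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["Af", "Ar", "A"])


@dataclass
class PathwayEnergetics:
    """Steady-state energetics of a pathway through a chemostatted network."""

    pathway: pd.Series  # integer weight per reaction
    affinities: pd.Series  # net affinity per reaction [kJ/mol]
    overall: pd.Series  # net chemostat stoichiometry of the summed reaction
    total_weighted: float  # sum_j w_j A_j [kJ/mol]
    total_chemostat: float  # from chemostat potentials [kJ/mol]

    @property
    def total(self) -> float:
        return self.total_weighted

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"weight": self.pathway, "affinity_kJ_per_mol": self.affinities}
        )
        df["contribution_kJ_per_mol"] = df["weight"] * df["affinity_kJ_per_mol"]
        return df


def pathway_energetics(
    network: ReactionNetwork,
    pathway: np.ndarray,
    x: np.ndarray,
    residual_tol: float = 1e-6,
) -> PathwayEnergetics:
    """Per-reaction and total pathway affinity at a steady state.

    The total is computed two independent ways -- as the weighted sum of
    member reaction affinities and from the chemostat potentials via the
    overall reaction N w -- and both are reported.  ``x`` must be a steady
    state of the chemostatted system (relative residual below
    ``residual_tol``).
    """
    w = np.asarray(pathway)
    if network.residual(x) > residual_tol:
        raise BondGraphError(
            f"state is not at steady state (residual {network.residual(x):.3g} "
            f"> {residual_tol:.3g})"
        )
    aff = reaction_affinities(network, x, kJ=True)["A"]
    total_weighted = float(w @ aff.to_numpy())

    net = network.N @ w  # internal rows are zero for a pathway vector
    mu = network.RT * np.log(network.activities(np.asarray(x, dtype=float)))
    chemo = network.chemostat_mask
    total_chemostat = -float(net[chemo] @ mu[chemo]) * 1e-3
    overall = pd.Series(
        {network.species[i]: int(net[i]) for i in np.nonzero(net)[0]}
    )
    return PathwayEnergetics(
        pathway=pd.Series(w, index=network.reaction_names),
        affinities=aff,
        overall=overall,
        total_weighted=total_weighted,
        total_chemostat=total_chemostat,
    )


def dissipation(network: ReactionNetwork, x: np.ndarray) -> float:
    """Instantaneous dissipation sum_j A_j v_j [J/s].

    Non-negative for every thermodynamically consistent rate law; zero iff
    every reaction is at equilibrium.
    """
    aff = reaction_affinities(network, x)["A"].to_numpy()
    v = network.fluxes(x)
    return float(aff @ v)
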