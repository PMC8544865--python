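"""Constitutive relations: species potentials and reaction rate laws.

All rate laws here are *thermodynamically consistent*: the flux is zero
exactly when the forward and reverse affinities balance, and the flux always
runs down the affinity gradient, so the dissipation A*v is non-negative at
every state.

Internally fluxes are evaluated in *amount space*: the Boltzmann factor
exp(mu/RT) of a species equals its dimensionless thermodynamic activity
a = K*x, so exp(Af/RT) is computed as a product of activities rather than
via logarithms.  This keeps x = 0 well-defined (no -inf potentials) and is
why mass-action bond-graph models reduce to polynomial ODEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

R_GAS = 8.314  # J K^-1 mol^-1
T_DEFAULT = 310.15  # K; physiological temperature
RT_DEFAULT = R_GAS * T_DEFAULT  # ~2578.6 J/mol

__all__ = [
    "R_GAS",
    "T_DEFAULT",
    "RT_DEFAULT",
    "K_from_mu0",
    "mu0_from_K",
    "chemical_potential",
    "RateLaw",
    "MassAction",
    "MichaelisMenten",
    "GeneralisedKinetics",
    "flux_mass_action",
    "flux_michaelis_menten",
    "flux_generalised_kinetics",
]


def K_from_mu0(mu0: float, RT: float = RT_DEFAULT, V: float = 1.0, c0: float = 1.0) -> float:
    """Thermodynamic constant from a standard potential.

    K = exp(mu0/RT) / (c0 V), where mu0 [J/mol] is the standard chemical
    potential at reference concentration c0 [M] (1 M by default) and V [L]
    is the compartment volume.
    """
    if RT <= 0 or V <= 0 or c0 <= 0:
        raise ValueError("RT, V and c0 must be positive")
    return math.exp(mu0 / RT) / (c0 * V)


def mu0_from_K(K: float, RT: float = RT_DEFAULT, V: float = 1.0, c0: float = 1.0) -> float:
    if K <= 0:
        raise ValueError("K must be positive")
    return RT * math.log(K * c0 * V)


def chemical_potential(K: float, x: float, RT: float = RT_DEFAULT) -> float:
    """mu = RT ln(K x)  [J/mol].

    Strictly increasing in x; undefined at x <= 0 (callers that must handle
    empty pools should work with activity products instead of potentials).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if x <= 0:
        raise ValueError(f"chemical potential undefined for x = {x} <= 0")
    return RT * math.log(K * x)


class RateLaw:
    """Base class: maps per-site activities to a molar flux."""

    def flux(self, af: Sequence[float], ar: Sequence[float]) -> float:
        """Flux given forward- and reverse-side activities (one per site)."""
        raise NotImplementedError

    def parameters(self) -> dict:
        raise NotImplementedError

    def copy(self) -> "RateLaw":
        import copy as _copy

        return _copy.deepcopy(self)

    def _check_sites(self, n_f: int, n_r: int) -> None:
        """Hook: laws with per-site parameters validate the site count."""


def _positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass
class MassAction(RateLaw):
    """Reversible mass action (Marcelin-de Donder form).

    v = kappa * [exp(Af/RT) - exp(Ar/RT)] = kappa * (prod_f a_s - prod_r a_p).
    """

    kappa: float

    def __post_init__(self) -> None:
        _positive(kappa=self.kappa)

    def flux(self, af, ar) -> float:
        return self.kappa * (float(np.prod(af)) - float(np.prod(ar)))

    def parameters(self) -> dict:
        return {"kappa": self.kappa}


@dataclass
class MichaelisMenten(RateLaw):
    """Reversible Michaelis-Menten kinetics.

    v = kbar e0 (aS - aP) / (1 + aS/Rb0 + aP/Rb1)

    with rate constant kbar [1/s], total enzyme e0, and dimensionless binding
    constants Rb0 (substrate) and Rb1 (product).  For reactions with several
    species per side the activities are lumped into their product, i.e. the
    law saturates in the *total* forward/reverse Boltzmann factor; this is
    exact for 1-substrate/1-product reactions and is how chemostatted
    co-substrates are folded in when simplifying a detailed model.
    """

    kbar: float
    e0: float
    Rb0: float
    Rb1: float

    def __post_init__(self) -> None:
        _positive(kbar=self.kbar, Rb0=self.Rb0, Rb1=self.Rb1)
        if self.e0 < 0:
            raise ValueError(f"e0 must be non-negative, got {self.e0}")

    def flux(self, af, ar) -> float:
        F = float(np.prod(af))
        R = float(np.prod(ar))
        return self.kbar * self.e0 * (F - R) / (1.0 + F / self.Rb0 + R / self.Rb1)

    def parameters(self) -> dict:
        return {"kbar": self.kbar, "e0": self.e0, "Rb0": self.Rb0, "Rb1": self.Rb1}


@dataclass
class GeneralisedKinetics(RateLaw):
    """Generalised (convenience-type) kinetics with one binding constant per site.

    v = kbar e0 (prod_f a_s - prod_r a_p)
        / ( -1 + prod_f (1 + a_s/Rb_s) + prod_r (1 + a_p/Rb_p) )

    Species with stoichiometry n contribute n sites, each with its own
    binding constant.  When every stoichiometry is one this coincides with
    convenience kinetics, and with exactly one substrate and one product it
    reduces algebraically to :class:`MichaelisMenten`
    (-1 + (1+a) + (1+b) = 1 + a + b).
    """

    kbar: float
    e0: float
    Rb_f: tuple[float, ...]
    Rb_r: tuple[float, ...]

    def __post_init__(self) -> None:
        _positive(kbar=self.kbar)
        if self.e0 < 0:
            raise ValueError(f"e0 must be non-negative, got {self.e0}")
        self.Rb_f = tuple(self.Rb_f)
        self.Rb_r = tuple(self.Rb_r)
        for rb in (*self.Rb_f, *self.Rb_r):
            _positive(Rb=rb)

    def _check_sites(self, n_f: int, n_r: int) -> None:
        if (len(self.Rb_f), len(self.Rb_r)) != (n_f, n_r):
            raise ValueError(
                f"binding-site count mismatch: law has "
                f"{len(self.Rb_f)}/{len(self.Rb_r)} Rb parameters but the "
                f"reaction has {n_f}/{n_r} sites"
            )

    def flux(self, af, ar) -> float:
        af = np.asarray(af, dtype=float)
        ar = np.asarray(ar, dtype=float)
        if len(af) != len(self.Rb_f) or len(ar) != len(self.Rb_r):
            raise ValueError("site/parameter count mismatch")
        F = float(np.prod(af))
        R = float(np.prod(ar))
        denom = (
            -1.0
            + float(np.prod(1.0 + af / np.asarray(self.Rb_f)))
            + float(np.prod(1.0 + ar / np.asarray(self.Rb_r)))
        )
        return self.kbar * self.e0 * (F - R) / denom

    def parameters(self) -> dict:
        return {
            "kbar": self.kbar,
            "e0": self.e0,
            "Rb_f": self.Rb_f,
            "Rb_r": self.Rb_r,
        }


# -- potential-space wrappers -------------------------------------------


def flux_mass_action(law: MassAction, Af: float, Ar: float, RT: float = RT_DEFAULT) -> float:
    """v = kappa (e^{Af/RT} - e^{Ar/RT}); sign(v) = sign(Af - Ar)."""
    return law.flux([math.exp(Af / RT)], [math.exp(Ar / RT)])


def flux_michaelis_menten(
    law: MichaelisMenten, muS: float, muP: float, RT: float = RT_DEFAULT
) -> float:
    return law.flux([math.exp(muS / RT)], [math.exp(muP / RT)])


def flux_generalised_kinetics(
    law: GeneralisedKinetics,
    mu_f: Sequence[float],
    mu_r: Sequence[float],
    RT: float = RT_DEFAULT,
) -> float:
    """Flux from per-site potentials; Af = sum(mu_f), Ar = sum(mu_r)."""
    return law.flux(
        [math.exp(m / RT) for m in mu_f], [math.exp(m / RT) for m in mu_r]
    )
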