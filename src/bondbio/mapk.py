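"""Hierarchical bond-graph model of a Mos/MAPK phosphorylation cascade.

The cascade (as in *Xenopus* oocytes) is three levels of phosphorylation
cycles: the input kinase MAP4K phosphorylates MAP3K; MAP3KP doubly
phosphorylates MAP2K; MAP2KPP doubly phosphorylates MAPK.  Each level is
balanced by a phosphatase, so every cycle hydrolyses one ATP per turn --
the energy of ATP hydrolysis is what holds the cascade away from
equilibrium and makes switch-like (ultrasensitive) responses possible.

The model is assembled from generic kinase and phosphatase modules
(two-state mechanisms with explicit enzyme-substrate complexes, as in the
Huang-Ferrell formulation, but fully reversible and with explicit ATP/ADP/Pi
energetics), combined into a phosphorylation-cycle module that is
instantiated five times (1 + 2 + 2; double phosphorylation is distributive).
Feedback variants add a sixth cycle acting on the input: MAPKPP
phosphorylates MAP4K, and whether the phosphorylated form is the *active*
input (positive feedback) or the *inactive* one (negative feedback) is set
purely by which cycle port each species connects to.

Parameterisation
----------------
Kinetic targets follow Huang and Ferrell: effective on-rate 1e9 /M/s,
complex dissociation 150 /s, catalytic step 150 /s (Km = 300 nM), made
reversible through the thermodynamic parameterisation.  Each
phosphorylation raises the substrate's thermodynamic constant by a factor
of 1e4, and the ATP/ADP/Pi clamp contributes an activity ratio of 1e8, so
each half of a cycle is driven by half of the ~47 kJ/mol hydrolysis
affinity (RT ln 1e8 at 310 K).  Concentrations follow the cascade's
standard operating point: 3 nM MAP3K, 1.2 uM MAP2K and MAPK, phosphatases
at 0.3 nM / 0.3 nM / 0.12 uM, with the input MAP4K around 0.03 nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BondGraphModel, CompositeModule, Junction, Reaction, Species
from .network import ReactionNetwork
from .ratelaws import MassAction, RT_DEFAULT
from .simulate import find_steady_state, signal_response_curve

__all__ = [
    "EnzymeKinetics",
    "CascadeConfig",
    "build_kinase_module",
    "build_phosphatase_module",
    "build_cycle",
    "build_cascade",
    "activation_analysis",
    "hill_coefficient",
    "ACTIVE_FORMS",
]

# nominal chemostat clamp: dimensionless activities a = K*x of the cofactors.
# a_ATP/(a_ADP*a_Pi) = 1e8 puts ~18.4 RT (~47 kJ/mol at 310 K) across each
# phosphorylation/dephosphorylation cycle.
ACT_ATP = 1e8
ACT_ADP = 1.0
ACT_PI = 1.0
X_ATP = 1e-3  # M
X_ADP = 1e-4
X_PI = 1e-3

# thermodynamic constant ratio per attached phosphate: splits the hydrolysis
# affinity evenly between the kinase and phosphatase legs of a cycle
PHOS_FACTOR = 1e4

ACTIVE_FORMS = {"MAP3K": "MAP3KP", "MAP2K": "MAP2KPP", "MAPK": "MAPKPP"}


@dataclass
class EnzymeKinetics:
    """Target kinetics of one enzymatic step (Huang-Ferrell-like)."""

    a: float = 1e9  # effective on-rate [/M/s]
    d: float = 150.0  # complex dissociation [/s]
    k: float = 150.0  # catalytic step [/s]

    @property
    def Km(self) -> float:
        return (self.d + self.k) / self.a


@dataclass
class CascadeConfig:
    """Concentrations [M] and kinetic targets for the cascade."""

    x_MAP4K: float = 3e-11
    x_MAP3K: float = 3e-9
    x_MAP2K: float = 1.2e-6
    x_MAPK: float = 1.2e-6
    x_MAP3K_Pase: float = 3e-10
    x_MAP2K_Pase: float = 3e-10
    x_MAPK_Pase: float = 1.2e-7
    x_FB_Pase: float = 3e-10  # feedback phosphatase (feedback variants only)
    kinase_kinetics: EnzymeKinetics = field(default_factory=EnzymeKinetics)
    phosphatase_kinetics: EnzymeKinetics = field(default_factory=EnzymeKinetics)
    atp_energy_fraction: float = 1.0  # scales mu_ATP - mu_ADP - mu_Pi
    RT: float = RT_DEFAULT


def build_kinase_module(
    kappa1: float, kappa2: float, K_C: float, name: str = "kinase"
) -> CompositeModule:
    """Two-state kinase: E + X + ATP <-> C <-> E + XP + ADP.

    Exposes ports (E, X, XP, ATP, ADP); contains one complex species and two
    mass-action reactions.
    """
    m = CompositeModule(name)
    m.add(Species("C", K=K_C))
    m.add(Reaction("r1", MassAction(kappa1)))
    m.add(Reaction("r2", MassAction(kappa2)))
    for label in ("E", "X", "XP", "ATP", "ADP", "C"):
        m.add(Junction(f"j{label}", "0"))
    m.add(Junction("jf", "1"))
    m.add(Junction("jr", "1"))
    m.connect("jE", "jf")
    m.connect("jX", "jf")
    m.connect("jATP", "jf")
    m.connect("jf", "r1.f")
    m.connect("r1.r", "jC")
    m.connect("C", "jC")
    m.connect("jC", "r2.f")
    m.connect("r2.r", "jr")
    m.connect("jr", "jE")
    m.connect("jr", "jXP")
    m.connect("jr", "jADP")
    for label in ("E", "X", "XP", "ATP", "ADP"):
        m.expose(f"j{label}", label)
    return m


def build_phosphatase_module(
    kappa1: float, kappa2: float, K_C: float, name: str = "phosphatase"
) -> CompositeModule:
    """Two-state phosphatase: E + XP <-> C <-> E + X + Pi; ports (E, X, XP, Pi)."""
    m = CompositeModule(name)
    m.add(Species("C", K=K_C))
    m.add(Reaction("r1", MassAction(kappa1)))
    m.add(Reaction("r2", MassAction(kappa2)))
    for label in ("E", "X", "XP", "Pi", "C"):
        m.add(Junction(f"j{label}", "0"))
    m.add(Junction("jf", "1"))
    m.add(Junction("jr", "1"))
    m.connect("jE", "jf")
    m.connect("jXP", "jf")
    m.connect("jf", "r1.f")
    m.connect("r1.r", "jC")
    m.connect("C", "jC")
    m.connect("jC", "r2.f")
    m.connect("r2.r", "jr")
    m.connect("jr", "jE")
    m.connect("jr", "jX")
    m.connect("jr", "jPi")
    for label in ("E", "X", "XP", "Pi"):
        m.expose(f"j{label}", label)
    return m


def build_cycle(
    kinase: CompositeModule, phosphatase: CompositeModule, name: str = "cycle"
) -> CompositeModule:
    """Phosphorylation cycle: kinase + phosphatase sharing X/XP mass balance.

    X and XP are linked through common-potential junctions (conservation of
    mass); all other ports stay exposed so enzymes and cofactors can be
    shared across the full cascade: (E_kin, E_pho, X, XP, ATP, ADP, Pi).
    """
    m = CompositeModule(name)
    m.add(kinase, "kinase")
    m.add(phosphatase, "phosphatase")
    m.add(Junction("jX", "0"))
    m.add(Junction("jXP", "0"))
    m.connect("kinase.X", "jX")
    m.connect("phosphatase.X", "jX")
    m.connect("kinase.XP", "jXP")
    m.connect("phosphatase.XP", "jXP")
    m.expose("jX", "X")
    m.expose("jXP", "XP")
    m.expose("kinase.E", "E_kin")
    m.expose("phosphatase.E", "E_pho")
    m.expose("kinase.ATP", "ATP")
    m.expose("kinase.ADP", "ADP")
    m.expose("phosphatase.Pi", "Pi")
    return m


def _cycle_for(
    K: dict[str, float],
    E_kin: str,
    X: str,
    XP: str,
    E_pho: str,
    kin: EnzymeKinetics,
    pho: EnzymeKinetics,
    act_ATP: float,
    name: str,
) -> CompositeModule:
    """Instantiate a cycle whose mass-action constants hit the kinetic targets."""
    kappa1 = kin.a / (K[E_kin] * K[X] * act_ATP)
    K_C = kin.d / kappa1
    kappa2 = kin.k / K_C
    kinase = build_kinase_module(kappa1, kappa2, K_C)
    kappa1p = pho.a / (K[E_pho] * K[XP])
    K_Cp = pho.d / kappa1p
    kappa2p = pho.k / K_Cp
    phosphatase = build_phosphatase_module(kappa1p, kappa2p, K_Cp)
    return build_cycle(kinase, phosphatase, name=name)


def build_cascade(
    config: CascadeConfig | None = None, feedback: str = "none"
) -> BondGraphModel:
    """Assemble the full cascade model; ``feedback`` in {none, positive, negative}.

    Positive and negative feedback differ *only* in which cycle port
    (X or XP) the active input MAP4K connects to.
    """
    cfg = config or CascadeConfig()
    if feedback not in ("none", "positive", "negative"):
        raise ValueError(f"unknown feedback mode {feedback!r}")
    f = cfg.atp_energy_fraction
    if not 0 < f <= 1:
        raise ValueError("atp_energy_fraction must be in (0, 1]")

    K: dict[str, float] = {
        "MAP4K": 1.0,
        "MAP3K": 1.0,
        "MAP3KP": PHOS_FACTOR,
        "MAP2K": 1.0,
        "MAP2KP": PHOS_FACTOR,
        "MAP2KPP": PHOS_FACTOR**2,
        "MAPK": 1.0,
        "MAPKP": PHOS_FACTOR,
        "MAPKPP": PHOS_FACTOR**2,
        "MAP3K_Pase": 1.0,
        "MAP2K_Pase": 1.0,
        "MAPK_Pase": 1.0,
        "ATP": ACT_ATP / X_ATP,
        "ADP": ACT_ADP / X_ADP,
        "Pi": ACT_PI / X_PI,
    }
    cycles: dict[str, tuple[str, str, str, str]] = {
        "L1": ("MAP4K", "MAP3K", "MAP3KP", "MAP3K_Pase"),
        "L2a": ("MAP3KP", "MAP2K", "MAP2KP", "MAP2K_Pase"),
        "L2b": ("MAP3KP", "MAP2KP", "MAP2KPP", "MAP2K_Pase"),
        "L3a": ("MAP2KPP", "MAPK", "MAPKP", "MAPK_Pase"),
        "L3b": ("MAP2KPP", "MAPKP", "MAPKPP", "MAPK_Pase"),
    }
    if feedback != "none":
        K["FB_Pase"] = 1.0
        if feedback == "positive":
            # active input is the phosphorylated species: X1 = XP -> MAP4K
            K["MAP4K_I"] = 1.0
            K["MAP4K"] = PHOS_FACTOR
            cycles["FB"] = ("MAPKPP", "MAP4K_I", "MAP4K", "FB_Pase")
        else:
            # active input is the unphosphorylated species: X1 = X -> MAP4K
            K["MAP4K_I"] = PHOS_FACTOR
            cycles["FB"] = ("MAPKPP", "MAP4K", "MAP4K_I", "FB_Pase")

    # the clamp mu_ATP - mu_ADP - mu_Pi is scaled to the requested fraction
    # of its nominal value by moving the ATP chemostat concentration; rate
    # constants are untouched, so only the boundary potential changes
    x_atp = ACT_ATP ** f * (ACT_ADP * ACT_PI) ** (1 - f) / K["ATP"]

    cascade = CompositeModule("cascade")
    for name, Kval in K.items():
        cascade.add(Species(name, K=Kval))
        cascade.add(Junction(f"j_{name}", "0"))
        cascade.connect(name, f"j_{name}")
    for inst, (E_kin, X, XP, E_pho) in cycles.items():
        cyc = _cycle_for(
            K, E_kin, X, XP, E_pho,
            cfg.kinase_kinetics, cfg.phosphatase_kinetics,
            act_ATP=ACT_ATP, name=inst,
        )
        cascade.add(cyc, inst)
        cascade.connect(f"j_{E_kin}", f"{inst}.E_kin")
        cascade.connect(f"j_{X}", f"{inst}.X")
        cascade.connect(f"j_{XP}", f"{inst}.XP")
        cascade.connect(f"j_{E_pho}", f"{inst}.E_pho")
        cascade.connect("j_ATP", f"{inst}.ATP")
        cascade.connect("j_ADP", f"{inst}.ADP")
        cascade.connect("j_Pi", f"{inst}.Pi")

    initial = {
        "MAP4K": cfg.x_MAP4K,
        "MAP3K": cfg.x_MAP3K,
        "MAP2K": cfg.x_MAP2K,
        "MAPK": cfg.x_MAPK,
        "MAP3K_Pase": cfg.x_MAP3K_Pase,
        "MAP2K_Pase": cfg.x_MAP2K_Pase,
        "MAPK_Pase": cfg.x_MAPK_Pase,
    }
    if feedback != "none":
        initial["FB_Pase"] = cfg.x_FB_Pase
    chemostats = {"ATP": x_atp, "ADP": X_ADP, "Pi": X_PI}
    return BondGraphModel(cascade, chemostats=chemostats, initial=initial, RT=cfg.RT)


def activation_analysis(
    config: CascadeConfig | None = None,
    input_grid: np.ndarray | None = None,
    feedback: str = "none",
    atp_energy_fraction: float | None = None,
    active_branch: bool = False,
    ss_kwargs: dict | None = None,
) -> dict:
    """Steady-state activation of each cascade level vs input concentration.

    Activation of a level is the percentage of its substrate moiety in the
    fully phosphorylated (active) form.  ``active_branch=True`` starts every
    grid point from a fully activated initial condition (all substrate in
    the active form), which exposes the upper branch of a bistable system.
    """
    cfg = config or CascadeConfig()
    if atp_energy_fraction is not None:
        cfg = replace(cfg, atp_energy_fraction=atp_energy_fraction)
    if input_grid is None:
        input_grid = np.geomspace(1e-12, 1e-8, 13)
    model = build_cascade(cfg, feedback=feedback)
    net: ReactionNetwork = model.network()
    totals = {"MAP3K": cfg.x_MAP3K, "MAP2K": cfg.x_MAP2K, "MAPK": cfg.x_MAPK}
    base = None
    if active_branch:
        base = {
            "MAP3K": 0.0, "MAP2K": 0.0, "MAPK": 0.0,
            "MAP3KP": cfg.x_MAP3K, "MAP2KPP": cfg.x_MAP2K, "MAPKPP": cfg.x_MAPK,
        }
    kwargs = {"t_init": 100.0, "tol": 1e-6}
    kwargs.update(ss_kwargs or {})
    res = signal_response_curve(
        net, "MAP4K", input_grid, list(ACTIVE_FORMS.values()),
        base_initial=base, ss_kwargs=kwargs,
    )
    activation = {
        level: 100.0 * res["outputs"][active] / totals[level]
        for level, active in ACTIVE_FORMS.items()
    }
    return {
        "input": input_grid,
        "activation_percent": activation,
        "concentrations": res["outputs"],
        "errors": res["errors"],
    }


def hill_coefficient(u: np.ndarray, y: np.ndarray) -> float:
    """Effective Hill exponent of a monotone response curve.

    n_H = ln 81 / ln(u90/u10), where u10 and u90 are the inputs at 10% and
    90% of the maximal response (log-interpolated).  Larger values mean a
    steeper, more switch-like transition.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    yn = y / np.max(y)

    def crossing(level: float) -> float:
        above = np.nonzero(yn >= level)[0]
        if len(above) == 0 or above[0] == 0:
            raise ValueError(f"response does not cross {level} inside the grid")
        i = above[0]
        lu0, lu1 = np.log(u[i - 1]), np.log(u[i])
        y0, y1 = yn[i - 1], yn[i]
        return float(np.exp(lu0 + (level - y0) / (y1 - y0) * (lu1 - lu0)))

    u10, u90 = crossing(0.1), crossing(0.9)
    return float(np.log(81.0) / np.log(u90 / u10))
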