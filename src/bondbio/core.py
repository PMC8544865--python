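"""Bond-graph data model: components, ports, bonds and hierarchical modules.

A bond graph represents a biochemical network as an energy-conserving graph.
Each edge (bond) carries an effort -- here a chemical potential mu [J/mol] --
and a flow -- a molar flux v [mol/s] -- whose product is power, so every
connection transfers both mass and energy.  Three kinds of leaf component
appear in biochemical bond graphs:

* :class:`Species` stores chemical energy; its potential is a function of its
  amount (see :mod:`bondbio.ratelaws`).
* :class:`Reaction` dissipates energy; its flux is a function of the forward
  and reverse affinities through one of several thermodynamically consistent
  rate laws.
* :class:`Junction` routes energy losslessly.  A ``"0"`` junction (common
  potential) makes all attached bonds share one potential while their flows
  sum to zero -- the mass-balance, Kirchhoff-current analogue.  A ``"1"``
  junction (common flow) makes all attached bonds share one flow while their
  potentials sum to zero -- the affinity-summation, Kirchhoff-voltage
  analogue.

Models are composed hierarchically: a :class:`CompositeModule` holds named
child components (or sub-modules), internal bonds, and a set of *exposed*
ports through which the module can be wired into a larger model.  Components
are addressed by dot-separated instance paths such as
``"cascade.L2.kinase.E"``.  :func:`flatten` removes the hierarchy, producing
an equivalent single-level module from which the governing equations are
assembled (:mod:`bondbio.network`).
"""

from __future__ import annotations

import copy
import sys
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = [
    "BondGraphError",
    "DanglingPortError",
    "Port",
    "Bond",
    "Component",
    "Species",
    "Reaction",
    "Junction",
    "CompositeModule",
    "BondGraphModel",
    "compose",
    "connect",
    "instantiate",
    "flatten",
    "set_parameter",
    "get_parameter",
]


class BondGraphError(Exception):
    """Structural error in a bond-graph model."""


class DanglingPortError(BondGraphError):
    """A non-exposed port was left unbonded when flattening."""


@dataclass(eq=False)
class Port:
    """A connection point on a component.

    ``direction`` fixes the sign convention: positive flux runs *into* an
    ``"in"`` port and *out of* an ``"out"`` port.  A port participates in at
    most one bond.
    """

    component: "Component"
    label: str
    direction: str = "in"
    bond: "Bond | None" = field(default=None, repr=False)

    @property
    def is_bonded(self) -> bool:
        return self.bond is not None

    def other_end(self) -> "Port":
        if self.bond is None:
            raise BondGraphError(f"port {self.component.name}.{self.label} is not bonded")
        return self.bond.head if self.bond.tail is self else self.bond.tail


@dataclass(eq=False)
class Bond:
    """A lossless power bond between two distinct ports.

    Both ends see the same effort (chemical potential) and the same flow
    (molar flux); power ``mu * v`` entering one end leaves the other.
    """

    tail: Port
    head: Port

    def __post_init__(self) -> None:
        if self.tail is self.head:
            raise BondGraphError("a bond must connect two distinct ports")
        for p in (self.tail, self.head):
            if p.is_bonded:
                raise BondGraphError(
                    f"port {p.component.name}.{p.label} is already bonded"
                )
        self.tail.bond = self
        self.head.bond = self

    @property
    def ports(self) -> tuple[Port, Port]:
        return (self.tail, self.head)


class Component:
    """Base class for bond-graph leaf components."""

    def __init__(self, name: str):
        if "." in name:
            raise BondGraphError(f"component name {name!r} contains reserved '.'")
        self.name = name
        self.ports: dict[str, Port] = {}

    def add_port(self, label: str, direction: str = "in") -> Port:
        if label in self.ports:
            raise BondGraphError(f"duplicate port label {label!r} on {self.name}")
        port = Port(self, label, direction)
        self.ports[label] = port
        return port

    def port(self, label: str) -> Port:
        return self.ports[label]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.name!r})"


class Species(Component):
    """A chemical species with thermodynamic constant ``K``.

    ``K`` [M^-1 when state is a concentration] encodes the species' standard
    free energy; together with the amount x it determines the chemical
    potential mu = RT ln(K x).  The single port carries that potential and
    receives the net molar flux (positive flux increases x).
    """

    def __init__(self, name: str, K: float | None = None):
        super().__init__(name)
        if K is not None and K <= 0:
            raise ValueError(f"species {name}: K must be positive, got {K}")
        self.K = K
        self.add_port("pot", direction="in")


class Reaction(Component):
    """A reversible reaction with a thermodynamically consistent rate law.

    The ``f`` port receives the forward affinity (sum of reactant
    potentials), the ``r`` port the reverse affinity (sum of product
    potentials); the rate law maps the two onto a single molar flux in the
    declared forward direction.
    """

    def __init__(self, name: str, law=None):
        super().__init__(name)
        self.law = law
        self.add_port("f", direction="in")
        self.add_port("r", direction="out")


class Junction(Component):
    """A ``"0"`` (common potential) or ``"1"`` (common flow) junction.

    Ports are created on demand, one per bond; degree-2 junctions behave as
    pass-throughs during equation assembly.
    """

    def __init__(self, name: str, kind: str):
        super().__init__(name)
        if kind not in ("0", "1"):
            raise BondGraphError(f"junction kind must be '0' or '1', got {kind!r}")
        self.kind = kind

    def new_port(self, direction: str = "in") -> Port:
        i = 0
        while f"p{i}" in self.ports:
            i += 1
        return self.add_port(f"p{i}", direction)

    def port(self, label: str) -> Port:
        # ports materialise lazily so serialised bond lists can name them
        if label not in self.ports:
            self.add_port(label)
        return self.ports[label]


Child = Union[Component, "CompositeModule"]


class CompositeModule:
    """A named collection of components, internal bonds and exposed ports.

    Modules act both as templates (deep-copied by :func:`instantiate`) and as
    the root of a model.  ``exposed`` maps an external label to an internal
    :class:`Port` that is left free for exactly one external bond.
    """

    def __init__(self, name: str):
        if "." in name:
            raise BondGraphError(f"module name {name!r} contains reserved '.'")
        self.name = name
        self.children: dict[str, Child] = {}
        self.bonds: list[Bond] = []
        self.exposed: dict[str, Port] = {}

    # -- composition ---------------------------------------------------

    def add(self, child: Child, instance_name: str | None = None) -> Child:
        """Add a component or sub-module under ``instance_name``."""
        name = instance_name if instance_name is not None else child.name
        if "." in name:
            raise BondGraphError(f"instance name {name!r} contains reserved '.'")
        if name in self.children:
            raise BondGraphError(f"duplicate instance name {name!r} in {self.name}")
        self.children[name] = child
        return child

    def resolve(self, path: str) -> Child:
        """Resolve a dot-separated instance path to a child."""
        node: Child = self
        for part in path.split("."):
            if not isinstance(node, CompositeModule) or part not in node.children:
                raise BondGraphError(f"cannot resolve path {path!r} in {self.name!r}")
            node = node.children[part]
        return node

    def resolve_port(self, path: str) -> Port:
        """Resolve a path to a port.

        The final path element may be a port label on a leaf component, an
        exposed label of a sub-module, or a component name -- in which case
        an implicit port is used (the single port of a species, or a fresh
        port on a junction).
        """
        parts = path.split(".")
        node: Child | Port = self
        for i, part in enumerate(parts):
            where = ".".join(parts[: i + 1])
            if isinstance(node, CompositeModule):
                if part in node.children:
                    node = node.children[part]
                elif part in node.exposed:
                    if i != len(parts) - 1:
                        raise BondGraphError(
                            f"exposed label {where!r} is not a module"
                        )
                    node = node.exposed[part]
                else:
                    raise BondGraphError(f"cannot resolve {where!r} in {self.name!r}")
            elif isinstance(node, Component):
                if i != len(parts) - 1:
                    raise BondGraphError(f"{where!r}: component has no children")
                node = node.port(part)
            else:
                raise BondGraphError(f"cannot resolve {path!r} past a port")
        if isinstance(node, Port):
            return node
        if isinstance(node, Species):
            return node.port("pot")
        if isinstance(node, Junction):
            return node.new_port()
        if isinstance(node, Reaction):
            raise BondGraphError(
                f"{path!r}: specify a reaction port explicitly ('.f' or '.r')"
            )
        raise BondGraphError(f"{path!r} resolves to a module, not a port")

    def connect(self, port_a: str | Port, port_b: str | Port) -> Bond:
        """Bond two ports, given as paths or port objects."""
        pa = port_a if isinstance(port_a, Port) else self.resolve_port(port_a)
        pb = port_b if isinstance(port_b, Port) else self.resolve_port(port_b)
        if pa is pb:
            raise BondGraphError("cannot bond a port to itself")
        bond = Bond(pa, pb)
        self.bonds.append(bond)
        return bond

    def expose(self, path: str | Port, label: str) -> Port:
        """Expose an internal port under an external label."""
        if label in self.exposed:
            raise BondGraphError(f"duplicate exposed label {label!r} on {self.name}")
        port = path if isinstance(path, Port) else self.resolve_port(path)
        if port.is_bonded:
            raise BondGraphError(f"cannot expose bonded port {label!r}")
        self.exposed[label] = port
        return port

    # -- introspection -------------------------------------------------

    def walk(self, prefix: str = "") -> Iterator[tuple[str, Component]]:
        """Yield ``(dotted_path, leaf_component)`` pairs, depth-first."""
        for name, child in self.children.items():
            path = f"{prefix}{name}"
            if isinstance(child, CompositeModule):
                yield from child.walk(prefix=f"{path}.")
            else:
                yield path, child

    def all_bonds(self) -> Iterator[Bond]:
        yield from self.bonds
        for child in self.children.values():
            if isinstance(child, CompositeModule):
                yield from child.all_bonds()

    def component_path(self, component: Component) -> str | None:
        for path, leaf in self.walk():
            if leaf is component:
                return path
        return None

    def port_path(self, port: Port) -> str:
        path = self.component_path(port.component)
        if path is None:
            raise BondGraphError("port's component is not in this module")
        return f"{path}.{port.label}"


@contextmanager
def _deep_recursion(limit: int = 200_000):
    # ports, bonds and components form long reference chains; deepcopy
    # walks them recursively, so large models need more stack headroom
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, limit))
    try:
        yield
    finally:
        sys.setrecursionlimit(old)


def _deepcopy_module(module: CompositeModule) -> CompositeModule:
    with _deep_recursion():
        return copy.deepcopy(module)


# -- parameter access ---------------------------------------------------


def set_parameter(module: CompositeModule, key: str, value: float) -> None:
    """Set a parameter addressed as ``"path.to.component.param"``.

    Species expose ``K``; reactions expose the attributes of their rate law
    (``kappa``, ``kbar``, ``e0``, ``Rb0``, ...).
    """
    path, _, param = key.rpartition(".")
    if not path:
        raise KeyError(f"parameter key {key!r} must include a component path")
    comp = module.resolve(path)
    if isinstance(comp, Species) and param == "K":
        if value <= 0:
            raise ValueError(f"{key}: K must be positive")
        comp.K = value
    elif isinstance(comp, Reaction) and comp.law is not None and hasattr(comp.law, param):
        setattr(comp.law, param, value)
    else:
        raise KeyError(f"unknown parameter {param!r} on component {path!r}")


def get_parameter(module: CompositeModule, key: str) -> float:
    path, _, param = key.rpartition(".")
    comp = module.resolve(path)
    if isinstance(comp, Species) and param == "K":
        return comp.K
    if isinstance(comp, Reaction) and comp.law is not None and hasattr(comp.law, param):
        return getattr(comp.law, param)
    raise KeyError(f"unknown parameter {param!r} on component {path!r}")


# -- the spec'd operations as free functions ----------------------------


def compose(module: CompositeModule, child: Child, instance_name: str) -> CompositeModule:
    """Add ``child`` to ``module`` under ``instance_name`` (dot-namespaced)."""
    module.add(child, instance_name)
    return module


def connect(module: CompositeModule, port_a: str, port_b: str) -> CompositeModule:
    module.connect(port_a, port_b)
    return module


def instantiate(
    template: CompositeModule, name: str, overrides: dict[str, float] | None = None
) -> CompositeModule:
    """Deep, independent copy of a template with optional parameter overrides.

    Overrides are keyed ``"path.to.component.param"`` and must reference
    parameters the template declares; unknown keys raise ``KeyError``.
    """
    inst = _deepcopy_module(template)
    inst.name = name
    for key, value in (overrides or {}).items():
        set_parameter(inst, key, value)
    return inst


def flatten(module: CompositeModule) -> CompositeModule:
    """Replace the hierarchy with a single-level module.

    Child names become dot-separated paths; bonds and exposed ports are
    carried over unchanged (the flat graph induces identical equations).
    The input is deep-copied, never mutated.  Raises
    :class:`DanglingPortError` naming the path of any unbonded, unexposed
    port, and :class:`BondGraphError` for unbound parameters.
    """
    src = _deepcopy_module(module)
    flat = CompositeModule(src.name)
    for path, leaf in src.walk():
        flat.children[path] = leaf
    flat.bonds = list(src.all_bonds())

    def _exposed_ports(mod: CompositeModule) -> Iterator[Port]:
        yield from mod.exposed.values()

    exposed = set(id(p) for p in _exposed_ports(src))
    flat.exposed = dict(src.exposed)
    for path, leaf in flat.children.items():
        if isinstance(leaf, Species) and leaf.K is None:
            raise BondGraphError(f"unbound parameter: {path}.K")
        if isinstance(leaf, Reaction) and leaf.law is None:
            raise BondGraphError(f"unbound rate law on reaction {path}")
        for label, port in leaf.ports.items():
            if not port.is_bonded and id(port) not in exposed:
                raise DanglingPortError(f"dangling port: {path}.{label}")
    return flat


@dataclass
class BondGraphModel:
    """A complete model: root module, chemostats, initial state, temperature.

    ``chemostats`` maps flat species names to fixed concentrations [M] --
    species exchanged with the environment whose amounts have zero rate of
    change.  ``initial`` maps flat species names to initial concentrations;
    unlisted species start at zero.
    """

    root: CompositeModule
    chemostats: dict[str, float] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    RT: float = 8.314 * 310.15

    def flat(self) -> CompositeModule:
        return flatten(self.root)

    def network(self):
        """Assemble the flat reaction network (see :mod:`bondbio.network`)."""
        from .network import extract_network

        return extract_network(self)
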