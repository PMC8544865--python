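"""JSON serialisation of bond-graph models.

The dialect mirrors the in-memory structure: a document holds a schema
version, the temperature (as RT), chemostat and initial-state tables, and a
``root`` module.  Modules list their children (species, reactions, junctions
or nested modules), internal bonds (pairs of dot-separated port paths,
relative to the module) and exposed ports (label -> port path).  Documents
round-trip losslessly: parse -> serialise -> parse is the identity.

Validation errors carry a JSON-pointer-style location, e.g.
``/root/children/L1/bonds/3``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .core import (
    BondGraphError,
    BondGraphModel,
    CompositeModule,
    Component,
    Junction,
    Reaction,
    Species,
)
from .network import ReactionNetwork, network_from_reactions
from .ratelaws import GeneralisedKinetics, MassAction, MichaelisMenten, RT_DEFAULT

__all__ = [
    "ModelDocumentError",
    "to_document",
    "from_document",
    "write_model",
    "read_model",
    "read_parameters",
    "apply_parameters",
    "module_from_network",
]

SCHEMA_VERSION = 1

_LAW_TAGS = {
    MassAction: "mass_action",
    MichaelisMenten: "michaelis_menten",
    GeneralisedKinetics: "generalised_kinetics",
}


class ModelDocumentError(BondGraphError):
    """Schema violation, annotated with a JSON-pointer location."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


def _law_to_doc(law) -> dict:
    tag = _LAW_TAGS.get(type(law))
    if tag is None:
        raise BondGraphError(f"cannot serialise rate law {type(law).__name__}")
    doc = {"type": tag}
    for key, value in law.parameters().items():
        doc[key] = list(value) if isinstance(value, tuple) else value
    return doc


def _law_from_doc(doc: dict, pointer: str):
    if not isinstance(doc, dict) or "type" not in doc:
        raise ModelDocumentError(pointer, "rate law must be an object with a 'type'")
    params = {k: v for k, v in doc.items() if k != "type"}
    try:
        if doc["type"] == "mass_action":
            return MassAction(**params)
        if doc["type"] == "michaelis_menten":
            return MichaelisMenten(**params)
        if doc["type"] == "generalised_kinetics":
            params["Rb_f"] = tuple(params.get("Rb_f", ()))
            params["Rb_r"] = tuple(params.get("Rb_r", ()))
            return GeneralisedKinetics(**params)
    except (TypeError, ValueError) as exc:
        raise ModelDocumentError(pointer, f"bad rate-law parameters: {exc}") from exc
    raise ModelDocumentError(pointer + "/type", f"unknown rate law {doc['type']!r}")


def _module_to_doc(mod: CompositeModule) -> dict:
    children: dict[str, dict] = {}
    for name, child in mod.children.items():
        if isinstance(child, CompositeModule):
            children[name] = _module_to_doc(child)
        elif isinstance(child, Species):
            children[name] = {"kind": "species", "K": child.K}
        elif isinstance(child, Reaction):
            children[name] = {"kind": "reaction", "law": _law_to_doc(child.law)}
        elif isinstance(child, Junction):
            children[name] = {"kind": "junction", "junction": child.kind}
        else:  # pragma: no cover - defensive
            raise BondGraphError(f"unknown child type {type(child).__name__}")
    bonds = [
        [mod.port_path(b.tail), mod.port_path(b.head)] for b in mod.bonds
    ]
    exposed = {label: mod.port_path(p) for label, p in mod.exposed.items()}
    return {"kind": "module", "children": children, "bonds": bonds, "exposed": exposed}


def _module_from_doc(doc: dict, name: str, pointer: str) -> CompositeModule:
    if not isinstance(doc, dict):
        raise ModelDocumentError(pointer, "module must be an object")
    mod = CompositeModule(name)
    children = doc.get("children", {})
    if not isinstance(children, dict):
        raise ModelDocumentError(pointer + "/children", "must be an object")
    for cname, cdoc in children.items():
        cptr = f"{pointer}/children/{cname}"
        if not isinstance(cdoc, dict) or "kind" not in cdoc:
            raise ModelDocumentError(cptr, "child must be an object with a 'kind'")
        kind = cdoc["kind"]
        if kind == "module":
            mod.add(_module_from_doc(cdoc, cname, cptr), cname)
        elif kind == "species":
            if "K" not in cdoc or not isinstance(cdoc["K"], (int, float)):
                raise ModelDocumentError(cptr + "/K", "species needs a numeric K")
            mod.add(Species(cname, K=float(cdoc["K"])))
        elif kind == "reaction":
            mod.add(Reaction(cname, _law_from_doc(cdoc.get("law"), cptr + "/law")))
        elif kind == "junction":
            jkind = cdoc.get("junction")
            if jkind not in ("0", "1"):
                raise ModelDocumentError(cptr + "/junction", "must be '0' or '1'")
            mod.add(Junction(cname, jkind))
        else:
            raise ModelDocumentError(cptr + "/kind", f"unknown component kind {kind!r}")
    bonds = doc.get("bonds", [])
    if not isinstance(bonds, list):
        raise ModelDocumentError(pointer + "/bonds", "must be an array")
    for i, pair in enumerate(bonds):
        bptr = f"{pointer}/bonds/{i}"
        if not (isinstance(pair, list) and len(pair) == 2):
            raise ModelDocumentError(bptr, "bond must name exactly two port paths")
        try:
            mod.connect(pair[0], pair[1])
        except BondGraphError as exc:
            raise ModelDocumentError(bptr, str(exc)) from exc
    exposed = doc.get("exposed", {})
    if not isinstance(exposed, dict):
        raise ModelDocumentError(pointer + "/exposed", "must be an object")
    for label, path in exposed.items():
        try:
            mod.expose(path, label)
        except BondGraphError as exc:
            raise ModelDocumentError(f"{pointer}/exposed/{label}", str(exc)) from exc
    return mod


def to_document(model: BondGraphModel) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "name": model.root.name,
        "RT": model.RT,
        "chemostats": dict(model.chemostats),
        "initial": dict(model.initial),
        "root": _module_to_doc(model.root),
    }


def from_document(doc: dict) -> BondGraphModel:
    if not isinstance(doc, dict):
        raise ModelDocumentError("", "document must be an object")
    if doc.get("schema") != SCHEMA_VERSION:
        raise ModelDocumentError("/schema", f"unsupported schema {doc.get('schema')!r}")
    root = _module_from_doc(doc.get("root", {}), doc.get("name", "model"), "/root")
    model = BondGraphModel(
        root,
        chemostats=dict(doc.get("chemostats", {})),
        initial=dict(doc.get("initial", {})),
        RT=float(doc.get("RT", RT_DEFAULT)),
    )
    return model


def write_model(model: BondGraphModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_document(model), indent=1) + "\n")


def read_model(path: str | Path) -> BondGraphModel:
    return from_document(json.loads(Path(path).read_text()))


def read_parameters(path: str | Path) -> dict[str, float]:
    """Read a parameter CSV with columns (component_path, parameter, value, units).

    Returns ``{"component.path.parameter": value}`` suitable for
    :func:`bondbio.core.set_parameter` / ``instantiate`` overrides.  The
    units column is carried for documentation only; values must already be
    in the package's working units (M, s, kJ/mol).
    """
    import pandas as pd

    table = pd.read_csv(path)
    required = {"component_path", "parameter", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ModelDocumentError("", f"parameter CSV lacks columns {sorted(missing)}")
    return {
        f"{row.component_path}.{row.parameter}": float(row.value)
        for row in table.itertuples()
    }


def apply_parameters(model: BondGraphModel, path: str | Path) -> BondGraphModel:
    """Merge a parameter CSV into a model by component path (in place)."""
    from .core import set_parameter

    for key, value in read_parameters(path).items():
        set_parameter(model.root, key, value)
    return model


def module_from_network(net: ReactionNetwork, name: str = "model") -> BondGraphModel:
    """Rebuild a serialisable single-module bond graph from a flat network."""
    K = {s: float(k) for s, k in zip(net.species, net.K)}
    reactions = {
        r.name.replace(".", "_"): (r.law.copy(), list(r.forward), list(r.reverse))
        for r in net.reactions
    }
    if any("." in r.name for r in net.reactions) or any("." in s for s in net.species):
        raise BondGraphError(
            "namespaced (hierarchical) names cannot be rebuilt into a flat module"
        )
    mod = network_from_reactions(name, K, reactions)
    return BondGraphModel(
        mod, chemostats=dict(net.chemostats), initial=dict(net.initial), RT=net.RT
    )
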