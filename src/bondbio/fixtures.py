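"""Random, detailed-balance-consistent toy networks for tests and demos.

Fixture networks are drawn directly in *thermodynamic* parameter space
(species constants K and reaction constants kappa, both log-uniform), so
they satisfy the Wegscheider conditions by construction no matter how many
cycles the topology contains -- the whole point of the thermodynamic
parameterisation.  Generation is deterministic: the same seed yields an
identical model (and an identical serialised document).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BondGraphModel
from .network import network_from_reactions
from .ratelaws import MassAction, RT_DEFAULT

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass
class FixtureSpec:
    """Recipe for a random mass-action network.

    ``shape``: "chain" (A1 <-> A2 <-> ... <-> An), "cycle" (chain closed
    back on itself, exercising Wegscheider constraints), or "random"
    (a connected random pairing with extra shortcut reactions).
    K and kappa ranges are log-uniform.
    """

    seed: int = 0
    n_species: int = 5
    shape: str = "random"
    K_range: tuple[float, float] = (1e-2, 1e2)
    kappa_range: tuple[float, float] = (1e-1, 1e1)
    x_range: tuple[float, float] = (1e-2, 1e1)
    n_chemostats: int = 0
    RT: float = RT_DEFAULT


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def generate_fixture(spec: FixtureSpec) -> BondGraphModel:
    """Build a reproducible, thermodynamically consistent toy model."""
    if spec.n_species < 2:
        raise ValueError("fixture needs at least 2 species")
    if spec.shape not in ("chain", "cycle", "random"):
        raise ValueError(f"unknown fixture shape {spec.shape!r}")
    if spec.shape == "cycle" and spec.n_species < 3:
        raise ValueError("a cycle needs at least 3 species")
    rng = np.random.default_rng(spec.seed)
    names = [f"A{i}" for i in range(spec.n_species)]
    K = {s: float(k) for s, k in zip(names, _log_uniform(rng, *spec.K_range, spec.n_species))}

    pairs: list[tuple[str, str]] = [(names[i], names[i + 1]) for i in range(spec.n_species - 1)]
    if spec.shape == "cycle":
        pairs.append((names[-1], names[0]))
    elif spec.shape == "random":
        n_extra = int(rng.integers(1, max(2, spec.n_species // 2) + 1))
        for _ in range(n_extra):
            i, j = rng.choice(spec.n_species, size=2, replace=False)
            pairs.append((names[int(i)], names[int(j)]))

    reactions = {}
    for idx, (sa, sb) in enumerate(pairs):
        kappa = float(_log_uniform(rng, *spec.kappa_range))
        reactions[f"r{idx}"] = (MassAction(kappa), [sa], [sb])

    mod = network_from_reactions(f"fixture{spec.seed}", K, reactions)
    x0 = {s: float(x) for s, x in zip(names, _log_uniform(rng, *spec.x_range, spec.n_species))}
    chemo_names = names[: spec.n_chemostats]
    chemostats = {s: x0[s] for s in chemo_names}
    return BondGraphModel(mod, chemostats=chemostats, initial=x0, RT=spec.RT)
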