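"""Structure and basic behaviour of the MAPK cascade builders."""

import numpy as np
import pytest

import bondbio as bb
from bondbio import mapk


def wire_cycle_standalone(x_kinase=1e-9, x_total=1e-6, act_drive=1e4):
    """A single phosphorylation cycle with its own species and chemostats.

    ``act_drive`` is the activity ratio driving each leg of the cycle.
    """
    K = {"E1": 1.0, "E2": 1.0, "X": 1.0, "XP": act_drive,
         "ATP": act_drive**2 / 1e-3, "ADP": 1.0 / 1e-4, "Pi": 1.0 / 1e-3}
    kin = mapk.EnzymeKinetics()
    kappa1 = kin.a / (K["E1"] * K["X"] * act_drive**2)
    K_C = kin.d / kappa1
    kappa2 = kin.k / K_C
    kinase = mapk.build_kinase_module(kappa1, kappa2, K_C)
    kappa1p = kin.a / (K["E2"] * K["XP"])
    K_Cp = kin.d / kappa1p
    kappa2p = kin.k / K_Cp
    phosphatase = mapk.build_phosphatase_module(kappa1p, kappa2p, K_Cp)
    cycle = mapk.build_cycle(kinase, phosphatase)
    top = bb.CompositeModule("top")
    top.add(cycle, "cyc")
    for name, Kv in K.items():
        top.add(bb.Species(name, K=Kv))
        top.add(bb.Junction(f"j{name}", "0"))
        top.connect(name, f"j{name}")
    for label, ext in [("E_kin", "E1"), ("E_pho", "E2"), ("X", "X"),
                       ("XP", "XP"), ("ATP", "ATP"), ("ADP", "ADP"), ("Pi", "Pi")]:
        top.connect(f"j{ext}", f"cyc.{label}")
    model = bb.BondGraphModel(
        top,
        chemostats={"ATP": 1e-3, "ADP": 1e-4, "Pi": 1e-3},
        initial={"E1": x_kinase, "E2": 3e-10, "X": x_total},
    )
    return model.network()


class TestModules:
    def test_kinase_port_set_and_contents(self):
        m = mapk.build_kinase_module(1.0, 1.0, 1.0)
        assert set(m.exposed) == {"E", "X", "XP", "ATP", "ADP"}
        flat = bb.flatten(m)
        kinds = [type(c).__name__ for c in flat.children.values()]
        assert kinds.count("Reaction") == 2
        assert kinds.count("Species") == 1  # the enzyme-substrate complex

    def test_phosphatase_port_set_and_contents(self):
        m = mapk.build_phosphatase_module(1.0, 1.0, 1.0)
        assert set(m.exposed) == {"E", "X", "XP", "Pi"}
        flat = bb.flatten(m)
        kinds = [type(c).__name__ for c in flat.children.values()]
        assert kinds.count("Reaction") == 2 and kinds.count("Species") == 1

    def test_cycle_port_set(self):
        cycle = mapk.build_cycle(
            mapk.build_kinase_module(1.0, 1.0, 1.0),
            mapk.build_phosphatase_module(1.0, 1.0, 1.0),
        )
        assert set(cycle.exposed) == {"E_kin", "E_pho", "X", "XP", "ATP", "ADP", "Pi"}

    def test_cycle_net_reaction_is_atp_hydrolysis(self):
        """One full turn of the cycle converts ATP to ADP + Pi and nothing else."""
        net = wire_cycle_standalone()
        w = np.zeros(len(net.reactions), dtype=int)
        for j, r in enumerate(net.reactions):
            w[j] = 1  # r1 and r2 of both enzymes, one turn each
        overall = dict(zip(net.species, net.N @ w))
        assert {s: c for s, c in overall.items() if c != 0} == {
            "ATP": -1, "ADP": 1, "Pi": 1,
        }

    def test_cycle_substrate_moiety_is_conserved_dynamically(self):
        net = wire_cycle_standalone()
        traj = bb.integrate(net, net.x0(), (0.0, 50.0),
                            t_eval=np.linspace(0, 50, 20))
        idx = [net.index[s] for s in
               ("X", "XP", "cyc.kinase.C", "cyc.phosphatase.C")]
        totals = traj.x[idx, :].sum(axis=0)
        assert np.max(np.abs(totals - totals[0])) <= 1e-6 * totals[0]

    def test_zero_kinase_means_fully_dephosphorylated(self):
        net = wire_cycle_standalone(x_kinase=0.0)
        x0 = net.x0()
        i_X, i_XP = net.index["X"], net.index["XP"]
        x0[i_X], x0[i_XP] = 0.0, 1e-6  # start fully phosphorylated
        ss = bb.find_steady_state(net, x0, tol=1e-6, t_init=10.0)
        assert ss.x[i_XP] < 0.01 * 1e-6
        assert ss.x[i_X] == pytest.approx(1e-6, rel=0.01)

    def test_phosphorylated_fraction_increases_with_kinase(self):
        fractions = []
        for xk in (1e-10, 1e-9, 1e-8):
            net = wire_cycle_standalone(x_kinase=xk)
            ss = bb.find_steady_state(net, tol=1e-6, t_init=10.0)
            fractions.append(ss["XP"])
        assert fractions[0] < fractions[1] < fractions[2]


class TestCascade:
    def test_species_census_core(self):
        net = mapk.build_cascade().network()
        free = {s for s in net.species if "." not in s}
        assert free == {
            "MAP4K", "MAP3K", "MAP3KP", "MAP2K", "MAP2KP", "MAP2KPP",
            "MAPK", "MAPKP", "MAPKPP", "MAP3K_Pase", "MAP2K_Pase", "MAPK_Pase",
            "ATP", "ADP", "Pi",
        }
        complexes = {s for s in net.species if "." in s}
        assert len(complexes) == 10  # one kinase + one phosphatase complex per cycle
        assert set(net.chemostats) == {"ATP", "ADP", "Pi"}

    def test_default_initial_conditions(self):
        cfg = mapk.CascadeConfig()
        assert cfg.x_MAP3K == 3e-9
        assert cfg.x_MAP2K == cfg.x_MAPK == 1.2e-6
        assert cfg.x_MAP3K_Pase == cfg.x_MAP2K_Pase == 3e-10
        assert cfg.x_MAPK_Pase == 1.2e-7
        assert cfg.x_MAP4K == 3e-11
        net = mapk.build_cascade(cfg).network()
        x0 = net.x0()
        assert x0[net.index["MAP2K"]] == 1.2e-6
        assert x0[net.index["MAP2KPP"]] == 0.0

    def test_feedback_variants_differ_only_in_port_assignment(self):
        pos = mapk.build_cascade(feedback="positive").network()
        neg = mapk.build_cascade(feedback="negative").network()
        assert set(pos.species) == set(neg.species)
        sites = {}
        for net in (pos, neg):
            r1 = next(r for r in net.reactions if r.name == "FB.kinase.r1")
            sites[id(net)] = set(r1.forward)
        swap = {"MAP4K": "MAP4K_I", "MAP4K_I": "MAP4K"}
        assert sites[id(pos)] == {swap.get(s, s) for s in sites[id(neg)]}

    def test_flatten_matches_hand_built_flat_network(self):
        """The hierarchical cascade induces the same reactions as a flat build."""
        net = mapk.build_cascade().network()
        expected = {}
        for inst, (E, X, XP, Ep) in {
            "L1": ("MAP4K", "MAP3K", "MAP3KP", "MAP3K_Pase"),
            "L2a": ("MAP3KP", "MAP2K", "MAP2KP", "MAP2K_Pase"),
            "L2b": ("MAP3KP", "MAP2KP", "MAP2KPP", "MAP2K_Pase"),
            "L3a": ("MAP2KPP", "MAPK", "MAPKP", "MAPK_Pase"),
            "L3b": ("MAP2KPP", "MAPKP", "MAPKPP", "MAPK_Pase"),
        }.items():
            kc, pc = f"{inst}.kinase.C", f"{inst}.phosphatase.C"
            expected[f"{inst}.kinase.r1"] = ({E, X, "ATP"}, {kc})
            expected[f"{inst}.kinase.r2"] = ({kc}, {E, XP, "ADP"})
            expected[f"{inst}.phosphatase.r1"] = ({Ep, XP}, {pc})
            expected[f"{inst}.phosphatase.r2"] = ({pc}, {Ep, X, "Pi"})
        actual = {r.name: (set(r.forward), set(r.reverse)) for r in net.reactions}
        assert actual == expected

    def test_zero_hydrolysis_energy_admits_exact_equilibrium(self):
        """With the cofactor clamp at zero affinity, x = 1/K is a fixed point
        with zero dissipation -- the cascade is thermodynamically consistent."""
        net = mapk.build_cascade().network()
        zero_drive = {s: 1.0 / net.K[net.index[s]] for s in ("ATP", "ADP", "Pi")}
        net0 = net.with_chemostats(zero_drive)
        x_eq = 1.0 / net0.K
        # every activity K*x equals 1 to rounding, so every flux vanishes
        assert np.max(np.abs(net0.fluxes(x_eq))) < 1e-12
        assert abs(bb.dissipation(net0, x_eq)) < 1e-20

    def test_output_activation_increases_with_input(self):
        net = mapk.build_cascade().network()
        out = []
        for u in (1e-12, 1e-9):
            x0 = net.x0()
            x0[net.index["MAP4K"]] = u
            ss = bb.find_steady_state(net, x0, tol=1e-6, t_init=100.0)
            out.append(ss["MAPKPP"])
        assert out[1] > 10 * out[0]

    def test_atp_energy_fraction_moves_only_the_clamp(self):
        full = mapk.build_cascade().network()
        low = mapk.build_cascade(
            mapk.CascadeConfig(atp_energy_fraction=0.8)
        ).network()
        assert low.chemostats["ATP"] < full.chemostats["ATP"]
        assert low.chemostats["ADP"] == full.chemostats["ADP"]
        # rate laws are identical; only the boundary concentration moved
        for r_full, r_low in zip(full.reactions, low.reactions):
            assert r_full.law.parameters() == r_low.law.parameters()

    def test_invalid_feedback_and_fraction_rejected(self):
        with pytest.raises(ValueError):
            mapk.build_cascade(feedback="sideways")
        with pytest.raises(ValueError):
            mapk.build_cascade(mapk.CascadeConfig(atp_energy_fraction=0.0))
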