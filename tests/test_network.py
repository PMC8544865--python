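"""Stoichiometry, ODE assembly, conserved moieties and pathway vectors."""

import numpy as np
import pytest

import bondbio as bb
from bondbio.network import PathwayDimensionError


def chain_module(K=(1.0, 1.0, 1.0), kappas=(1.0, 1.0)):
    names = [f"A{i}" for i in range(len(K))]
    return bb.network_from_reactions(
        "chain",
        dict(zip(names, K)),
        {
            f"r{i}": (bb.MassAction(k), [names[i]], [names[i + 1]])
            for i, k in enumerate(kappas)
        },
    )


class TestStoichiometry:
    def test_enzyme_motif_matrix(self, enzyme_network):
        S = enzyme_network.stoichiometry().to_frame()
        expected = {
            "E": [-1, 1], "C": [1, -1], "S": [-1, 0], "P": [0, 1],
        }
        for species, row in expected.items():
            assert list(S.loc[species]) == row

    def test_single_reaction(self):
        net = bb.extract_network(bb.BondGraphModel(chain_module(K=(1.0, 2.0), kappas=(1.0,))))
        assert net.N.tolist() == [[-1], [1]]

    def test_multi_site_stoichiometry_counts_sites(self):
        mod = bb.network_from_reactions(
            "dimer", {"A": 1.0, "B": 1.0},
            {"r": (bb.MassAction(1.0), ["A", "A"], ["B"])},
        )
        net = bb.extract_network(bb.BondGraphModel(mod))
        assert net.N[net.index["A"], 0] == -2

    def test_glycolysis_internal_structure(self, glycolysis_reference):
        net = glycolysis_reference.network
        assert len(net.reactions) == 9
        assert set(net.internal_species) == {
            "F6P", "F16P", "DHAP", "GAP", "13DPG", "3PG", "2PG", "PEP",
        }


class TestAssembledOdes:
    def test_reproduces_polynomial_mass_action_form(self, enzyme_network):
        """dx/dt matches the explicitly derived two-reaction enzyme equations."""
        net = enzyme_network
        KE, KC, KS, KP = (net.K[net.index[s]] for s in "ECSP")
        k1, k2 = 1.2, 0.7
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(0.01, 4.0, 4)
            xE, xC, xS, xP = (x[net.index[s]] for s in "ECSP")
            v1 = k1 * (KE * xE * KS * xS - KC * xC)
            v2 = k2 * (KC * xC - KE * xE * KP * xP)
            expected = {"E": -v1 + v2, "C": v1 - v2, "S": -v1, "P": v2}
            dx = net.rhs(x)
            for s, val in expected.items():
                assert dx[net.index[s]] == pytest.approx(val, rel=1e-12)

    def test_all_chemostatted_is_static(self):
        mod = chain_module()
        model = bb.BondGraphModel(
            mod, chemostats={"A0": 1.0, "A1": 2.0, "A2": 3.0}
        )
        net = model.network()
        assert np.all(net.rhs(net.x0()) == 0.0)

    def test_brute_force_oracle_on_random_networks(self, rng):
        """Assembled dx/dt equals a per-species sum of mass-action terms.

        The oracle recomputes every flux as k+ prod(reactant x) - k- prod
        (product x) straight from the site lists and accumulates species by
        species, independent of the junction-traversal assembly.
        """
        from bondbio.fixtures import FixtureSpec, generate_fixture

        for seed in range(10):
            net = generate_fixture(
                FixtureSpec(seed=seed, n_species=4, shape="random")
            ).network()
            for _ in range(10):
                x = rng.uniform(0.05, 5.0, len(net.species))
                dx_oracle = np.zeros_like(x)
                for j, rxn in enumerate(net.reactions):
                    kf = rxn.law.kappa * np.prod(
                        [net.K[net.index[s]] for s in rxn.forward]
                    )
                    kr = rxn.law.kappa * np.prod(
                        [net.K[net.index[s]] for s in rxn.reverse]
                    )
                    v = kf * np.prod([x[net.index[s]] for s in rxn.forward]) - (
                        kr * np.prod([x[net.index[s]] for s in rxn.reverse])
                    )
                    for s in rxn.forward:
                        dx_oracle[net.index[s]] -= v
                    for s in rxn.reverse:
                        dx_oracle[net.index[s]] += v
                assert net.rhs(x) == pytest.approx(dx_oracle, rel=1e-10)

    def test_detailed_balance_equilibrium_is_exact(self, enzyme_network):
        x_eq = 1.0 / enzyme_network.K
        assert np.all(enzyme_network.fluxes(x_eq) == 0.0)
        assert np.all(enzyme_network.rhs(x_eq) == 0.0)


class TestConservedMoieties:
    def test_two_species_total(self):
        net = bb.extract_network(bb.BondGraphModel(chain_module(K=(1.0, 2.0), kappas=(1.0,))))
        (g,) = net.conserved_moieties()
        assert list(g) == [1, 1]

    def test_enzyme_motif_spans_expected_totals(self, enzyme_network):
        basis = enzyme_network.conserved_moieties()
        assert len(basis) == 2
        span = np.array(basis, dtype=float)
        idx = enzyme_network.index
        for target in ([1, 1, 0, 0], [0, 1, 1, 1]):  # E+C and S+C+P
            vec = np.zeros(4)
            for s, c in zip("ECSP", target):
                vec[idx[s]] = c
            _, res, *_ = np.linalg.lstsq(span.T, vec, rcond=None)
            assert float(res[0]) if len(res) else 0.0 == pytest.approx(0.0, abs=1e-12)

    def test_mapk_cycle_conserves_substrate_and_enzymes(self):
        from bondbio import mapk

        kin = mapk.build_kinase_module(1.0, 1.0, 1.0)
        pho = mapk.build_phosphatase_module(1.0, 1.0, 1.0)
        cycle = mapk.build_cycle(kin, pho)
        top = bb.CompositeModule("top")
        top.add(cycle, "cyc")
        for name in ("E1", "E2", "X", "XP", "ATP", "ADP", "Pi"):
            top.add(bb.Species(name, K=1.0))
            top.add(bb.Junction(f"j{name}", "0"))
            top.connect(name, f"j{name}")
        for label, ext in [
            ("E_kin", "E1"), ("E_pho", "E2"), ("X", "X"), ("XP", "XP"),
            ("ATP", "ATP"), ("ADP", "ADP"), ("Pi", "Pi"),
        ]:
            top.connect(f"j{ext}", f"cyc.{label}")
        net = bb.extract_network(
            bb.BondGraphModel(top, chemostats={"ATP": 1.0, "ADP": 1.0, "Pi": 1.0})
        )
        basis = net.conserved_moieties()
        span = np.array(basis, dtype=float)
        idx = net.index
        # substrate moiety: X + XP + both complexes
        vec = np.zeros(len(net.species))
        for s in ("X", "XP", "cyc.kinase.C", "cyc.phosphatase.C"):
            vec[idx[s]] = 1.0
        _, res, *_ = np.linalg.lstsq(span.T, vec, rcond=None)
        assert (float(res[0]) if len(res) else 0.0) == pytest.approx(0.0, abs=1e-10)


class TestSteadyStatePathway:
    def test_linear_chain(self):
        mod = chain_module()
        net = bb.BondGraphModel(mod, chemostats={"A0": 1.0, "A2": 1.0}).network()
        assert list(net.steady_state_pathway()) == [1, 1]

    def test_parallel_chains_report_dimension_two(self):
        mod = bb.network_from_reactions(
            "twochains",
            {f"{p}{i}": 1.0 for p in "AB" for i in range(3)},
            {
                f"r{p}{i}": (bb.MassAction(1.0), [f"{p}{i}"], [f"{p}{i+1}"])
                for p in "AB" for i in range(2)
            },
        )
        net = bb.BondGraphModel(
            mod, chemostats={"A0": 1.0, "A2": 1.0, "B0": 1.0, "B2": 1.0}
        ).network()
        with pytest.raises(PathwayDimensionError) as exc:
            net.steady_state_pathway()
        assert exc.value.dimension == 2

    def test_glycolysis_pathway_weights(self, glycolysis_reference):
        net = glycolysis_reference.network
        w = dict(zip(net.reaction_names, net.steady_state_pathway()))
        assert w == {
            "pgi": 1, "pfk": 1, "fba": 1, "tpi": 1,
            "gap": 2, "pgk": 2, "gpm": 2, "eno": 2, "pyk": 2,
        }
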