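"""Integration, steady states, response times and perturbations."""

import math

import numpy as np
import pytest

import bondbio as bb
from bondbio.simulate import IntegrationError, find_steady_state, response_time


def ab_network(KA=1.0, KB=1.0, kappa=1.0, x0=(1.0, 0.0), chemo=None):
    mod = bb.network_from_reactions(
        "ab", {"A": KA, "B": KB}, {"r": (bb.MassAction(kappa), ["A"], ["B"])}
    )
    model = bb.BondGraphModel(
        mod, chemostats=chemo or {}, initial={"A": x0[0], "B": x0[1]}
    )
    return model.network()


class TestIntegrate:
    def test_equilibrium_initial_state_stays_constant(self, enzyme_network):
        net = enzyme_network
        x_eq = 1.0 / net.K
        traj = bb.integrate(net, x_eq, (0.0, 50.0), t_eval=np.linspace(0, 50, 20))
        assert np.allclose(traj.x, x_eq[:, None], rtol=1e-9, atol=1e-12)

    def test_ab_relaxes_mono_exponentially(self):
        """Closed A <-> B: x_A(t) - x_A(inf) decays at rate k+ + k-."""
        KA, KB, kappa = 2.0, 0.5, 1.3
        net = ab_network(KA, KB, kappa, x0=(1.0, 0.0))
        kf, kr = kappa * KA, kappa * KB
        t = np.linspace(0, 3.0, 30)
        traj = bb.integrate(net, net.x0(), (0.0, 3.0), t_eval=t)
        total = 1.0
        xA_inf = total * kr / (kf + kr)
        expected = xA_inf + (1.0 - xA_inf) * np.exp(-(kf + kr) * t)
        assert np.allclose(traj.series("A"), expected, rtol=1e-6, atol=1e-9)

    def test_thermodynamic_and_kinetic_forms_agree(self, enzyme_network):
        """Trajectories of the K/kappa form match the k+/k- polynomial form."""
        from scipy.integrate import solve_ivp

        net = enzyme_network
        kin = bb.thermo_to_kinetic(net)
        k1p, k1m = kin.loc["r1", "k_plus"], kin.loc["r1", "k_minus"]
        k2p, k2m = kin.loc["r2", "k_plus"], kin.loc["r2", "k_minus"]
        idx = net.index

        def kinetic_rhs(t, x):
            xE, xC, xS, xP = x[idx["E"]], x[idx["C"]], x[idx["S"]], x[idx["P"]]
            v1 = k1p * xE * xS - k1m * xC
            v2 = k2p * xC - k2m * xE * xP
            dx = np.zeros_like(x)
            dx[idx["E"]] = -v1 + v2
            dx[idx["C"]] = v1 - v2
            dx[idx["S"]] = -v1
            dx[idx["P"]] = v2
            return dx

        x0 = net.x0()
        t = np.linspace(0, 5.0, 25)
        traj = bb.integrate(net, x0, (0.0, 5.0), t_eval=t)
        ref = solve_ivp(kinetic_rhs, (0.0, 5.0), x0, t_eval=t, rtol=1e-10, atol=1e-14)
        assert np.allclose(traj.x, ref.y, rtol=1e-6, atol=1e-12)

    def test_moiety_conservation_along_trajectory(self, enzyme_network):
        net = enzyme_network
        traj = bb.integrate(net, net.x0(), (0.0, 100.0), t_eval=np.linspace(0, 100, 50))
        for g in net.conserved_moieties():
            totals = g @ traj.x
            assert np.max(np.abs(totals - totals[0])) <= 1e-6 * abs(totals[0])

    def test_rejects_negative_initial_state(self, enzyme_network):
        with pytest.raises(ValueError):
            bb.integrate(enzyme_network, np.array([-1.0, 1, 1, 1]), (0, 1.0))


class TestFindSteadyState:
    def test_closed_system_reaches_detailed_balance(self, enzyme_network):
        ss = find_steady_state(enzyme_network)
        aff = bb.reaction_affinities(enzyme_network, ss.x)["A"]
        assert np.allclose(aff, 0.0, atol=1e-5)  # J/mol, ~1e-9 RT
        assert np.allclose(ss.fluxes, 0.0, atol=1e-8)

    def test_chemostatted_chain_matches_linear_algebra(self):
        """A <-> B <-> C with A, C clamped: solve the linear steady state."""
        K = {"A": 1.0, "B": 2.0, "C": 0.5}
        kap = {"r1": 1.0, "r2": 3.0}
        mod = bb.network_from_reactions(
            "chain", K,
            {
                "r1": (bb.MassAction(kap["r1"]), ["A"], ["B"]),
                "r2": (bb.MassAction(kap["r2"]), ["B"], ["C"]),
            },
        )
        xA, xC = 2.0, 0.1
        net = bb.BondGraphModel(
            mod, chemostats={"A": xA, "C": xC}, initial={"B": 0.0}
        ).network()
        ss = find_steady_state(net)
        # dB/dt = k1 KA xA - k1 KB xB - k2 KB xB + k2 KC xC = 0
        xB = (kap["r1"] * K["A"] * xA + kap["r2"] * K["C"] * xC) / (
            (kap["r1"] + kap["r2"]) * K["B"]
        )
        assert ss["B"] == pytest.approx(xB, rel=1e-9)

    def test_already_steady_input_returns_itself(self, glycolysis_trio):
        net, x_ref = glycolysis_trio["GK"], glycolysis_trio["x_ref"]
        ss = find_steady_state(net, x_ref)
        assert np.allclose(ss.x, x_ref, rtol=1e-12)

    def test_steady_state_is_a_fixed_point(self, glycolysis_trio):
        net, x_ref = glycolysis_trio["GK"], glycolysis_trio["x_ref"]
        traj = bb.integrate(net, x_ref, (0.0, 1e4), t_eval=np.array([0.0, 1e4]))
        assert np.allclose(traj.x[:, -1], x_ref, rtol=1e-6)

    def test_nonconvergence_reports_residual(self):
        net = ab_network(x0=(1.0, 0.0))
        with pytest.raises(IntegrationError, match="residual"):
            find_steady_state(net, tol=1e-30, max_horizon=2.0)


class TestResponseTime:
    def test_exponential_decay_closed_form(self):
        """d(t) = d0 e^{-t/tau} crosses 5% for the last time at tau ln 20."""
        tau = 2.5
        t = np.linspace(0, 12 * tau, 4000)
        d = 3.0 * np.exp(-t / tau)
        assert response_time(t, d) == pytest.approx(tau * math.log(20.0), rel=1e-3)

    def test_scale_invariance_and_zero_case(self):
        t = np.linspace(0, 10, 200)
        d = np.exp(-t) * (1 + 0.3 * np.sin(4 * t))
        assert response_time(t, d) == response_time(t, 17.0 * d)
        assert response_time(t, np.zeros_like(t)) == 0.0

    def test_last_crossing_wins_for_non_monotone_deviation(self):
        t = np.linspace(0, 10, 1001)
        d = np.exp(-t)
        d[t > 8] = 0.2  # late rebound above the 5% threshold
        assert response_time(t, d) == pytest.approx(10.0)


class TestPerturbations:
    def test_unit_factor_is_a_no_op(self, glycolysis_trio):
        net, x_ref = glycolysis_trio["GK"], glycolysis_trio["x_ref"]
        ss = find_steady_state(net, x_ref)
        res = bb.perturb_internal(net, "F6P", factor=1.0, steady_state=ss,
                                  t_init=1.0, max_horizon=4.0)
        assert np.max(res.deviation) == pytest.approx(0.0, abs=1e-10)
        assert res.response_time == 0.0

    def test_internal_perturbation_returns_to_reference(self, glycolysis_trio):
        net, x_ref = glycolysis_trio["GK"], glycolysis_trio["x_ref"]
        ss = find_steady_state(net, x_ref)
        res = bb.perturb_internal(net, "PEP", factor=1.3, steady_state=ss, t_init=10.0)
        assert res.deviation[-1] < 0.01 * np.max(res.deviation)
        assert res.response_time > 0.0

    def test_internal_rejects_chemostat_species(self, glycolysis_trio):
        net, x_ref = glycolysis_trio["GK"], glycolysis_trio["x_ref"]
        ss = find_steady_state(net, x_ref)
        with pytest.raises(bb.BondGraphError, match="chemostat"):
            bb.perturb_internal(net, "ATP", steady_state=ss)

    def test_chemostat_perturbation_matches_linear_oracle(self):
        K = {"A": 1.0, "B": 2.0, "C": 0.5}
        mod = bb.network_from_reactions(
            "chain", K,
            {
                "r1": (bb.MassAction(1.0), ["A"], ["B"]),
                "r2": (bb.MassAction(3.0), ["B"], ["C"]),
            },
        )
        net = bb.BondGraphModel(
            mod, chemostats={"A": 2.0, "C": 0.1}, initial={"B": 0.0}
        ).network()
        ss = find_steady_state(net)
        res = bb.perturb_chemostat(net, "A", factor=1.3, steady_state=ss)
        xA = 2.0 * 1.3
        xB_new = (1.0 * 1.0 * xA + 3.0 * 0.5 * 0.1) / ((1.0 + 3.0) * 2.0)
        xB_old = float(ss["B"])
        assert res.steady_state_deviation == pytest.approx(
            abs(xB_new - xB_old), rel=1e-6
        )

    def test_signal_response_curve_flat_for_input_independent_output(self):
        # B's steady state is set entirely by the chemostats; A is an
        # isolated spectator pool acting as the "input"
        mod = bb.network_from_reactions(
            "flat", {"A": 1.0, "S": 1.0, "B": 1.0, "P": 1.0},
            {
                "r1": (bb.MassAction(1.0), ["S"], ["B"]),
                "r2": (bb.MassAction(1.0), ["B"], ["P"]),
                "r3": (bb.MassAction(1.0), ["A"], ["A"]),
            },
        )
        net = bb.BondGraphModel(
            mod, chemostats={"S": 1.0, "P": 1.0}, initial={"B": 0.0, "A": 1.0}
        ).network()
        res = bb.signal_response_curve(net, "A", np.geomspace(0.1, 10, 4), ["B"])
        curve = res["outputs"]["B"]
        assert np.allclose(curve, curve[0], rtol=1e-6)
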