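"""Core network construction, integration and serialization."""

import numpy as np
import pytest

from erbbqsp.network_model import (
    AVOGADRO,
    CompiledNetwork,
    ConfigurationError,
    ParameterSet,
    Protocol,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
    ValidationError,
    build_erbb_network,
    network_from_sbml,
    network_to_sbml,
    observable_timeseries,
    receptors_to_concentration,
    simulate,
    steady_state,
)

from conftest import make_binding_toy


class TestReceptorsToConcentration:
    def test_zero_count(self):
        assert receptors_to_concentration(0.0) == 0.0

    def test_avogadro_consistency(self):
        # N_A * 1e-9 receptors in 1e-9 l is 1 mol/l = 1e9 nmol/l
        count = AVOGADRO * 1e-9
        assert receptors_to_concentration(count, volume=1e-9) == pytest.approx(1e9)

    def test_pericellular_default(self):
        # 2e5 / (6.022e23 * 1e-12) = 3.321e-7 mol/l = 332.1 nmol/l
        assert receptors_to_concentration(2e5) == pytest.approx(332.11, rel=1e-3)

    def test_invalid_volume(self):
        with pytest.raises(ValidationError):
            receptors_to_concentration(1.0, volume=0.0)


class TestBuildNetwork:
    def test_documented_topology_counts(self, default_network):
        # independent enumeration (docs/topology.md): species by class and
        # reactions by class, summed by hand
        n_dimers, n_erbb3_dimers = 8, 5
        species = 2 + 3 + 2 + 3 + 3 * n_dimers + 2 * n_erbb3_dimers
        reactions = 2 + 5 + 3 + 5 * n_dimers + 7 * n_erbb3_dimers + 1
        assert len(default_network.species) == species == 44
        assert len(default_network.reactions) == reactions == 86

    def test_default_dimer_set_excludes_erbb3_homodimer(self, default_network):
        names = set(default_network.species_names)
        for dimer in ("EGFR:EGFR", "EGFR:HER2", "EGFR:ErbB3", "HER2:HER2", "HER2:ErbB3"):
            assert dimer in names
        assert "ErbB3:ErbB3" not in names

    def test_her2_zero_keeps_her2_dimers_empty(self, hrg_protocol):
        net = build_erbb_network({"HER2": 0.0})
        res = simulate(net, hrg_protocol)
        for i, name in enumerate(res.species_names):
            if "HER2" in name:
                assert np.allclose(res.state_matrix[i, :], 0.0, atol=1e-9), name

    def test_btc_requires_erbb3_route(self):
        # without the BTC:EGFR->ErbB3 route (and with basal dimerization
        # silenced) BTC has no path to phospho-ErbB3 at all
        net = build_erbb_network(
            parameter_overrides={"kon_dim_const": 0.0},
            btc_erbb3_route=False,
        )
        prot = Protocol(30.0, events=((0.0, "BTC", 1.0, "add"),),
                        readout_times=tuple(np.arange(0.0, 61.0, 5.0)))
        res = simulate(net, prot)
        assert np.allclose(observable_timeseries(res, "p-ErbB3"), 0.0, atol=1e-9)
        # sanity: with the route restored the same stimulus does signal
        net2 = build_erbb_network(parameter_overrides={"kon_dim_const": 0.0})
        res2 = simulate(net2, prot)
        assert observable_timeseries(res2, "p-ErbB3").max() > 100

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            build_erbb_network(parameter_overrides={"not_a_rate": 1.0})

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            build_erbb_network({"ErbB3": -5.0})


class TestSimulate:
    def test_zero_state_is_fixed_point(self, default_network):
        net = default_network.with_initial(
            {s.name: 0.0 for s in default_network.species}
        )
        res = simulate(net, Protocol(30.0, readout_times=(60.0,)))
        assert np.allclose(res.state_matrix, 0.0)

    def test_binding_toy_equilibrium_closed_form(self, binding_toy):
        a0, b0 = 100.0, 60.0
        kd = 0.5 / 0.02  # kr/kf in molecules
        # C* solves C^2 - (a0+b0+kd) C + a0 b0 = 0 (smaller root)
        s = a0 + b0 + kd
        c_star = (s - np.sqrt(s * s - 4 * a0 * b0)) / 2
        res = simulate(binding_toy, Protocol(0.0, readout_times=(2000.0,)))
        assert res.observable_traces["C"][-1] == pytest.approx(c_star, rel=1e-6)

    def test_default_network_matches_euler_oracle(self, default_network):
        """Adaptive solver against a brute-force fixed-step Euler integration."""
        comp = CompiledNetwork(default_network)
        dt = 1e-3
        y = comp.initial_state()
        # 30 min equilibration + 30 min of 1 nmol/l HRG
        for _ in range(int(30 / dt)):
            y = y + dt * comp.rhs(0.0, y)
        y[comp.index["HRG"]] += comp.to_molecules(comp.index["HRG"], 1.0)
        checkpoints = {}
        for step in range(int(30 / dt)):
            y = y + dt * comp.rhs(0.0, y)
            t = (step + 1) * dt
            if abs(t - round(t)) < dt / 2 and round(t) in (5, 10, 20, 30):
                checkpoints[round(t)] = comp.to_native(y)

        prot = Protocol(30.0, events=((0.0, "HRG", 1.0, "add"),),
                        readout_times=(5.0, 10.0, 20.0, 30.0))
        res = simulate(default_network, prot)
        weights = default_network.observables["p-ErbB3"]
        for t, y_native in checkpoints.items():
            euler = sum(w * y_native[comp.index[sp]] for sp, w in weights.items())
            i = np.argmin(np.abs(res.time_grid - t))
            assert res.observable_traces["p-ErbB3"][i] == pytest.approx(euler, rel=1e-3)

    def test_hrg_response_rises_then_relaxes(self, default_network, hrg_protocol):
        res = simulate(default_network, hrg_protocol)
        trace = observable_timeseries(res, "p-ErbB3")
        peak = np.argmax(trace)
        assert trace[peak] > 10 * trace[0]
        assert 0 < peak < len(trace) - 1
        assert trace[-1] < trace[peak]

    def test_determinism_bit_identical(self, default_network, hrg_protocol):
        a = simulate(default_network, hrg_protocol)
        b = simulate(default_network, hrg_protocol)
        assert np.array_equal(a.state_matrix, b.state_matrix)
        for obs in a.observable_traces:
            assert np.array_equal(a.observable_traces[obs], b.observable_traces[obs])

    def test_non_negativity(self, default_network, hrg_protocol):
        res = simulate(default_network, hrg_protocol)
        assert res.state_matrix.min() >= -10 * 1e-8

    def test_event_unknown_species_rejected(self, default_network):
        prot = Protocol(30.0, events=((0.0, "EGF", 1.0, "add"),), readout_times=(10.0,))
        with pytest.raises(ValidationError):
            simulate(default_network, prot)

    def test_protocol_validation(self):
        with pytest.raises(ValidationError):
            Protocol(30.0, events=((5.0, "HRG", 1.0, "add"), (0.0, "BTC", 1.0, "add")))
        with pytest.raises(ValidationError):
            Protocol(-1.0)
        with pytest.raises(ValidationError):
            Protocol(0.0, events=((0.0, "HRG", 1.0, "replace"),))


class TestConservation:
    @pytest.mark.parametrize("ligands", [(), (("HRG", 1.0),), (("HRG", 1.0), ("BTC", 2.0))])
    def test_receptor_mass_conserved_without_degradation(self, ligands):
        net = build_erbb_network(parameter_overrides={"kdeg": 0.0})
        events = tuple((0.0, sp, amt, "add") for sp, amt in ligands)
        prot = Protocol(30.0, events=events, readout_times=tuple(np.arange(0.0, 121.0, 10.0)))
        res = simulate(net, prot)
        content = net.metadata["receptor_content"]
        for receptor in ("EGFR", "HER2", "ErbB3"):
            total = np.zeros(len(res.time_grid))
            for sp, copies in content.items():
                if copies.get(receptor):
                    total += copies[receptor] * res.state_matrix[res.species_names.index(sp), :]
            assert np.max(np.abs(total / total[0] - 1.0)) < 1e-6, receptor


class TestSteadyState:
    def test_symmetric_isomerization_equalizes(self):
        params = ParameterSet()
        params.set("k", 1.0, "1/min", "")
        net = ReactionNetwork(
            [SpeciesDef("A", "cytosol", 10.0), SpeciesDef("B", "cytosol", 0.0)],
            [Reaction((("A", 1),), (("B", 1),), "k", "k", "iso")],
            params, {},
        )
        state, converged = steady_state(net, tol=1e-8)
        assert converged
        assert state["A"] == pytest.approx(state["B"], rel=1e-6)

    def test_derivatives_below_tol_at_convergence(self, binding_toy):
        state, converged = steady_state(binding_toy, tol=1e-8)
        assert converged
        comp = CompiledNetwork(binding_toy)
        y = np.array([state[n] for n in comp.names])
        dy = comp.rhs(0.0, y)
        assert np.max(np.abs(dy) / (np.abs(y) + 1e-9)) < 1e-8

    def test_default_network_equilibration_near_quasi_steady_state(self, default_network):
        # with degradation on, the only fixed point is the empty state
        # (receptors decay exponentially), so the long-horizon comparison
        # uses the degradation-balanced network
        res = simulate(default_network, Protocol(30.0, readout_times=(0.0,)))
        state, converged = steady_state(
            default_network, parameter_overrides={"kdeg": 0.0}, tol=1e-6
        )
        assert converged
        for receptor in ("EGFR", "HER2", "ErbB3"):
            i = res.species_names.index(receptor)
            assert res.state_matrix[i, -1] == pytest.approx(state[receptor], rel=0.05)

    def test_degrading_network_flags_non_convergence(self, default_network):
        _, converged = steady_state(default_network, tol=1e-7, max_time=2000.0)
        assert not converged


class TestObservables:
    def test_single_phospho_dimer_counts_for_both_receptors(self, default_network):
        net = default_network.with_initial(
            {s.name: 0.0 for s in default_network.species} | {"p:EGFR:ErbB3": 123.0}
        )
        res = simulate(net, Protocol(0.0, readout_times=(0.0,)),
                       solver_opts={"atol": 1e-12})
        assert res.observable_traces["p-ErbB3"][0] == pytest.approx(123.0, abs=1e-6)
        assert res.observable_traces["p-EGFR"][0] == pytest.approx(123.0, abs=1e-6)

    def test_hand_summed_erbb3_total(self, default_network):
        amounts = {"p:HER2:ErbB3": 10.0, "p:HRG:ErbB3:EGFR@endo": 20.0,
                   "p:BTC:EGFR:ErbB3:PI3K": 30.0}
        net = default_network.with_initial(
            {s.name: 0.0 for s in default_network.species} | amounts
        )
        res = simulate(net, Protocol(0.0, readout_times=(0.0,)))
        assert res.observable_traces["p-ErbB3"][0] == pytest.approx(60.0, rel=1e-9)

    def test_unknown_observable_rejected(self, default_network, hrg_protocol):
        res = simulate(default_network, hrg_protocol)
        with pytest.raises(KeyError):
            observable_timeseries(res, "p-Erk")


class TestSBMLRoundTrip:
    def test_round_trip_exact(self, default_network):
        doc = network_to_sbml(default_network)
        net2 = network_from_sbml(doc)
        assert [s.name for s in net2.species] == default_network.species_names
        for a, b in zip(default_network.species, net2.species):
            assert (a.compartment, a.initial_amount, a.tags) == (
                b.compartment, b.initial_amount, b.tags)
        assert len(net2.reactions) == len(default_network.reactions)
        for a, b in zip(default_network.reactions, net2.reactions):
            assert (a.reactants, a.products, a.kf, a.kr) == (
                b.reactants, b.products, b.kf, b.kr)
        for name in default_network.parameters:
            assert net2.parameters[name] == default_network.parameters[name]
            assert net2.parameters.unit(name) == default_network.parameters.unit(name)
        assert net2.observables == default_network.observables

    def test_round_trip_simulates_identically(self, default_network, hrg_protocol):
        net2 = network_from_sbml(network_to_sbml(default_network))
        a = simulate(default_network, hrg_protocol)
        b = simulate(net2, hrg_protocol)
        assert np.array_equal(a.state_matrix, b.state_matrix)


def test_make_binding_toy_validates():
    toy = make_binding_toy()
    assert len(toy.reactions) == 1
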