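"""Antibody, bispecific and TKI mechanism behavior."""

import numpy as np
import pytest
from scipy.optimize import brentq

from erbbqsp.drug_mechanisms import (
    BispecificParams,
    BlockerParams,
    TKIParams,
    TopologyError,
    extend_with_bispecific,
    extend_with_egfr_tki,
    extend_with_erbb3_blocker,
)
from erbbqsp.dose_response import default_doses, fit_ic50, simulate_dose_response
from erbbqsp.network_model import (
    ParameterSet,
    Protocol,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
    build_erbb_network,
    observable_timeseries,
    simulate,
)


def _peak(network, observable, drugs, ligands, horizon=60.0):
    events = [(0.0, sp, dose, "set") for sp, dose in drugs]
    events += [(30.0, lig, amt, "add") for lig, amt in ligands]
    prot = Protocol(30.0, events=tuple(sorted(events)),
                    readout_times=tuple(np.arange(30.0, 30.0 + horizon + 1, 1.0)))
    res = simulate(network, prot)
    mask = res.time_grid >= 30.0
    return observable_timeseries(res, observable)[mask].max()


@pytest.fixture(scope="module")
def base():
    return build_erbb_network()


@pytest.fixture(scope="module")
def blocked(base):
    return extend_with_erbb3_blocker(base, BlockerParams())


@pytest.fixture(scope="module")
def tki(base):
    return extend_with_egfr_tki(base, TKIParams())


class TestZeroDoseEquivalence:
    @pytest.mark.parametrize("mechanism,params", [
        (extend_with_erbb3_blocker, BlockerParams()),
        (extend_with_bispecific, BispecificParams()),
        (extend_with_egfr_tki, TKIParams()),
    ])
    def test_trajectories_identical_at_zero_dose(self, base, mechanism, params):
        extended = mechanism(base, params)
        prot = Protocol(30.0, events=((0.0, "HRG", 1.0, "add"),),
                        readout_times=tuple(np.arange(0.0, 61.0, 5.0)))
        ref = simulate(base, prot)
        ext = simulate(extended, prot)
        for obs in ref.observable_traces:
            np.testing.assert_allclose(
                ext.observable_traces[obs], ref.observable_traces[obs],
                rtol=1e-9, atol=1e-9,
            )


class TestBlocker:
    def test_requires_erbb3(self):
        params = ParameterSet()
        params.set("k", 1.0, "1/min", "")
        bare = ReactionNetwork([SpeciesDef("X", "membrane", 1.0)], [], params, {})
        with pytest.raises(TopologyError):
            extend_with_erbb3_blocker(bare, BlockerParams())

    def test_saturating_dose_abolishes_hrg_response(self, base, blocked):
        # pre-incubation with 1000x kd, then 10 nmol/l HRG
        ratio = _peak(blocked, "p-ErbB3", [("AB", 200.0)], [("HRG", 10.0)]) / \
            _peak(base, "p-ErbB3", [], [("HRG", 10.0)])
        assert ratio < 0.05

    def test_total_erbb3_downregulation_monotone(self, base, blocked):
        times = tuple(np.arange(0.0, 241.0, 5.0))
        ref = simulate(base, Protocol(30.0, readout_times=times))
        drug = simulate(blocked, Protocol(
            30.0, events=((0.0, "AB", 10.0, "set"),), readout_times=times))
        t_ref = observable_timeseries(ref, "total-ErbB3")
        t_drug = observable_timeseries(drug, "total-ErbB3")
        assert np.all(t_drug <= t_ref + 1e-6)
        assert t_drug[-1] < 0.5 * t_ref[-1]  # strong downregulation

    def test_competition_toy_matches_root_finding_oracle(self):
        """One receptor, ligand vs blocker; equilibrium from the coupled
        competition equations solved numerically, independent of the ODE."""
        r_tot, l_tot, b_tot = 1e4, 3e4, 5e4  # molecules
        kd_l, kd_b = 2e3, 5e2  # molecules (dissociation constants)

        params = ParameterSet()
        params.set("kon_l", 1e-4, "1/(molec/cell)/min", "")
        params.set("koff_l", 1e-4 * kd_l, "1/min", "")
        params.set("kon_b", 1e-4, "1/(molec/cell)/min", "")
        params.set("koff_b", 1e-4 * kd_b, "1/min", "")
        net = ReactionNetwork(
            [SpeciesDef("R", "membrane", r_tot), SpeciesDef("L", "membrane", l_tot),
             SpeciesDef("B", "membrane", b_tot), SpeciesDef("RL", "membrane", 0.0),
             SpeciesDef("RB", "membrane", 0.0)],
            [Reaction((("R", 1), ("L", 1)), (("RL", 1),), "kon_l", "koff_l", ""),
             Reaction((("R", 1), ("B", 1)), (("RB", 1),), "kon_b", "koff_b", "")],
            params, {"RL": {"RL": 1.0}},
        )
        res = simulate(net, Protocol(0.0, readout_times=(5000.0,)))
        rl_ode = res.observable_traces["RL"][-1]

        def free_receptor_residual(r):
            rl = r * l_tot / (kd_l + r)
            rb = r * b_tot / (kd_b + r)
            return r + rl + rb - r_tot

        r_free = brentq(free_receptor_residual, 1e-12, r_tot, xtol=1e-12, rtol=1e-14)
        rl_exact = r_free * l_tot / (kd_l + r_free)
        assert rl_ode == pytest.approx(rl_exact, rel=1e-6)

    def test_drug_mass_conserved_without_degradation(self, base):
        # degradation fraction 0: antibody recycles, total drug constant
        net = extend_with_erbb3_blocker(
            base, BlockerParams(degradation_fraction_on_internalization=0.0))
        prot = Protocol(30.0, events=((0.0, "AB", 5.0, "set"),),
                        readout_times=tuple(np.arange(0.0, 121.0, 10.0)))
        res = simulate(net, prot)
        conv = 1e9 / (6.02214076e23 * 1e-9)  # nmol/l per molecule
        total = res.state_matrix[res.species_names.index("AB"), :] / conv
        for sp in ("AB:ErbB3", "AB:ErbB3@endo"):
            total = total + res.state_matrix[res.species_names.index(sp), :]
        assert np.max(np.abs(total / total[0] - 1.0)) < 1e-6


class TestBispecific:
    def test_requires_her2(self):
        params = ParameterSet()
        params.set("k", 1.0, "1/min", "")
        bare = ReactionNetwork([SpeciesDef("ErbB3", "membrane", 1.0)], [], params, {})
        with pytest.raises(TopologyError):
            extend_with_bispecific(bare, BispecificParams())

    def test_no_her2_no_ternary_no_inhibition(self):
        net = extend_with_bispecific(build_erbb_network({"HER2": 0.0}), BispecificParams())
        curve = simulate_dose_response(net, "BS", default_doses(7), readout="p-ErbB3")
        i = net.species_names.index("BS:HER2:ErbB3")
        assert np.all(curve.responses > 0.97)
        prot = Protocol(30.0, events=((0.0, "BS", 1e3, "set"),), readout_times=(60.0,))
        res = simulate(net, prot)
        assert np.allclose(res.state_matrix[i, :], 0.0, atol=1e-9)

    def test_crosslink_factor_raises_potency(self, base):
        doses = default_doses(9)
        ic50s = {}
        for factor in (1.0, 100.0):
            net = extend_with_bispecific(base, BispecificParams(crosslink_factor=factor))
            curve = simulate_dose_response(net, "BS", doses)
            ic50s[factor] = fit_ic50(curve).ic50
        assert ic50s[100.0] < ic50s[1.0]

    def test_more_potent_at_high_her2(self):
        doses = default_doses(9)
        ic50s = {}
        for her2 in (1e4, 1e6):
            net = extend_with_bispecific(build_erbb_network({"HER2": her2}),
                                         BispecificParams())
            curve = simulate_dose_response(net, "BS", doses)
            ic50s[her2] = fit_ic50(curve).ic50
        assert ic50s[1e6] < ic50s[1e4]


class TestTKI:
    def test_requires_egfr(self):
        params = ParameterSet()
        params.set("k", 1.0, "1/min", "")
        bare = ReactionNetwork([SpeciesDef("ErbB3", "membrane", 1.0)], [], params, {})
        with pytest.raises(TopologyError):
            extend_with_egfr_tki(bare, TKIParams())

    def test_saturating_dose_abolishes_btc_response(self, base, tki):
        ratio = _peak(tki, "p-EGFR", [("TKI", 2e4)], [("BTC", 1.0)]) / \
            _peak(base, "p-EGFR", [], [("BTC", 1.0)])
        assert ratio < 0.05

    def test_her2_route_survives_tki_but_not_combination(self, base, blocked, tki):
        """Under HRG+BTC co-stimulation the TKI alone leaves most HRG-driven
        p-ErbB3 (HER2:ErbB3 route) intact; only blocker+TKI silences both."""
        ligands = [("HRG", 1.0), ("BTC", 1.0)]
        ref = _peak(base, "p-ErbB3", [], ligands)
        tki_only = _peak(tki, "p-ErbB3", [("TKI", 2e4)], ligands)
        both_net = extend_with_egfr_tki(blocked, TKIParams())
        both = _peak(both_net, "p-ErbB3", [("AB", 200.0), ("TKI", 2e4)], ligands)
        assert tki_only > 0.5 * ref
        assert both < 0.05 * ref
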