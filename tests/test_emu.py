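import time

import numpy as np
import pytest

from avdflux.emu import (
    EMUNode,
    EMUSimulator,
    TracerSpec,
    decompose_emu,
    glucose_1_13c,
    glucose_u13c_mix,
    natural_glucose,
    simulate_mids,
    substrate_mid,
)
from avdflux.fitting import FluxParameterization
from avdflux.isotopes import NATURAL_13C, natural_carbon_mid
from avdflux.network import AtomMapVariant, FluxVector, NetworkModel, Reaction

from _oracle import isotopomer_mids


def toy_fluxes(name):
    if name == "linear":
        return FluxVector(
            net={"upt": 100.0, "r1": 100.0, "r2": 100.0, "r3": 100.0, "out": 100.0}
        )
    if name == "cleave":
        return FluxVector(
            net={"upt": 100.0, "cleave": 60.0, "cond": 60.0, "bypass": 40.0, "out": 100.0},
            exchange={"cleave": 25.0},
        )
    return FluxVector(
        net={"upt": 100.0, "intact": 70.0, "cleave": 30.0, "recomb": 30.0, "out": 100.0}
    )


def toy_targets(name):
    if name == "linear":
        return [("D", (1, 2)), ("B", (1,))]
    if name == "cleave":
        return [("R", (1, 2, 3, 4)), ("R", (1, 2)), ("P", (1, 2)), ("S", (1, 2, 3, 4))]
    return [("P", (1, 2)), ("X", (1,))]


def toy_tracer(name):
    n = {"linear": 2, "cleave": 4, "split_recombine": 2}[name]
    return TracerSpec("S.ext", (("1" + "0" * (n - 1), 0.5), ("U", 0.5)), purity=0.99)


class TestSubstrateMid:
    def test_first_position_tracer_single_atom(self):
        mid = substrate_mid(glucose_1_13c(), (1,), 6)
        assert mid == pytest.approx([0.01, 0.99], abs=1e-12)

    def test_u13c_mix_three_carbon_intact_unit(self):
        mid = substrate_mid(glucose_u13c_mix(), (1, 2, 3), 6)
        natural = natural_carbon_mid(3)
        expected = 0.5 * natural
        expected = expected.copy()
        # labeled component: each position 13C with p = 0.99
        p = 0.99
        labeled = np.array(
            [(1 - p) ** 3, 3 * p * (1 - p) ** 2, 3 * p**2 * (1 - p), p**3]
        )
        expected += 0.5 * labeled
        assert np.allclose(mid, expected, atol=1e-12)
        assert mid[3] == pytest.approx(0.5 * 0.99**3, abs=1e-5)

    def test_unlabeled_single_carbon_is_natural(self):
        mid = substrate_mid(natural_glucose(), (4,), 6)
        assert mid == pytest.approx([1 - NATURAL_13C, NATURAL_13C], abs=1e-15)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TracerSpec("S.ext", (("10", 0.4), ("01", 0.4)))


class TestDecomposition:
    def test_two_node_linear_chain(self):
        model = NetworkModel(
            reactions=[
                Reaction("feed", ["A.ext"], ["A"], [AtomMapVariant(("ab",), ("ab",))]),
                Reaction("r", ["A"], ["B"], [AtomMapVariant(("ab",), ("ab",))]),
                Reaction("out", ["B"], ["B.ext"], [AtomMapVariant(("ab",), ("ab",))]),
            ]
        )
        nodes = decompose_emu(model, [("B", (1, 2))])
        assert set(nodes) == {EMUNode("A", (1, 2)), EMUNode("B", (1, 2))}

    def test_cleave_network_matches_hand_enumeration(self, toy_models):
        nodes = decompose_emu(toy_models["cleave"], [("R", (1, 2, 3, 4))])
        expected = {
            EMUNode("R", (1, 2, 3, 4)),
            EMUNode("S", (1, 2, 3, 4)),
            EMUNode("S", (1, 2)),
            EMUNode("S", (3, 4)),
            EMUNode("P", (1, 2)),
            EMUNode("Q", (1, 2)),
        }
        assert set(nodes) == expected

    def test_central_network_decomposition_bounded(self, central_model):
        from avdflux.isotopes import load_fragments

        frags = load_fragments()
        nodes = decompose_emu(central_model, [(f.metabolite, f.atoms) for f in frags.values()])
        assert max(n.size for n in nodes) <= 6
        assert len(nodes) > 20

    def test_disconnected_target_rejected(self):
        model = NetworkModel(
            reactions=[
                Reaction("feed", ["A.ext"], ["A"], [AtomMapVariant(("ab",), ("ab",))]),
                Reaction("r", ["A"], ["B"], [AtomMapVariant(("ab",), ("ab",))]),
                Reaction("out", ["B"], ["B.ext"], [AtomMapVariant(("ab",), ("ab",))]),
            ]
        )
        with pytest.raises((KeyError, ValueError)):
            decompose_emu(model, [("C", (1,))])


class TestOracleEquivalence:
    @pytest.mark.parametrize("name", ["linear", "cleave", "split_recombine"])
    def test_matches_brute_force_enumeration(self, toy_models, name):
        model = toy_models[name]
        fv = toy_fluxes(name)
        tracer = toy_tracer(name)
        targets = toy_targets(name)
        sim = EMUSimulator(model, targets)
        got = sim.simulate(fv, tracer)
        expected = isotopomer_mids(model, fv, tracer, targets)
        for met, atoms in targets:
            node = EMUNode(met, tuple(atoms))
            assert np.allclose(got[node], expected[(met, tuple(sorted(atoms)))], atol=1e-9), (
                name, met, atoms,
            )

    def test_central_network_spot_check_against_oracle(self, central_model):
        par = FluxParameterization(
            central_model, {"upt": 100.0, "lys_out": 0.0, "avd_out": 31.6},
            free_reactions=["oxppp", "gapn", "mae"],
        )
        fv = FluxVector(
            net=par.net_fluxes(np.array([40.0, 80.0, 10.0])),
            exchange={"pgi": 30.0, "tkt1": 8.0, "tal": 8.0, "tkt2": 8.0},
        )
        targets = [("PYR", (1, 2, 3)), ("OAA", (1, 2, 3, 4)), ("LYS", (1, 2, 3, 4, 5, 6))]
        sim = EMUSimulator(central_model, targets)
        got = sim.simulate(fv, glucose_1_13c())
        expected = isotopomer_mids(
            central_model, fv, glucose_1_13c(), targets, n_iter=20000, tol=1e-12
        )
        for met, atoms in targets:
            assert np.allclose(
                got[EMUNode(met, atoms)], expected[(met, atoms)], atol=1e-8
            ), met

    def test_toy_oracle_suite_is_fast(self, toy_models):
        start = time.time()
        for name, model in toy_models.items():
            sim = EMUSimulator(model, toy_targets(name))
            sim.simulate(toy_fluxes(name), toy_tracer(name))
            isotopomer_mids(model, toy_fluxes(name), toy_tracer(name), toy_targets(name))
        assert time.time() - start < 10.0


class TestSimulatorProperties:
    def test_linear_pathway_is_flux_invariant(self, toy_models):
        model = toy_models["linear"]
        tracer = toy_tracer("linear")
        sim = EMUSimulator(model, [("D", (1, 2))])
        for scale in (1.0, 0.3, 42.0):
            fv = toy_fluxes("linear").scaled(scale)
            got = sim.simulate(fv, tracer)[EMUNode("D", (1, 2))]
            src = substrate_mid(tracer, (1, 2), 2)
            assert np.allclose(got, src, atol=1e-12)

    def test_mid_normalization_preserved(self, central_model):
        par = FluxParameterization(
            central_model, {"upt": 100.0, "lys_out": 0.0, "avd_out": 31.6},
            free_reactions=["oxppp", "gapn", "mae"],
        )
        fv = FluxVector(
            net=par.net_fluxes(np.array([55.0, 20.0, 25.0])),
            exchange={"pgi": 70.0, "tkt1": 15.0, "tal": 5.0, "tkt2": 12.0},
        )
        frags = {"a": ("PYR", (1, 2, 3)), "b": ("LYS", (1, 2, 3, 4, 5, 6)), "c": ("P5P", (1, 2, 3, 4, 5))}
        for tracer in (glucose_1_13c(), glucose_u13c_mix()):
            for mid in simulate_mids(central_model, fv, tracer, frags).values():
                assert mid.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all(mid >= -1e-12)

    def test_unlabeled_tracer_gives_natural_mids(self, central_model):
        par = FluxParameterization(
            central_model, {"upt": 100.0, "lys_out": 0.0, "avd_out": 31.6},
            free_reactions=["oxppp", "gapn", "mae"],
        )
        fv = FluxVector(net=par.net_fluxes(np.array([40.0, 80.0, 10.0])))
        frags = {"pyr": ("PYR", (1, 2, 3)), "akg": ("AKG", (1, 2, 3, 4, 5))}
        for fid, mid in simulate_mids(central_model, fv, natural_glucose(), frags).items():
            n = len(mid) - 1
            assert np.allclose(mid, natural_carbon_mid(n), atol=1e-9)

    def test_scaling_homogeneity_on_central_network(self, central_model):
        par = FluxParameterization(
            central_model, {"upt": 100.0, "lys_out": 0.0, "avd_out": 31.6},
            free_reactions=["oxppp", "gapn", "mae"],
        )
        fv = FluxVector(
            net=par.net_fluxes(np.array([40.0, 80.0, 10.0])),
            exchange={"pgi": 30.0},
        )
        frags = {"lys": ("LYS", (1, 2, 3, 4, 5, 6))}
        a = simulate_mids(central_model, fv, glucose_u13c_mix(), frags)["lys"]
        b = simulate_mids(central_model, fv.scaled(2.5), glucose_u13c_mix(), frags)["lys"]
        assert np.allclose(a, b, atol=1e-12)

    def test_branch_ratio_sensor_matches_closed_form(self, toy_models):
        """M+1 of the recombination-product pool is linear in the branch ratio."""
        model = toy_models["split_recombine"]
        tracer = toy_tracer("split_recombine")
        p, a = 0.99, NATURAL_13C
        # tracer: 50% [1-13C] + 50% [U-13C2]; atom 1 is labeled in both
        # components (prob p), atom 2 only in the uniform one
        q1 = p
        q2 = 0.5 * a + 0.5 * p
        # intact route keeps within-molecule correlation of the two atoms
        m1_intact = 0.5 * (p * (1 - a) + (1 - p) * a) + 0.5 * 2 * p * (1 - p)
        # recombination draws atoms independently from well-mixed pools
        m1_recomb = q1 * (1 - q2) + (1 - q1) * q2
        sim = EMUSimulator(model, [("P", (1, 2))])
        for r in (0.0, 0.25, 0.7, 0.95):
            fv = FluxVector(
                net={"upt": 100.0, "intact": 100.0 * r, "cleave": 100.0 * (1 - r),
                     "recomb": 100.0 * (1 - r), "out": 100.0}
            )
            got = sim.simulate(fv, tracer)[EMUNode("P", (1, 2))]
            expected_m1 = r * m1_intact + (1 - r) * m1_recomb
            assert got[1] == pytest.approx(expected_m1, abs=1e-12)

    def test_zero_throughput_names_the_metabolite(self, toy_models):
        model = toy_models["cleave"]
        fv = FluxVector(
            net={"upt": 100.0, "cleave": 0.0, "cond": 0.0, "bypass": 100.0, "out": 100.0}
        )
        sim = EMUSimulator(model, [("P", (1, 2))])
        with pytest.raises(ValueError, match="P|Q"):
            sim.simulate(fv, toy_tracer("cleave"))
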