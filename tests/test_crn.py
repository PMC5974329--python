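"""Pair encoding, unit reaction schemes, network synthesis, preservation."""

import numpy as np
import pytest

from crnfrac.circuits import UnitSpec, build_function_circuit
from crnfrac.crn import (EncodingError, ReactionNetwork, WiringError,
                         decode_value, encode_value, make_input_preserving,
                         synthesize_network, unit_reactions)
from crnfrac.kinetics import build_rate_equations, integrate

from conftest import single_unit_circuit


class TestEncoding:
    def test_unipolar_split(self):
        p = encode_value(0.3, "unipolar", 1.0)
        assert (p.initial_0, p.initial_1) == (0.7, 0.3)

    def test_bipolar_zero_is_equal_concentrations(self):
        p = encode_value(0.0, "bipolar", 2.0)
        assert (p.initial_0, p.initial_1) == (1.0, 1.0)

    def test_bipolar_boundary(self):
        p = encode_value(-1.0, "bipolar", 1.0)
        assert (p.initial_0, p.initial_1) == (1.0, 0.0)

    @pytest.mark.parametrize("args,expected", [
        ((0.5, 0.5, "unipolar"), 0.5),
        ((0.25, 0.75, "bipolar"), 0.5),
        ((0.7, 0.3, "unipolar"), 0.3),
    ])
    def test_decode(self, args, expected):
        assert decode_value(*args) == pytest.approx(expected)

    def test_roundtrip_is_identity(self, rng):
        for _ in range(20):
            v = float(rng.uniform(-1, 1))
            pol = "bipolar" if v < 0 or rng.random() < 0.5 else "unipolar"
            total = float(rng.uniform(0.1, 10))
            p = encode_value(v, pol, total)
            assert decode_value(p.initial_0, p.initial_1, pol) == \
                pytest.approx(v, abs=1e-12)

    def test_out_of_range_and_empty(self):
        with pytest.raises(EncodingError):
            encode_value(1.2, "unipolar", 1.0)
        with pytest.raises(EncodingError):
            encode_value(0.5, "unipolar", 0.0)
        with pytest.raises(EncodingError):
            decode_value(0.0, 0.0, "unipolar")


class TestUnitReactions:
    def test_every_kind_emits_four_bimolecular_reactions(self):
        for kind in ("MULT_U", "NMULT_U", "MULT_B", "NMULT_B"):
            unit = UnitSpec(kind, ("a", "b"), "c")
            rxns = unit_reactions(unit, {"a": "A", "b": "B", "c": "C"})
            assert len(rxns) == 4
            assert all(len(r.reactants) == 2 and len(r.products) == 1
                       for r in rxns)

    def test_mux_pairs_data_with_select_members(self):
        unit = UnitSpec("MUX", ("a", "b", "s"), "c")
        rxns = unit_reactions(unit, {"a": "A", "b": "B", "s": "S", "c": "C"})
        as_sets = {frozenset(r.reactants) for r in rxns}
        assert as_sets == {frozenset({"A_1", "S_0"}), frozenset({"A_0", "S_0"}),
                           frozenset({"B_1", "S_1"}), frozenset({"B_0", "S_1"})}

    def test_nmult_is_mult_with_output_members_swapped(self):
        pairs = {"a": "A", "b": "B", "c": "C"}
        mult = unit_reactions(UnitSpec("MULT_U", ("a", "b"), "c"), pairs)
        nmult = unit_reactions(UnitSpec("NMULT_U", ("a", "b"), "c"), pairs)
        swap = {"C_0": "C_1", "C_1": "C_0"}
        assert [(r.reactants, swap[r.products[0]]) for r in mult] == \
            [(r.reactants, r.products[0]) for r in nmult]

    def test_unresolved_port_raises(self):
        with pytest.raises(WiringError):
            unit_reactions(UnitSpec("MULT_U", ("a", "b"), "c"), {"a": "A"})


class TestSynthesize:
    def test_exp_neg_network_counts(self):
        net = synthesize_network(build_function_circuit("exp_neg", 5), 0.3)
        assert len(net.reactions) == 32          # 8 unit quadruples
        assert net.output.polarity == "unipolar"

    def test_single_mult_counts(self):
        circ = single_unit_circuit("MULT_U", {"b": (0.5, "unipolar")})
        net = synthesize_network(circ, 0.5)
        assert len(net.reactions) == 4
        assert len(net.species) == 6

    def test_sine_at_zero_decodes_to_zero(self):
        from crnfrac.circuits import build_scaled_sine_circuit
        net = synthesize_network(build_scaled_sine_circuit(), 0.0)
        traj = integrate(net, 1e3)
        assert traj.final_output == pytest.approx(0.0, abs=1e-6)

    def test_network_text_roundtrip(self):
        net = synthesize_network(build_function_circuit("exp_neg", 5), 0.3)
        back = ReactionNetwork.from_text(net.to_text())
        assert back.to_text() == net.to_text()
        assert integrate(back, 1e2).final_output == pytest.approx(
            integrate(net, 1e2).final_output, abs=1e-12)


class TestInputPreserving:
    def _mult_net(self):
        circ = single_unit_circuit("MULT_U", {"b": (0.6, "unipolar")})
        return synthesize_network(circ, 0.5)

    def test_preserved_pair_is_constant_over_time(self):
        net = make_input_preserving(self._mult_net(), ["a"])
        traj = integrate(net, 1e3)
        a1 = traj.species_series("a_1")
        assert np.allclose(a1, a1[0], atol=1e-9)
        # and its rate law contribution is exactly zero
        model = build_rate_equations(net)
        rhs = model.rhs(0.0, model.initial_state())
        assert rhs[model.index["a_1"]] == 0.0

    def test_preserved_unit_still_computes_product(self):
        net = make_input_preserving(self._mult_net(), ["a"])
        assert integrate(net, 1e3).final_output == pytest.approx(0.3,
                                                                 abs=1e-6)

    def test_no_pairs_leaves_network_unchanged(self):
        net = self._mult_net()
        same = make_input_preserving(net, [])
        assert same.to_text() == net.to_text()

    def test_unknown_pair_raises(self):
        with pytest.raises(WiringError):
            make_input_preserving(self._mult_net(), ["nope"])


class TestKineticProperties:
    def test_input_ratio_conserved_along_trajectory(self):
        """Both members of every input pair are consumed proportionally,
        so each input's fractional reading is constant in time."""
        net = synthesize_network(build_function_circuit("exp_neg", 5), 0.37)
        traj = integrate(net, 1e3)
        interior = slice(1, 151, 3)   # 50 interior time points
        for name in net.input_pairs + net.constant_pairs:
            reading = traj.pair_reading(name)[interior]
            expected = net.pairs[name].value
            ok = ~np.isnan(reading)
            assert np.all(np.abs(reading[ok] - expected) < 1e-9), name

    @pytest.mark.parametrize("kind", ["MULT_U", "NMULT_U", "MULT_B",
                                      "NMULT_B"])
    def test_output_mass_equals_consumed_input(self, kind):
        pol = "bipolar" if kind.endswith("_B") else "unipolar"
        circ = single_unit_circuit(kind, {"b": (0.25 if pol == "unipolar"
                                                else -0.5, pol)})
        net = synthesize_network(circ, 0.6 if pol == "unipolar" else 0.4)
        traj = integrate(net, 1e3)
        a_left = traj.species_series("a_0")[-1] + traj.species_series("a_1")[-1]
        out = net.output
        c_tot = (traj.species_series(out.species_0)[-1]
                 + traj.species_series(out.species_1)[-1])
        assert c_tot == pytest.approx(1.0 - a_left, abs=1e-8)

    def test_bipolar_sign_symmetry(self, rng):
        """Mult output invariant under negating both inputs; negated
        under negating exactly one."""
        def run(a, b):
            circ = single_unit_circuit("MULT_B", {"b": (b, "bipolar")})
            return integrate(synthesize_network(circ, a), 1e3).final_output

        for _ in range(10):
            a, b = rng.uniform(-1, 1, size=2)
            base = run(a, b)
            assert run(-a, -b) == pytest.approx(base, abs=1e-7)
            assert run(-a, b) == pytest.approx(-base, abs=1e-7)

    def test_mult_b_saturated_inputs(self):
        circ = single_unit_circuit("MULT_B", {"b": (-1.0, "bipolar")})
        net = synthesize_network(circ, -1.0)
        assert integrate(net, 1e3).final_output == pytest.approx(1.0)

    def test_mult_u_identity_input(self):
        circ = single_unit_circuit("MULT_U", {"b": (0.6, "unipolar")})
        net = synthesize_network(circ, 1.0)
        assert integrate(net, 1e3).final_output == pytest.approx(0.6)


class TestRatePerturbation:
    """Equal rates within a unit underpin the exactness proofs; this
    quantifies the drift when rates are mismatched by up to 20%."""

    def test_unequal_rates_shift_output_but_modestly(self, rng):
        from dataclasses import replace
        circ = single_unit_circuit("MULT_U", {"b": (0.5, "unipolar")})
        net = synthesize_network(circ, 0.5)
        drifts = []
        for _ in range(5):
            factors = rng.uniform(0.8, 1.2, size=len(net.reactions))
            perturbed = ReactionNetwork(
                reactions=[replace(r, rate_constant=float(f * r.rate_constant))
                           for r, f in zip(net.reactions, factors)],
                pairs=dict(net.pairs), input_pairs=list(net.input_pairs),
                constant_pairs=list(net.constant_pairs),
                output_pair=net.output_pair)
            drifts.append(abs(integrate(perturbed, 1e3).final_output - 0.25))
        # the drift is real (rates are not "free") but stays bounded
        assert max(drifts) > 1e-6
        assert max(drifts) < 0.05
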