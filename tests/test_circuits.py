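"""Circuit builders: symbolic expansions, ideal evaluation, anchors."""

import math
from fractions import Fraction as F

import pytest

from crnfrac.circuits import (Circuit, CircuitError, build_function_circuit,
                              build_horner_circuit,
                              build_hybrid_sigmoid_circuit,
                              build_scaled_cosine_circuit,
                              build_scaled_sine_circuit,
                              evaluate_circuit_ideal,
                              expand_circuit_polynomial)
from crnfrac.series import (HornerChain, horner_factorize,
                            maclaurin_coefficients)


class TestHornerCircuit:
    def test_exp_neg_has_eight_elements_and_correct_expansion(self):
        chain = horner_factorize(maclaurin_coefficients("exp_neg", 5))
        circ = build_horner_circuit(chain)
        assert len(circ.units) == 8
        assert expand_circuit_polynomial(circ).exact == (
            F(1), F(-1), F(1, 2), F(-1, 6), F(1, 24), F(-1, 120))

    def test_single_nmult_for_one_minus_x(self):
        circ = build_horner_circuit(HornerChain((1.0, 1.0)))
        assert len(circ.units) == 1
        assert circ.units[0].kind == "NMULT_U"
        assert evaluate_circuit_ideal(circ, 0.3) == pytest.approx(0.7)

    def test_hand_expanded_degree_two_chain(self):
        circ = build_horner_circuit(HornerChain((1.0, 1.0, 0.5)))
        # 1 - x(1 - x/2) at x=1 -> 0.5
        assert evaluate_circuit_ideal(circ, 1.0) == pytest.approx(0.5)

    def test_nonmappable_chain_rejected(self):
        with pytest.raises(CircuitError):
            build_horner_circuit(HornerChain((1.0, 2.0)))

    @pytest.mark.parametrize("x", [i / 19 for i in range(20)])
    def test_ideal_evaluation_equals_chain_evaluation(self, x):
        chain = horner_factorize(maclaurin_coefficients("exp_neg", 7))
        circ = build_horner_circuit(chain)
        assert evaluate_circuit_ideal(circ, x) == pytest.approx(
            chain(x), abs=1e-12)


class TestScaledTrig:
    def test_sine_anchor_values(self):
        circ = build_scaled_sine_circuit()
        assert evaluate_circuit_ideal(circ, 0.2) == pytest.approx(0.1871,
                                                                  abs=5e-5)
        assert evaluate_circuit_ideal(circ, 0.0) == 0.0
        assert evaluate_circuit_ideal(circ, 1.0) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_sine_tracks_exact_function(self):
        # the fixed factorization's own approximation error grows toward
        # x = 1 (about 1.1e-3 at x = 0.9)
        circ = build_scaled_sine_circuit()
        for x in (0.1, 0.3, 0.5, 0.9):
            assert evaluate_circuit_ideal(circ, x) == pytest.approx(
                math.sin(math.pi * x) / math.pi, abs=1.5e-3)

    def test_cosine_anchor_values(self):
        circ = build_scaled_cosine_circuit()
        assert evaluate_circuit_ideal(circ, 0.0) == pytest.approx(0.1685,
                                                                  abs=5e-5)
        assert abs(evaluate_circuit_ideal(circ, 0.5)) < 1e-3
        assert evaluate_circuit_ideal(circ, 1.0) == pytest.approx(-0.1689,
                                                                  abs=5e-5)

    def test_cosine_output_is_bipolar(self):
        circ = build_scaled_cosine_circuit()
        assert circ.output_polarity == "bipolar"
        assert evaluate_circuit_ideal(circ, 0.8) < 0


class TestHybridSigmoid:
    @pytest.mark.parametrize("degree", [5, 7])
    def test_expansion_equals_truncated_sigmoid_series(self, degree):
        circ = build_hybrid_sigmoid_circuit(degree)
        expanded = expand_circuit_polynomial(circ)
        assert expanded.exact == maclaurin_coefficients("sigmoid",
                                                        degree).exact

    def test_endpoint_values(self):
        circ = build_hybrid_sigmoid_circuit(7)
        assert evaluate_circuit_ideal(circ, 0.0) == pytest.approx(0.5)
        assert evaluate_circuit_ideal(circ, 1.0) == pytest.approx(0.7311,
                                                                  abs=2e-4)
        assert evaluate_circuit_ideal(circ, -1.0) == pytest.approx(0.2689,
                                                                   abs=2e-4)

    def test_unsupported_degree(self):
        with pytest.raises(ValueError):
            build_hybrid_sigmoid_circuit(9)

    def test_bipolar_input_range_enforced(self):
        circ = build_hybrid_sigmoid_circuit(7)
        with pytest.raises(CircuitError):
            evaluate_circuit_ideal(circ, 1.5)


class TestFunctionCircuits:
    @pytest.mark.parametrize("fid", ["exp_neg", "sin", "cos", "log1p",
                                     "tanh", "sigmoid"])
    def test_expansion_matches_truncated_series(self, fid):
        circ = build_function_circuit(fid)
        degree = int(circ.name.rsplit("_d", 1)[1])
        expanded = expand_circuit_polynomial(circ)
        target = maclaurin_coefficients(fid, degree).exact
        assert expanded.exact[:len(target)] == target
        assert all(c == 0 for c in expanded.exact[len(target):])

    def test_exp_neg_values(self):
        circ = build_function_circuit("exp_neg", 5)
        assert evaluate_circuit_ideal(circ, 0.0) == 1.0
        assert evaluate_circuit_ideal(circ, 1.0) == pytest.approx(11 / 30)
        assert evaluate_circuit_ideal(circ, 0.3) == pytest.approx(0.74082,
                                                                  abs=1e-5)

    def test_constants_are_unit_interval(self, shipped_circuits):
        for name, circ in shipped_circuits.items():
            for port, val in circ.constants.items():
                lo = -1.0 if circ.polarity[port] == "bipolar" else 0.0
                assert lo <= val <= 1.0, (name, port, val)


def test_circuit_text_roundtrip(shipped_circuits):
    for circ in shipped_circuits.values():
        back = Circuit.from_text(circ.to_text())
        assert back.to_text() == circ.to_text()
        for x in (0.0, 0.5, 1.0):
            assert evaluate_circuit_ideal(back, x) == pytest.approx(
                evaluate_circuit_ideal(circ, x)
                if circ.input_polarity == "unipolar"
                else evaluate_circuit_ideal(circ, x), abs=1e-12)


def test_validate_rejects_cycles_and_unknown_ports():
    c = Circuit(primary_input="x")
    c.polarity["x"] = "unipolar"
    c.add_unit("MULT_U", ("x", "ghost"), "t1")
    c.output = "t1"
    with pytest.raises(CircuitError):
        c.validate()
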