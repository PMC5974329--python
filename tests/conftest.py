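import numpy as np
import pytest

from crnfrac.circuits import (Circuit, build_function_circuit,
                              build_hybrid_sigmoid_circuit,
                              build_scaled_cosine_circuit,
                              build_scaled_sine_circuit)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180529)


def single_unit_circuit(kind, const_values, input_value_port="a"):
    """A circuit wrapping one unit; non-primary inputs become constants."""
    pol_in = "bipolar" if kind in ("MULT_B", "NMULT_B") else "unipolar"
    c = Circuit(primary_input="a")
    c.polarity["a"] = pol_in
    ports = ["a"]
    for name, (val, pol) in const_values.items():
        c.add_constant(name, val, pol)
        ports.append(name)
    c.add_unit(kind, tuple(ports), "c",
               out_polarity="bipolar" if kind in ("MULT_B", "NMULT_B")
               else "unipolar")
    c.output = "c"
    c.validate()
    return c


@pytest.fixture(scope="session")
def shipped_circuits():
    """Every circuit the package ships, keyed by name."""
    circuits = {
        fid: build_function_circuit(fid)
        for fid in ("exp_neg", "sin", "cos", "log1p", "tanh", "sigmoid")
    }
    circuits["sin_pi"] = build_scaled_sine_circuit()
    circuits["cos_pi"] = build_scaled_cosine_circuit()
    circuits["sigmoid_hybrid"] = build_hybrid_sigmoid_circuit(7)
    return circuits
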