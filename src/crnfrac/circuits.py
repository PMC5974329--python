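"""Circuits of Mult/NMult/MUX units over fractionally-coded signals.

A circuit is a DAG of two- and three-input computational units.  Every
port carries a molecular pair; the *fraction* of a pair is the share of
its 1-species, ``[X1]/([X0]+[X1])``.  A port tagged unipolar decodes to
the fraction itself (range [0, 1]); a port tagged bipolar decodes to
``2*fraction - 1`` (range [-1, 1]).  Re-reading a pair under the other
polarity is free — no unit is needed — which is what hybrid-
representation circuits exploit.

Unit semantics in fraction space (a, b, s are input fractions):

========  =============================  decoded meaning
MULT_U    ``a*b``                        unipolar product
NMULT_U   ``1 - a*b``                    unipolar 1 - product
MUX       ``a*(1-s) + b*s``              scaled addition (either polarity)
MULT_B    ``(1+(2a-1)(2b-1))/2``         bipolar product
NMULT_B   ``(1-(2a-1)(2b-1))/2``         negated bipolar product
========  =============================  decoded meaning

The MUX formula is affine, so it implements scaled addition for
unipolar and bipolar data alike; its select is always unipolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

from .series import HornerChain, PowerPolynomial

__all__ = [
    "UnitSpec",
    "Circuit",
    "CircuitError",
    "UNIT_KINDS",
    "build_horner_circuit",
    "build_scaled_sine_circuit",
    "build_scaled_cosine_circuit",
    "build_hybrid_sigmoid_circuit",
    "evaluate_circuit_ideal",
    "expand_circuit_polynomial",
]

UNIT_KINDS = ("MULT_U", "NMULT_U", "MUX", "MULT_B", "NMULT_B")

UNIPOLAR = "unipolar"
BIPOLAR = "bipolar"


class CircuitError(ValueError):
    """Invalid circuit structure or an input outside a port's range."""


@dataclass(frozen=True)
class UnitSpec:
    """One computational unit: kind, ordered input ports, output port.

    Mult/NMult take two inputs; MUX takes three in the order
    (a, b, select).
    """

    kind: str
    inputs: Tuple[str, ...]
    output: str

    def __post_init__(self):
        if self.kind not in UNIT_KINDS:
            raise CircuitError(f"unknown unit kind {self.kind!r}")
        arity = 3 if self.kind == "MUX" else 2
        if len(self.inputs) != arity:
            raise CircuitError(
                f"{self.kind} takes {arity} inputs, got {len(self.inputs)}"
            )


@dataclass
class Circuit:
    """A DAG of units plus port polarity tags and constant bindings.

    ``constants`` maps a port name to its *decoded* value (in [0,1] for
    unipolar ports, [-1,1] for bipolar ones).
    """

    units: List[UnitSpec] = field(default_factory=list)
    polarity: Dict[str, str] = field(default_factory=dict)
    constants: Dict[str, float] = field(default_factory=dict)
    primary_input: str = "x"
    output: str = ""
    name: Optional[str] = None
    # optional exact rational view of the constants, for symbolic expansion
    exact_constants: Dict[str, Fraction] = field(default_factory=dict)

    def add_unit(self, kind: str, inputs: Tuple[str, ...], output: str,
                 out_polarity: str = UNIPOLAR) -> str:
        self.units.append(UnitSpec(kind, tuple(inputs), output))
        self.polarity[output] = out_polarity
        return output

    def add_constant(self, port: str, value, polarity: str = UNIPOLAR) -> str:
        fval = float(value)
        lo = 0.0 if polarity == UNIPOLAR else -1.0
        if not (lo <= fval <= 1.0):
            raise CircuitError(
                f"constant {port}={fval} outside {polarity} range [{lo}, 1]"
            )
        self.constants[port] = fval
        self.polarity[port] = polarity
        if isinstance(value, Fraction):
            self.exact_constants[port] = value
        return port

    @property
    def input_polarity(self) -> str:
        return self.polarity[self.primary_input]

    @property
    def output_polarity(self) -> str:
        return self.polarity[self.output]

    def producers(self, port: str) -> List[UnitSpec]:
        return [u for u in self.units if u.output == port]

    def validate(self) -> None:
        """Check acyclicity: each unit may only read already-defined ports.

        A port may be produced by several units (a shared output, as in
        the perceptron inner product); all its producers must appear
        before any reader.
        """
        defined = {self.primary_input, *self.constants}
        last_producer = {}
        for i, u in enumerate(self.units):
            last_producer[u.output] = i
        for i, u in enumerate(self.units):
            for p in u.inputs:
                if p not in defined and not (
                    p in last_producer and last_producer[p] < i
                ):
                    raise CircuitError(
                        f"unit {u.kind}->{u.output} reads undefined port {p!r}"
                    )
            if u.output in self.constants or u.output == self.primary_input:
                raise CircuitError(f"source port {u.output!r} also produced")
            defined.add(u.output)
        if self.output not in defined:
            raise CircuitError(f"output port {self.output!r} never produced")
        for p in self.polarity:
            if p not in defined:
                raise CircuitError(f"polarity tag for unknown port {p!r}")

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        lines = ["# circuit"]
        if self.name:
            lines.append(f"name: {self.name}")
        lines.append(f"input: {self.primary_input} {self.polarity[self.primary_input]}")
        lines.append(f"output: {self.output} {self.polarity[self.output]}")
        for port in sorted(self.constants):
            lines.append(
                f"const: {port} {self.polarity[port]} {self.constants[port]!r}"
            )
        for u in self.units:
            lines.append(
                f"unit: {u.kind} {' '.join(u.inputs)} -> {u.output}"
                f" {self.polarity[u.output]}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Circuit":
        c = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(":")
            key, rest = key.strip(), rest.strip()
            if key == "name":
                c.name = rest
            elif key == "input":
                port, pol = rest.split()
                c.primary_input = port
                c.polarity[port] = pol
            elif key == "output":
                port, pol = rest.split()
                c.output = port
                c.polarity[port] = pol
            elif key == "const":
                port, pol, val = rest.split()
                c.constants[port] = float(val)
                c.polarity[port] = pol
            elif key == "unit":
                spec, _, out = rest.partition("->")
                parts = spec.split()
                out_parts = out.split()
                c.units.append(UnitSpec(parts[0], tuple(parts[1:]), out_parts[0]))
                c.polarity[out_parts[0]] = out_parts[1]
            else:
                raise CircuitError(f"unparseable circuit line: {line!r}")
        c.validate()
        return c


# ---------------------------------------------------------------------------
# unit semantics in fraction space

def _unit_fraction(kind: str, args):
    if kind == "MULT_U":
        a, b = args
        return a * b
    if kind == "NMULT_U":
        a, b = args
        return 1 - a * b
    if kind == "MUX":
        a, b, s = args
        return a * (1 - s) + b * s
    if kind == "MULT_B":
        a, b = args
        return (1 + (2 * a - 1) * (2 * b - 1)) / 2
    if kind == "NMULT_B":
        a, b = args
        return (1 - (2 * a - 1) * (2 * b - 1)) / 2
    raise CircuitError(f"unknown unit kind {kind!r}")


def _to_fraction(value, polarity):
    return value if polarity == UNIPOLAR else (1 + value) / 2


def _from_fraction(frac, polarity):
    return frac if polarity == UNIPOLAR else 2 * frac - 1


def evaluate_circuit_ideal(circuit: Circuit, x: float) -> float:
    """Propagate exact unit math through the DAG; return the decoded output.

    ``x`` is the decoded value of the primary input and must lie in its
    polarity's range.
    """
    circuit.validate()
    pol_in = circuit.input_polarity
    lo = 0.0 if pol_in == UNIPOLAR else -1.0
    if not (lo <= x <= 1.0):
        raise CircuitError(f"input {x} outside {pol_in} range [{lo}, 1]")
    frac = {circuit.primary_input: _to_fraction(x, pol_in)}
    for port, val in circuit.constants.items():
        frac[port] = _to_fraction(val, circuit.polarity[port])
    out = _propagate(circuit, frac)
    return _from_fraction(out, circuit.output_polarity)


def _propagate(circuit: Circuit, frac: dict):
    """Run units in order; a multiply-produced port reads as the average
    of its producers' values (equal unit totals at completion)."""
    shared: Dict[str, list] = {}
    for u in circuit.units:
        if len(circuit.producers(u.output)) > 1:
            shared.setdefault(u.output, [])

    def read(port):
        if port in shared:
            vals = shared[port]
            return sum(vals) / len(vals)
        return frac[port]

    for u in circuit.units:
        val = _unit_fraction(u.kind, [read(p) for p in u.inputs])
        if u.output in shared:
            shared[u.output].append(val)
        else:
            frac[u.output] = val
    return read(circuit.output)


def expand_circuit_polynomial(circuit: Circuit) -> PowerPolynomial:
    """Symbolic power-form expansion of the circuit's decoded output.

    The expansion variable is the decoded primary-input value.  Used to
    verify builders against their intended factorized expressions.
    """
    import sympy

    circuit.validate()
    t = sympy.Symbol("t")
    frac = {circuit.primary_input: _to_fraction(t, circuit.input_polarity)}
    for port, val in circuit.constants.items():
        ex = circuit.exact_constants.get(port)
        sval = sympy.Rational(ex.numerator, ex.denominator) if ex is not None \
            else sympy.nsimplify(val, rational=True)
        frac[port] = _to_fraction(sval, circuit.polarity[port])
    expr = _from_fraction(_propagate(circuit, frac),
                          circuit.output_polarity)
    poly = sympy.Poly(sympy.expand(expr), t)
    coeffs = poly.all_coeffs()[::-1]
    exact = tuple(Fraction(int(c.p), int(c.q)) for c in
                  (sympy.Rational(c) for c in coeffs))
    return PowerPolynomial(
        coefficients=tuple(float(e) for e in exact),
        function_tag=circuit.name,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# builders

def build_horner_circuit(chain: HornerChain) -> Circuit:
    """Map a mappable Horner chain onto the alternating Mult/NMult cascade.

    Innermost stage: NMult(x, b_n) = 1 - b_n x.  Each outer stage i
    first scales by the constant b_i (a Mult unit, skipped when
    b_i = 1) and then forms 1 - x * (scaled) with an NMult.  A final
    Mult applies b_0 when b_0 != 1.
    """
    if not chain.mappable:
        raise CircuitError(
            "Horner chain is not mappable: some b_i outside [0, 1]"
        )
    b = chain.b_coefficients
    n = chain.degree
    if n < 1:
        raise CircuitError("degree-0 chain has no variable input")
    exact = chain.exact

    def bval(i):
        return exact[i] if exact is not None else b[i]

    c = Circuit(primary_input="x", name=chain.function_tag or "horner")
    c.polarity["x"] = UNIPOLAR
    step = 0

    def fresh():
        nonlocal step
        step += 1
        return f"t{step}"

    cb = c.add_constant(f"b{n}", bval(n), UNIPOLAR)
    cur = c.add_unit("NMULT_U", ("x", cb), fresh())
    for i in range(n - 1, 0, -1):
        if b[i] != 1.0:
            cb = c.add_constant(f"b{i}", bval(i), UNIPOLAR)
            cur = c.add_unit("MULT_U", (cur, cb), fresh())
        cur = c.add_unit("NMULT_U", ("x", cur), fresh())
    if b[0] != 1.0:
        cb = c.add_constant("b0", bval(0), UNIPOLAR)
        cur = c.add_unit("MULT_U", (cur, cb), fresh())
    c.output = cur
    c.validate()
    return c


def build_scaled_sine_circuit() -> Circuit:
    """Half-period scaled sine sin(pi*x)/pi on [0, 1].

    Ideal function: x(1-x^2)(1-0.4x^2)(1-0.2488x^2(1-0.2637x^2)),
    a published stochastic-logic factorization with all constants in
    [0, 1]; unipolar input and output.
    """
    c = Circuit(primary_input="x", name="sin_pi")
    c.polarity["x"] = UNIPOLAR
    F = Fraction
    c.add_constant("c1", F(2637, 10000))
    c.add_constant("c2", F(2488, 10000))
    c.add_constant("c3", F(4, 10))
    c.add_constant("one", F(1))
    c.add_unit("MULT_U", ("x", "x"), "sq")
    c.add_unit("NMULT_U", ("sq", "c1"), "g1")          # 1 - 0.2637 x^2
    c.add_unit("MULT_U", ("sq", "g1"), "g2")           # x^2 (1 - 0.2637 x^2)
    c.add_unit("NMULT_U", ("g2", "c2"), "g3")          # 1 - 0.2488 x^2 (...)
    c.add_unit("NMULT_U", ("sq", "c3"), "g4")          # 1 - 0.4 x^2
    c.add_unit("NMULT_U", ("sq", "one"), "g5")         # 1 - x^2
    c.add_unit("MULT_U", ("x", "g5"), "m1")            # x (1 - x^2)
    c.add_unit("MULT_U", ("m1", "g4"), "m2")
    c.add_unit("MULT_U", ("m2", "g3"), "m3")
    c.output = "m3"
    c.validate()
    return c


def build_scaled_cosine_circuit() -> Circuit:
    """Scaled cosine cos(pi*x)/5.9348 on [0, 1], hybrid representation.

    Ideal function:

        (4.9348/5.9348) x^2 (2*0.4112 x^2 - 1)
        + (1/5.9348) (1 - 2*0.6676 x^6 (1 - 0.1762 x^2 (1 - 0.1097 x^2)))

    Realized as a MUX with select 1/5.9348 combining the two bracketed
    terms, each built as a pair whose *bipolar* reading is the term:
    a unipolar fraction (1+term)/2 is formed with Mult/NMult units and
    the pair is re-read in bipolar coding.  Input unipolar, output
    bipolar.
    """
    c = Circuit(primary_input="x", name="cos_pi")
    c.polarity["x"] = UNIPOLAR
    F = Fraction
    c.add_constant("c_a", F(8224, 10000))   # 2 * 0.4112
    c.add_constant("half", F(1, 2))
    c.add_constant("c_b1", F(1097, 10000))
    c.add_constant("c_b2", F(1762, 10000))
    c.add_constant("c_b3", F(6676, 10000))  # 2 * 0.6676 / 2
    c.add_constant("sel", F(10000, 59348))  # 1/5.9348
    c.add_unit("MULT_U", ("x", "x"), "sq")
    # first term: a = x^2 (0.8224 x^2 - 1); fraction (1+a)/2
    c.add_unit("NMULT_U", ("sq", "c_a"), "a1")     # 1 - 0.8224 x^2
    c.add_unit("NMULT_U", ("sq", "a1"), "a2")      # 1 - x^2 (1 - 0.8224 x^2)
    c.add_unit("MULT_U", ("a2", "half"), "a3")     # (1 + a)/2
    # second term: b = 1 - 1.3352 x^6 (1 - 0.1762 x^2 (1 - 0.1097 x^2))
    c.add_unit("NMULT_U", ("sq", "c_b1"), "b1")    # 1 - 0.1097 x^2
    c.add_unit("MULT_U", ("sq", "b1"), "b2")       # x^2 (...)
    c.add_unit("NMULT_U", ("b2", "c_b2"), "b3")    # 1 - 0.1762 x^2 (...)
    c.add_unit("MULT_U", ("sq", "sq"), "x4")
    c.add_unit("MULT_U", ("x4", "sq"), "x6")
    c.add_unit("MULT_U", ("x6", "b3"), "b4")       # x^6 (...)
    c.add_unit("NMULT_U", ("b4", "c_b3"), "b5")    # (1 + b)/2
    c.add_unit("MUX", ("a3", "b5", "sel"), "out", out_polarity=BIPOLAR)
    c.output = "out"
    c.validate()
    return c


def build_hybrid_sigmoid_circuit(degree: int = 7) -> Circuit:
    """Sigmoid with bipolar input u in [-1, 1] and unipolar output.

    The truncated Maclaurin sigmoid is ``(1 + v)/2`` with the odd
    series v = u/2 - u^3/24 + u^5/240 - 17 u^7/40320.  The circuit
    computes v as a shared-output sum: bipolar Mult units scale each
    odd power of u by a constant and all produce into one pair, whose
    bipolar reading is the equal-weight average of the unit values.
    The u/2 term is split over three identity units so every scaling
    constant stays within [-1, 1].  The output pair is simply re-read
    in unipolar coding, which applies (1 + v)/2 for free.

    A shared-output sum has a time-invariant production ratio, so the
    synthesized CRN decodes exactly at completion — unlike nested
    rescaling chains, whose intermediate pools are sampled by
    downstream units before they converge.
    """
    if degree not in (5, 7):
        raise ValueError(f"degree must be 5 or 7, got {degree}")
    # odd-series coefficients of v, term k scaled by the unit count
    v_coeffs = {1: Fraction(1, 2), 3: Fraction(-1, 24), 5: Fraction(1, 240)}
    if degree == 7:
        v_coeffs[7] = Fraction(-17, 40320)
    n_units = 2 + len(v_coeffs)  # u/2 takes three units, others one each

    c = Circuit(primary_input="x", name=f"sigmoid_hybrid_d{degree}")
    c.polarity["x"] = BIPOLAR
    # demand-limited copy of the input: each consumer slot of xc draws
    # exactly one pair total from x (against a unit-total constant),
    # which matters when x is a large shared pool — a squaring unit
    # reading x directly would drain it quadratically and starve the
    # slower constant-paired units
    c.add_constant("one_b", Fraction(1), BIPOLAR)
    c.add_unit("MULT_B", ("x", "one_b"), "xc", out_polarity=BIPOLAR)
    c.add_unit("MULT_B", ("xc", "xc"), "sq", out_polarity=BIPOLAR)
    c.add_unit("MULT_B", ("sq", "xc"), "u3", out_polarity=BIPOLAR)
    c.add_unit("MULT_B", ("sq", "sq"), "u4", out_polarity=BIPOLAR)
    c.add_unit("MULT_B", ("u4", "xc"), "u5", out_polarity=BIPOLAR)
    if degree == 7:
        c.add_unit("MULT_B", ("u4", "u3"), "u7", out_polarity=BIPOLAR)
    power_port = {1: "xc", 3: "u3", 5: "u5", 7: "u7"}

    c1 = n_units * v_coeffs[1] / 3
    c.add_constant("k1", c1, BIPOLAR)
    for rep in range(3):
        c.add_unit("MULT_B", (power_port[1], "k1"), "out",
                   out_polarity=UNIPOLAR)
    for k in sorted(v_coeffs)[1:]:
        ck = n_units * v_coeffs[k]
        c.add_constant(f"k{k}", ck, BIPOLAR)
        c.add_unit("MULT_B", (power_port[k], f"k{k}"), "out",
                   out_polarity=UNIPOLAR)
    c.output = "out"
    c.validate()
    return c


# ---------------------------------------------------------------------------
# unipolar function circuits (series with zero interior coefficients are
# factored through x or x^2 so every cascade ratio is well defined)

def _cascade(c: Circuit, b, var: str, prefix: str) -> str:
    """Append the Horner cascade b0(1 - b1 v(1 - b2 v(...))) in variable
    ``var`` and return its output port.  ``b`` are exact ratios."""
    n = len(b) - 1
    step = 0

    def fresh():
        nonlocal step
        step += 1
        return f"{prefix}{step}"

    cb = c.add_constant(f"{prefix}b{n}", b[n], UNIPOLAR)
    cur = c.add_unit("NMULT_U", (var, cb), fresh())
    for i in range(n - 1, 0, -1):
        if b[i] != 1:
            cb = c.add_constant(f"{prefix}b{i}", b[i], UNIPOLAR)
            cur = c.add_unit("MULT_U", (cur, cb), fresh())
        cur = c.add_unit("NMULT_U", (var, cur), fresh())
    if b[0] != 1:
        cb = c.add_constant(f"{prefix}b0", b[0], UNIPOLAR)
        cur = c.add_unit("MULT_U", (cur, cb), fresh())
    return cur


def _ratio_chain(coeffs) -> list:
    """b0 = a0, b_i = -a_i/a_{i-1}; raises if not realizable in [0, 1]."""
    b = [coeffs[0]]
    for i in range(1, len(coeffs)):
        if coeffs[i - 1] == 0:
            raise CircuitError(f"zero coefficient at index {i - 1} "
                               "breaks the cascade ratio rule")
        b.append(-coeffs[i] / coeffs[i - 1])
    if any(not 0 <= bi <= 1 for bi in b):
        raise CircuitError("cascade ratios fall outside [0, 1]")
    return b


def build_function_circuit(function_id: str, degree: Optional[int] = None
                           ) -> Circuit:
    """Unipolar circuit for a supported function on x in [0, 1].

    The truncated Maclaurin series is reformatted so that it maps onto
    Mult/NMult cascades:

    * ``exp_neg`` — plain alternating cascade in x;
    * ``log1p``   — x times an alternating cascade in x (the series has
      no constant term);
    * ``sin``, ``tanh`` — x times a cascade in w = x^2 (odd series);
    * ``cos``     — a cascade in w = x^2 (even series);
    * ``sigmoid`` — 1/2 + v/2 with the odd part v built like tanh and
      the affine step done by a MUX against a constant-1 pair.
    """
    from .series import (DEFAULT_DEGREES, horner_factorize,
                         maclaurin_coefficients)

    degree = DEFAULT_DEGREES[function_id] if degree is None else degree
    poly = maclaurin_coefficients(function_id, degree)
    a = list(poly.exact)
    name = f"{function_id}_d{degree}"

    if function_id == "exp_neg":
        circ = build_horner_circuit(horner_factorize(poly))
        circ.name = name
        return circ

    c = Circuit(primary_input="x", name=name)
    c.polarity["x"] = UNIPOLAR

    if function_id == "log1p":
        shifted = a[1:]
        while shifted and shifted[-1] == 0:
            shifted.pop()
        cur = _cascade(c, _ratio_chain(shifted), "x", "t")
        c.output = c.add_unit("MULT_U", ("x", cur), "out")
        c.validate()
        return c

    if function_id in ("sin", "tanh", "sigmoid"):
        if function_id == "sigmoid":
            a[0] = a[0] - Fraction(1, 2)  # odd part v = sigmoid - 1/2
            a = [2 * ai for ai in a]      # v scaled to x * cascade form
        odd = a[1::2]
        while odd and odd[-1] == 0:
            odd.pop()
        c.add_unit("MULT_U", ("x", "x"), "w")
        cur = _cascade(c, _ratio_chain(odd), "w", "t")
        cur = c.add_unit("MULT_U", ("x", cur), "xh")
        if function_id == "sigmoid":
            # xh already carries v = 2*(sigmoid - 1/2) including the
            # cascade's b0 = 1/2; out = (1-s)*1 + s*v at s = 1/2 = (1+v)/2
            c.add_constant("one", Fraction(1))
            c.add_constant("half", Fraction(1, 2))
            cur = c.add_unit("MUX", ("one", cur, "half"), "out")
        c.output = cur
        c.validate()
        return c

    if function_id == "cos":
        even = a[0::2]
        while even and even[-1] == 0:
            even.pop()
        c.add_unit("MULT_U", ("x", "x"), "w")
        c.output = _cascade(c, _ratio_chain(even), "w", "t")
        c.validate()
        return c

    raise CircuitError(f"no circuit construction for {function_id!r}")
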