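# crnfrac

Compile mathematical functions into chemical reaction networks (CRNs)
under **fractional coding**, simulate them with deterministic
mass-action kinetics, emulate them with DNA-strand-displacement (DSD)
reaction modules, and run a molecular perceptron classifier — all with
nothing but bimolecular reactions sharing one rate constant.

## Who this is for

Researchers in molecular programming / DNA computing who want a
systematic, testable pipeline from a target function `f(x)` to an
abstract CRN (and its DSD emulation), and a reference implementation of
the fractional-coding computational units for teaching or comparison.

## The model

A value is carried by a pair of species `(X0, X1)`:

- unipolar: `x = [X1] / ([X0] + [X1]) ∈ [0, 1]`
- bipolar:  `x = ([X1] − [X0]) / ([X0] + [X1]) ∈ [−1, 1]`

Four-reaction units compute on pairs (analogous to stochastic-logic
gates): `Mult` (`c = ab`), `NMult` (`c = 1 − ab`, or `−ab` in bipolar),
and `MUX` (`c = a(1−s) + bs`, select `s` unipolar).  A target function
is approximated by its truncated Maclaurin series

    P(x) = a0 + a1 x + ... + an x^n,

rewritten by Horner's rule into

    P(x) = b0 (1 − b1 x (1 − b2 x (... (1 − bn x)))),   b0 = a0,  bi = −ai/ai−1,

and, provided every `bi ∈ [0, 1]`, mapped onto an alternating cascade
of Mult and NMult units.  Series with zero interior coefficients
(sin, cos, tanh, sigmoid, log(1+x)) are factored through `x` or `x²`
first.  Each unit becomes four bimolecular reactions; the decoded
output-pair ratio converges to `P(x)` at completion.  A
Soloveichik-style translation maps every bimolecular reaction to three
strand-displacement steps with gate complexes buffered at `c_max`,
emulating the CRN kinetics with error `O(1/c_max)`.

The molecular perceptron computes `sigmoid((1/N) Σ wi xi)` for binary
inputs: `N` bipolar Mult units produce into one shared pair (whose
reading is the scaled weighted sum), feeding a hybrid sigmoid circuit
(bipolar input, unipolar output); decisions threshold the output at 0.5.

## Worked example

```
$ crnfrac compile exp_neg
function: exp_neg  degree: 5
b coefficients: 1 1 0.5 0.3333333333 0.25 0.2
truncation max abs error on [0,1]: 1.213e-03
units: 8
```

The six-term series of `e^−x` factorizes into the textbook chain
`1 − x(1 − x/2(1 − x/3(1 − x/4(1 − x/5))))` and maps to 8 units
(32 reactions).  Simulating the synthesized CRN:

```
$ crnfrac simulate exp_neg --grid 0:0.5:1
x       exact   ideal   crn     err_crn
0.000000        1.000000        1.000000        1.000000        0.000000
0.500000        0.606531        0.606510        0.606510        0.000020
1.000000        0.367879        0.366667        0.366667        0.001213
# mse_crn_vs_exact = 4.904106e-07
```

`ideal` is the circuit's exact mathematical value, `crn` the decoded
mass-action output at `t = 10^3`; the residual against `exact` is the
series truncation error.  `crnfrac dsd exp_neg` repeats this through
the strand-displacement layer; `crnfrac perceptron` runs the
three-perceptron classification experiment and prints per-preset
agreement, ones-counts and mean squared error.

## Library layout

| module | contents |
|---|---|
| `crnfrac.series` | Maclaurin coefficients (exact rationals), Horner factorization, mappability |
| `crnfrac.circuits` | unit/circuit model, builders (Horner cascades, scaled sine/cosine, hybrid sigmoid), ideal evaluator, symbolic expansion |
| `crnfrac.crn` | pair encoding, unit reaction quadruples, network synthesis, input-preserving variant |
| `crnfrac.kinetics` | sparse mass-action ODE model, stiff integration, decoding |
| `crnfrac.dsd` | strand-displacement translation, simulation, fidelity sweeps |
| `crnfrac.perceptron` | weight presets, seeded inputs, perceptron networks, classification experiment |
| `crnfrac.cli` | `crnfrac` command (compile / simulate / dsd / perceptron / sweep) |

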