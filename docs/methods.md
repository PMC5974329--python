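# Methods

## Fractional coding and unit semantics

Every signal is a species pair; the *fraction* `p = [X1]/([X0]+[X1])`
is the quantity all kinetics acts on.  A unipolar port decodes to `p`,
a bipolar port to `2p − 1`; re-reading a pair under the other polarity
costs nothing, which is how hybrid-representation circuits (unipolar
input / bipolar output and vice versa) are built.  Unit semantics in
fraction space:

| unit | fraction formula | decoded meaning |
|---|---|---|
| Mult (unipolar) | `ab` | product |
| NMult (unipolar) | `1 − ab` | one minus product |
| MUX | `a(1−s) + bs` | scaled addition (affine, so valid for either polarity) |
| Mult (bipolar) | `(1+(2a−1)(2b−1))/2` | bipolar product |
| NMult (bipolar) | `(1−(2a−1)(2b−1))/2` | negated bipolar product |

Each unit is four bimolecular reactions with one product and a common
rate constant (default 1 in normalized concentration/time units).
Equal rates within a unit are assumed by the exactness arguments; a
rate-perturbation check is part of the test suite rather than assumed
harmless.

## Series compilation

Maclaurin coefficients are computed as exact rationals — closed forms
for `e^−x`, sin, cos, `log(1+x)`; the recurrence from `t' = 1 − t²`
for tanh, with `sigmoid(x) = 1/2 + tanh(x/2)/2` — and converted to
floating point once.  The Horner chain `b0 = a0`, `bi = −ai/ai−1` maps
to a unit cascade when every `bi ∈ [0, 1]`; the sufficient condition
(signs strictly alternating from `+`, magnitudes ≤ 1 and
non-increasing) is implemented with a *non-strict* magnitude bound,
since that is what the ratio rule actually requires and the `e^−x`
series (`|a0| = |a1| = 1`) must qualify.

Zero interior coefficients make the ratio rule undefined, so plain
factorization refuses them and dedicated builders reformat instead:
odd series (sin, tanh, and the odd part of sigmoid) become
`x · chain(x²)`, even series (cos) become `chain(x²)`, and `log(1+x)`
(no constant term) becomes `x · chain(x)`.  The sigmoid's affine offset
is realized as `MUX(1, v, 1/2) = (1+v)/2`.

Default truncation degrees: exp_neg 5, sin 7, cos 6, tanh 7, sigmoid 7,
log1p 15.  These keep the truncation's 11-point mean squared error on
[0, 1] below 1e-4; a uniform max-error target is unattainable for
`log(1+x)` and tanh, whose series converge slowly near `x = 1` (the
log series would need degree ~10^4 for a 1e-4 uniform bound).

Two fixed factorizations are shipped as given: the scaled half-period
sine `sin(πx)/π = x(1−x²)(1−0.4x²)(1−0.2488x²(1−0.2637x²))` and the
scaled cosine `cos(πx)/5.9348`, built as a MUX (select `1/5.9348`)
over two bracketed terms realized as pairs read in bipolar coding.
The sine factorization's own approximation error reaches ~1.1e-3 near
`x = 0.9`; tests account for it explicitly.

## Why the circuits decode exactly, and where they cannot

A central kinetic fact drives all wiring decisions: a pair whose
*production ratio* is constant in time keeps a correct fraction at
every instant, because consumption always removes both members
proportionally.  Source pairs trivially qualify; outputs of Mult/NMult
units with constant-ratio inputs qualify inductively; so do
shared-output sums (several units producing into one pair at equal
totals).  MUX outputs do **not**: the relative throughput of their two
data channels shifts over time, so a MUX output sampled *partially* by
a downstream consumer contributes an early-biased, wrong mixture that
never heals.  Consequently:

- builders place MUX units only where their data inputs have constant
  ratios (scaled cosine, unipolar sigmoid) or at the circuit output;
- the hybrid (bipolar-in, unipolar-out) sigmoid is wired as a
  **shared-output sum of odd powers** — bipolar Mult units computing
  `u·1` (three copies), `−u³/4`, `u⁵/40`, `−17u⁷/6720` into one pair,
  whose average is `v = u/2 − u³/24 + u⁵/240 − 17u⁷/40320`; re-reading
  the pair in unipolar coding applies `(1+v)/2`, the truncated
  Maclaurin sigmoid.  A nested rescaling chain with the same expansion
  was measured to carry a *persistent* ~2e-3 error for exactly the
  partial-sampling reason above; the sum form decodes exactly at
  completion.

Fan-out follows the same logic.  Each unit input draws from a private
pool: source signals are re-encoded per consumer (only the ratio
carries information, so copies are free), and a single-producer port
read by several consumers has its producing subtree duplicated.  This
also removes self-pairing (`x²` as a pool reacting with itself).  The
one deliberate exception is a shared-output pair, which is synthesized
once — its ratio is time-invariant, so competitive consumption is
safe.  Pool *totals* still matter there: every demand-limited consumer
(paired against a unit-total constant) must find enough material.  The
perceptron therefore (a) scales its input-pair totals so the shared
inner-product pool carries at least 32 total regardless of N, and
(b) buffers the sigmoid's input through demand-limited copy units
(`Mult_B(y, +1)` against a unit-total constant), because a squaring
unit reading a large shared pool directly drains it quadratically and
starves slower consumers (observed as convergence like `t^(−1/12)`).

## Mass-action integration

`d[S]/dt = Σ k·[R1]·[R2]·(net stoichiometry)`, built once as a sparse
stoichiometry matrix.  Integration uses BDF with analytic Jacobian,
`rtol = 1e-8`, `atol = 1e-10`, over 200 log-spaced points up to
`t_end = 10^3` normalized time units (completion tails decay like
1/t; at `t = 10^3` the residual finite-time error of the deepest
shipped cascade is ~4e-4).  Sub-`1e-12` negative excursions are
clipped.  Convergence is declared when the decoded output moves less
than 1e-8 over the final 10% of the span.

## Strand-displacement emulation

Every source reaction `A + B → products` (rate `k`) becomes

    A + L_i ⇌ H_i + G_i    (forward q_i, backward q_max)
    H_i + B → O_i          (q_max)
    O_i + T_i → products   (q_max)

with `L_i`, `G_i`, `T_i` buffered at `c_max` (default 1e4 × pair
total) and `q_max = 10^3`.  Quasi-steady-state analysis of `H_i` gives
effective flux `q_i[A][B]·c_max/(c_max+[B])`, so `q_i = k` reproduces
the source kinetics with relative error `O([B]/c_max) + O(k/q_max)`.
Wastes are untracked; species are abstract strands with role tags, and
no sequences are designed.  Because decoded ratios in these cascades
are time-invariant, emulation error only shows in the *completion
kinetics*; the fidelity sweep therefore measures the sup-norm distance
of the output pair's concentration trajectories (normalized), which
decreases monotonically in `c_max` as designed.

## Perceptron experiment

Presets A/B/C place the weights (1/2, −1/2, 1/4, −1/4) with
frequencies (8,8,8,8), (10,6,10,6), (6,10,6,10) in value blocks
(N = 32); their expected weighted sums under Bernoulli(1/2) inputs are
0, 1.5 and −1.5.  Inputs are a seeded 32×100 Bernoulli(1/2) matrix
(each bit equally likely 0 or 1); bit 1 encodes bipolar +1, bit 0
encodes bipolar 0 (equal pair concentrations), so absent inputs
contribute exactly zero to the shared average.  The decision rule is
`value ≥ 0.5 → 1`; decoded readings are rounded at 1e-8 (below solver
precision) before thresholding so that exact ties — weighted sum 0
decodes to 0.5 up to ~1e-16 — classify deterministically as 1 on both
the molecular and the reference side.  The smallest nonzero decision
margin under quarter-valued weights is `|sigmoid(±0.25/32) − 1/2| ≈
2e-3`, three orders above the molecular error (~4e-5 per column), so
agreement is robust, not incidental.  The reference classifier uses
the *true* sigmoid; the circuit realizes the degree-7 truncation,
whose deviation (< 2e-5 on the relevant range) is far below the margin.

## What the synthetic conditions do and do not show

All experiments are self-contained: seeded Bernoulli inputs, preset
weights, normalized concentrations, one shared rate constant.  Passing
tests demonstrate the *computational* correctness of the constructions
under ideal mass-action kinetics and the internal consistency of the
DSD emulation.  They say nothing about leak reactions, sequence
design, crosstalk, pipetting noise, or rate-constant heterogeneity in
a wet-lab setting; the rate-perturbation test quantifies sensitivity
to ±20% rate mismatch but is a caricature of real variability.

## Known limitations

- Values must live in [0, 1] / [−1, 1]: only scaled sine/cosine are
  computable, and the perceptron computes the weighted sum scaled by
  1/N — an inherent property of the coding, not an implementation gap.
- Plain Horner compilation requires alternating, non-increasing
  coefficients; arbitrary polynomials with zero interior coefficients
  are not auto-factorized (the shipped reformulations cover the six
  supported functions).
- Finite-horizon readouts carry O(1/t) completion error; the default
  horizon leaves ~4e-4 on the deepest cascade.
- The DSD layer models the translation scheme's kinetics only — no
  enumeration semantics, toeholds, or thermodynamics.
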