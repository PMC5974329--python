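"""Molecular perceptron: shared-output inner product plus hybrid sigmoid.

The perceptron computes ``sigmoid((1/N) * sum_i w_i x_i)`` for binary
inputs x_i and weights w_i in [-1, 1].  The inner product is N bipolar
Mult units that all produce into one shared pair: each unit contributes
total 1 with mean w_i*x_i, so the shared pair's bipolar reading is the
scaled weighted sum.  That pair feeds the hybrid sigmoid circuit
(bipolar input, unipolar output), and the decision is a 0.5 threshold
on the decoded output.

The 1/N scaling is inherent to the shared-output construction: the
fractional coding cannot represent the unscaled weighted sum, whose
range exceeds [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .circuits import BIPOLAR, UNIPOLAR, UnitSpec, build_hybrid_sigmoid_circuit
from .crn import (MolecularPair, ReactionNetwork, encode_value, synthesize_into,
                  unit_reactions)
from .kinetics import integrate, readout

__all__ = [
    "PerceptronWeights",
    "InputMatrix",
    "ClassificationResult",
    "preset_weights",
    "generate_inputs",
    "build_inner_product_network",
    "build_perceptron_network",
    "truncated_sigmoid",
    "exact_perceptron_value",
    "run_experiment",
]

#: exact values within this distance of the threshold are reported as
#: near-threshold columns (decision not meaningfully testable)
NEAR_THRESHOLD = 1e-3
#: decoded readings are rounded at solver precision before thresholding,
#: so an exact tie (weighted sum 0) classifies deterministically
READOUT_DECIMALS = 8


@dataclass(frozen=True)
class PerceptronWeights:
    """Ordered weight vector with every entry in [-1, 1]."""

    weights: Tuple[float, ...]
    label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if any(abs(w) > 1 for w in self.weights):
            raise ValueError("perceptron weights must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.weights)

    def scaled_sum(self, bits: Sequence[int]) -> float:
        if len(bits) != self.n:
            raise ValueError(
                f"got {len(bits)} bits for {self.n} weights"
            )
        return sum(w * b for w, b in zip(self.weights, bits)) / self.n


@dataclass(frozen=True)
class InputMatrix:
    """N x M binary matrix; columns are input vectors."""

    bits: np.ndarray
    seed: int

    def column(self, j: int) -> Tuple[int, ...]:
        return tuple(int(b) for b in self.bits[:, j])

    @property
    def n(self) -> int:
        return self.bits.shape[0]

    @property
    def count(self) -> int:
        return self.bits.shape[1]


#: preset frequencies of the weight values (1/2, -1/2, 1/4, -1/4)
_PRESET_FREQS = {
    "A": (8, 8, 8, 8),
    "B": (10, 6, 10, 6),
    "C": (6, 10, 6, 10),
}
_WEIGHT_VALUES = (0.5, -0.5, 0.25, -0.25)


def preset_weights(which: str) -> PerceptronWeights:
    """The three published 32-weight configurations, in value blocks.

    Expected weighted sums under Bernoulli(1/2) inputs are 0 (A),
    1.5 (B) and -1.5 (C).
    """
    if which not in _PRESET_FREQS:
        raise ValueError(f"unknown preset {which!r}; choose A, B or C")
    w: List[float] = []
    for value, freq in zip(_WEIGHT_VALUES, _PRESET_FREQS[which]):
        w.extend([value] * freq)
    return PerceptronWeights(tuple(w), label=which)


def generate_inputs(n: int, count: int, seed: int) -> InputMatrix:
    """Reproducible Bernoulli(0.5) binary input matrix (bits in columns)."""
    if n <= 0 or count <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=(n, count), dtype=np.uint8)
    return InputMatrix(bits=bits, seed=seed)


def build_inner_product_network(weights: PerceptronWeights,
                                bits: Sequence[int], total: float = 1.0,
                                rate: float = 1.0) -> ReactionNetwork:
    """N bipolar Mult units sharing one output pair.

    Bit 1 encodes bipolar +1 (pure 1-species); bit 0 encodes bipolar 0
    (equal concentrations), so an absent input contributes exactly zero
    to the average.  The shared pair's converged bipolar reading is
    (1/N) * sum_i w_i x_i.
    """
    if len(bits) != weights.n:
        raise ValueError(f"got {len(bits)} bits for {weights.n} weights")
    net = ReactionNetwork()
    net.pairs["y"] = MolecularPair("y", BIPOLAR, 0.0, 0.0)
    net.output_pair = "y"
    for i, (w, b) in enumerate(zip(weights.weights, bits)):
        wname, xname = f"w{i}", f"x{i}"
        net.pairs[wname] = encode_value(w, BIPOLAR, total, wname)
        net.constant_pairs.append(wname)
        net.pairs[xname] = encode_value(1.0 if b else 0.0, BIPOLAR, total,
                                        xname)
        net.input_pairs.append(xname)
        unit = UnitSpec("MULT_B", (wname, xname), "y")
        net.reactions.extend(unit_reactions(unit, [wname, xname, "y"], rate))
    net.validate()
    return net


#: the sigmoid stage's power trees and scaling units draw roughly this
#: much material from the shared inner-product pool; the pool total is
#: kept at or above it so no downstream unit is starved (only the
#: pool's ratio carries the value, so totals are free to scale)
_SIGMOID_POOL_DEMAND = 32.0


def build_perceptron_network(weights: PerceptronWeights, bits: Sequence[int],
                             degree: int = 7, total: float = 1.0,
                             rate: float = 1.0) -> ReactionNetwork:
    """Inner product composed with the hybrid sigmoid; unipolar output."""
    ip_total = total * max(1.0, _SIGMOID_POOL_DEMAND / weights.n)
    net = build_inner_product_network(weights, bits, ip_total, rate)
    sigmoid = build_hybrid_sigmoid_circuit(degree)
    net.output_pair = synthesize_into(sigmoid, net, "y", total, rate,
                                      prefix="s_")
    return net


def truncated_sigmoid(u: float, degree: int = 7) -> float:
    """The degree-5/7 Maclaurin sigmoid the molecular circuit realizes."""
    coeffs = {1: 0.5, 3: -1.0 / 24, 5: 1.0 / 240}
    if degree == 7:
        coeffs[7] = -17.0 / 40320
    return 0.5 + sum(c * u**k for k, c in coeffs.items()) / 2


def exact_perceptron_value(weights: PerceptronWeights,
                           bits: Sequence[int]) -> float:
    """Reference sigmoid((1/N) sum w_i x_i) with the true sigmoid."""
    return 1.0 / (1.0 + math.exp(-weights.scaled_sum(bits)))


@dataclass
class ClassificationResult:
    """Per-weight-set outcome of the classification experiment."""

    label: Optional[str]
    exact_values: np.ndarray
    molecular_values: np.ndarray
    exact_decisions: np.ndarray
    molecular_decisions: np.ndarray
    accuracy: float                    # % decision agreement
    mse: float                         # (1/M) sum |y - yhat|^2
    near_threshold: List[int]          # columns with |exact - thr| small
    threshold: float = 0.5

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "exact_value": self.exact_values,
            "molecular_value": self.molecular_values,
            "exact_decision": self.exact_decisions,
            "molecular_decision": self.molecular_decisions,
        })

    def summary(self) -> str:
        ones = int(self.molecular_decisions.sum())
        lines = [
            f"perceptron {self.label or '?'}:",
            f"  columns: {len(self.exact_values)}",
            f"  decision agreement: {self.accuracy:.2f} %",
            f"  molecular ones: {ones}",
            f"  mse (molecular vs exact): {self.mse:.3e}",
        ]
        if self.near_threshold:
            lines.append(f"  near-threshold columns: {self.near_threshold}")
        return "\n".join(lines)


def _decide(values: np.ndarray, threshold: float) -> np.ndarray:
    # ties (value == threshold) classify as 1
    return (values >= threshold).astype(int)


def run_experiment(weight_sets: Sequence[PerceptronWeights],
                   inputs: InputMatrix, threshold: float = 0.5,
                   degree: int = 7, t_end: float = 1e3,
                   ) -> List[ClassificationResult]:
    """Simulate every perceptron on every input column and classify.

    For each column the perceptron network is integrated to its default
    horizon, the output decoded (rounded at solver precision) and
    thresholded; the reference is the true sigmoid of the scaled
    weighted sum, thresholded the same way.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    results = []
    for weights in weight_sets:
        exact = np.empty(inputs.count)
        molecular = np.empty(inputs.count)
        cache: Dict[Tuple[int, ...], float] = {}
        for j in range(inputs.count):
            bits = inputs.column(j)
            exact[j] = exact_perceptron_value(weights, bits)
            if bits in cache:
                molecular[j] = cache[bits]
                continue
            try:
                net = build_perceptron_network(weights, bits, degree)
                traj = integrate(net, t_end)
                molecular[j] = round(readout(traj), READOUT_DECIMALS)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed on column {j}: {exc}"
                ) from exc
            cache[bits] = molecular[j]
        exact_dec = _decide(exact, threshold)
        mol_dec = _decide(molecular, threshold)
        agree = float((exact_dec == mol_dec).mean() * 100.0)
        mse = float(np.mean(np.abs(exact - molecular) ** 2))
        near = [j for j in range(inputs.count)
                if abs(exact[j] - threshold) < NEAR_THRESHOLD]
        results.append(ClassificationResult(
            label=weights.label,
            exact_values=exact,
            molecular_values=molecular,
            exact_decisions=exact_dec,
            molecular_decisions=mol_dec,
            accuracy=agree,
            mse=mse,
            near_threshold=near,
            threshold=threshold,
        ))
    return results
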