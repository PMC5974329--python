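"""Molecular-pair encoding and reaction-network synthesis.

A value is carried by a pair of species (X0, X1).  Unipolar coding
reads ``[X1]/([X0]+[X1])`` in [0, 1]; bipolar coding reads
``([X1]-[X0])/([X0]+[X1])`` in [-1, 1].  Each computational unit
becomes four bimolecular reactions with one product and a common rate
constant; a circuit becomes the union of its units' reactions.

Fan-out policy: every unit input draws from its own physical pair.
Source signals (the primary input and constants) are re-encoded per
consumer; a produced signal consumed more than once has its producing
subtree duplicated.  This keeps every reaction's reactant pools
private to one unit, so no unit competes with another for molecules
and no unit pairs a pool against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .circuits import BIPOLAR, UNIPOLAR, Circuit, UnitSpec

__all__ = [
    "MolecularPair",
    "Reaction",
    "ReactionNetwork",
    "EncodingError",
    "WiringError",
    "encode_value",
    "decode_value",
    "unit_reactions",
    "synthesize_network",
    "synthesize_into",
    "make_input_preserving",
]


class EncodingError(ValueError):
    """Value outside the coding range, or an unreadable (empty) pair."""


class WiringError(ValueError):
    """Unresolved port or invalid network structure."""


@dataclass(frozen=True)
class MolecularPair:
    """A named species pair carrying one fractionally-coded value."""

    name: str
    polarity: str
    initial_0: float
    initial_1: float

    @property
    def species_0(self) -> str:
        return f"{self.name}_0"

    @property
    def species_1(self) -> str:
        return f"{self.name}_1"

    @property
    def total(self) -> float:
        return self.initial_0 + self.initial_1

    @property
    def value(self) -> float:
        return decode_value(self.initial_0, self.initial_1, self.polarity)


def encode_value(value: float, polarity: str, total: float = 1.0,
                 name: str = "x") -> MolecularPair:
    """Encode a fractional value as initial pair concentrations."""
    if total <= 0:
        raise EncodingError(f"pair total must be positive, got {total}")
    if polarity == UNIPOLAR:
        if not 0.0 <= value <= 1.0:
            raise EncodingError(f"unipolar value {value} outside [0, 1]")
        c1 = value * total
        c0 = (1.0 - value) * total
    elif polarity == BIPOLAR:
        if not -1.0 <= value <= 1.0:
            raise EncodingError(f"bipolar value {value} outside [-1, 1]")
        c1 = (1.0 + value) / 2.0 * total
        c0 = (1.0 - value) / 2.0 * total
    else:
        raise EncodingError(f"unknown polarity {polarity!r}")
    return MolecularPair(name=name, polarity=polarity, initial_0=c0, initial_1=c1)


def decode_value(conc_0: float, conc_1: float, polarity: str) -> float:
    """Read the fractional value off a pair of concentrations."""
    tot = conc_0 + conc_1
    if tot <= 0:
        raise EncodingError("cannot decode a pair with zero total concentration")
    if polarity == UNIPOLAR:
        return conc_1 / tot
    if polarity == BIPOLAR:
        return (conc_1 - conc_0) / tot
    raise EncodingError(f"unknown polarity {polarity!r}")


@dataclass(frozen=True)
class Reaction:
    """A bimolecular reaction: exactly two reactants, one or more products."""

    reactants: Tuple[str, str]
    products: Tuple[str, ...]
    rate_constant: float = 1.0

    def __post_init__(self):
        if len(self.reactants) != 2:
            raise WiringError("reactions must have exactly two reactants")
        if not self.products:
            raise WiringError("reactions must have at least one product")
        if self.rate_constant <= 0:
            raise WiringError("rate constant must be positive")

    def __str__(self) -> str:
        return (f"{self.reactants[0]} + {self.reactants[1]} -> "
                f"{' + '.join(self.products)} ; k={self.rate_constant!r}")


# reaction tables: (A-member, B-member, C-member) per unit kind; the
# NMult variants are the Mult tables with the product member flipped.
_MULT_U_TABLE = [(1, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 0)]
_MULT_B_TABLE = [(1, 1, 1), (0, 0, 1), (1, 0, 0), (0, 1, 0)]
# MUX rows: (data pair, data member, select member, C member)
_MUX_TABLE = [("a", 1, 0, 1), ("a", 0, 0, 0), ("b", 1, 1, 1), ("b", 0, 1, 0)]


def unit_reactions(unit: UnitSpec, pair_names,
                   rate: float = 1.0) -> List[Reaction]:
    """The four bimolecular reactions realizing one unit.

    ``pair_names`` maps each of the unit's ports to the physical pair
    feeding (or receiving) it; alternatively a sequence of per-slot
    pair names (inputs in order, then the output), which permits a unit
    whose input slots read the same logical port from distinct pools.
    """
    if isinstance(pair_names, dict):
        for port in (*unit.inputs, unit.output):
            if port not in pair_names:
                raise WiringError(f"no pair resolved for port {port!r}")
        slots = [pair_names[p] for p in unit.inputs] + [pair_names[unit.output]]
    else:
        slots = list(pair_names)
        if len(slots) != len(unit.inputs) + 1:
            raise WiringError(
                f"{unit.kind} needs {len(unit.inputs) + 1} pair names, "
                f"got {len(slots)}"
            )
    out = slots[-1]
    if unit.kind == "MUX":
        a, b, s = slots[:3]
        data = {"a": a, "b": b}
        return [
            Reaction((f"{data[d]}_{dm}", f"{s}_{sm}"), (f"{out}_{cm}",), rate)
            for d, dm, sm, cm in _MUX_TABLE
        ]
    a, b = slots[:2]
    table = _MULT_U_TABLE if unit.kind in ("MULT_U", "NMULT_U") else _MULT_B_TABLE
    flip = unit.kind in ("NMULT_U", "NMULT_B")
    return [
        Reaction((f"{a}_{am}", f"{b}_{bm}"), (f"{out}_{1 - cm if flip else cm}",),
                 rate)
        for am, bm, cm in table
    ]


@dataclass
class ReactionNetwork:
    """Species, bimolecular reactions, and the designated coded pairs."""

    reactions: List[Reaction] = field(default_factory=list)
    pairs: Dict[str, MolecularPair] = field(default_factory=dict)
    input_pairs: List[str] = field(default_factory=list)
    constant_pairs: List[str] = field(default_factory=list)
    output_pair: str = ""
    #: unpaired species (e.g. strand-displacement gates) and their
    #: initial concentrations
    extra_initial: Dict[str, float] = field(default_factory=dict)

    @property
    def species(self) -> List[str]:
        seen = []
        for p in self.pairs.values():
            seen.extend((p.species_0, p.species_1))
        seen.extend(s for s in self.extra_initial if s not in seen)
        known = set(seen)
        extra = set()
        for r in self.reactions:
            for s in (*r.reactants, *r.products):
                if s not in known:
                    extra.add(s)
        return seen + sorted(extra)

    def initial_concentrations(self) -> Dict[str, float]:
        conc = {s: 0.0 for s in self.species}
        for p in self.pairs.values():
            conc[p.species_0] = p.initial_0
            conc[p.species_1] = p.initial_1
        conc.update(self.extra_initial)
        return conc

    @property
    def output(self) -> MolecularPair:
        return self.pairs[self.output_pair]

    def validate(self) -> None:
        sp = set(self.species)
        for r in self.reactions:
            for s in (*r.reactants, *r.products):
                if s not in sp:
                    raise WiringError(f"reaction uses undeclared species {s!r}")
        if self.output_pair and self.output_pair not in self.pairs:
            raise WiringError(f"unknown output pair {self.output_pair!r}")

    # -- serialization: line-oriented plain text --------------------------
    def to_text(self) -> str:
        lines = ["# reaction network"]
        for name in sorted(self.pairs):
            p = self.pairs[name]
            role = ("input" if name in self.input_pairs
                    else "constant" if name in self.constant_pairs
                    else "output" if name == self.output_pair
                    else "internal")
            lines.append(
                f"pair: {name} {p.polarity} {p.initial_0:.12g} "
                f"{p.initial_1:.12g} {role}"
            )
        for s in sorted(self.extra_initial):
            lines.append(f"species: {s} {self.extra_initial[s]:.12g}")
        lines.append(f"output: {self.output_pair}")
        for r in self.reactions:
            lines.append(str(r))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReactionNetwork":
        net = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("pair:"):
                _, name, pol, c0, c1, role = line.split()
                net.pairs[name] = MolecularPair(name, pol, float(c0), float(c1))
                if role == "input":
                    net.input_pairs.append(name)
                elif role == "constant":
                    net.constant_pairs.append(name)
            elif line.startswith("species:"):
                _, s, conc = line.split()
                net.extra_initial[s] = float(conc)
            elif line.startswith("output:"):
                net.output_pair = line.split(":", 1)[1].strip()
            else:
                lhs, _, rest = line.partition("->")
                prods, _, kpart = rest.partition(";")
                k = float(kpart.split("=", 1)[1])
                net.reactions.append(Reaction(
                    tuple(s.strip() for s in lhs.split("+")),
                    tuple(s.strip() for s in prods.split("+")),
                    k,
                ))
        net.validate()
        return net


def synthesize_network(circuit: Circuit, x_value: float, total: float = 1.0,
                       rate: float = 1.0) -> ReactionNetwork:
    """Instantiate a circuit as a reaction network at one input value.

    The circuit's primary input and every constant are encoded as
    initial concentrations; each unit contributes its four reactions.
    Fan-out is resolved by duplicating upstream subtrees (see module
    docstring), so the result is a tree of units rooted at the output —
    except for shared-output ports (several units producing one pair),
    which are synthesized once: their production ratio is constant in
    time, so all consumers may safely draw from the single pool.
    """
    circuit.validate()
    producers: Dict[str, list] = {}
    for u in circuit.units:
        producers.setdefault(u.output, []).append(u)
    net = ReactionNetwork()
    counts: Dict[str, int] = {}
    shared_done: Dict[str, str] = {}

    def fresh_name(port: str) -> str:
        counts[port] = counts.get(port, 0) + 1
        n = counts[port]
        return port if n == 1 else f"{port}.{n}"

    def instantiate(port: str) -> str:
        if port in shared_done:
            return shared_done[port]
        units = producers.get(port, ())
        shared = len(units) > 1
        name = fresh_name(port)
        pol = circuit.polarity[port]
        if port == circuit.primary_input:
            net.pairs[name] = encode_value(x_value, pol, total, name)
            net.input_pairs.append(name)
        elif port in circuit.constants:
            net.pairs[name] = encode_value(circuit.constants[port], pol,
                                           total, name)
            net.constant_pairs.append(name)
        elif units:
            if shared:
                shared_done[port] = name
            net.pairs[name] = MolecularPair(name, pol, 0.0, 0.0)
            for unit in units:
                slots = [instantiate(p) for p in unit.inputs] + [name]
                net.reactions.extend(unit_reactions(unit, slots, rate))
        else:
            raise WiringError(f"port {port!r} has no source")
        return name

    net.output_pair = instantiate(circuit.output)
    net.validate()
    return net


def synthesize_into(circuit: Circuit, net: ReactionNetwork, input_pair: str,
                    total: float = 1.0, rate: float = 1.0,
                    prefix: str = "") -> str:
    """Instantiate a circuit inside an existing network.

    The circuit's primary input is bound to ``input_pair``, an existing
    (typically produced) pair in ``net``; it is treated like a shared
    pool, so its production ratio must be time-invariant for exact
    decoding.  All other ports follow the same fan-out policy as
    :func:`synthesize_network`, with ``prefix`` prepended to new pair
    names.  Returns the name of the circuit's output pair.
    """
    circuit.validate()
    if input_pair not in net.pairs:
        raise WiringError(f"unknown input pair {input_pair!r}")
    producers: Dict[str, list] = {}
    for u in circuit.units:
        producers.setdefault(u.output, []).append(u)
    counts: Dict[str, int] = {}
    shared_done: Dict[str, str] = {circuit.primary_input: input_pair}

    def fresh_name(port: str) -> str:
        counts[port] = counts.get(port, 0) + 1
        n = counts[port]
        base = f"{prefix}{port}"
        return base if n == 1 else f"{base}.{n}"

    def instantiate(port: str) -> str:
        if port in shared_done:
            return shared_done[port]
        units = producers.get(port, ())
        name = fresh_name(port)
        pol = circuit.polarity[port]
        if port in circuit.constants:
            net.pairs[name] = encode_value(circuit.constants[port], pol,
                                           total, name)
            net.constant_pairs.append(name)
        elif units:
            if len(units) > 1:
                shared_done[port] = name
            net.pairs[name] = MolecularPair(name, pol, 0.0, 0.0)
            for unit in units:
                slots = [instantiate(p) for p in unit.inputs] + [name]
                net.reactions.extend(unit_reactions(unit, slots, rate))
        else:
            raise WiringError(f"port {port!r} has no source")
        return name

    out = instantiate(circuit.output)
    net.validate()
    return out


def make_input_preserving(network: ReactionNetwork,
                          pair_names: Sequence[str]) -> ReactionNetwork:
    """Catalytic variant: preserved pairs survive the reactions they feed.

    Every reaction consuming a species of a named pair gets that species
    appended to its products, so the pair's concentrations are constant
    along the trajectory.  This is this package's own realization of
    input preservation; it leaves each unit's output unchanged because
    production fluxes still see the same (now constant) input ratios.
    """
    preserved = set()
    for name in pair_names:
        if name not in network.pairs:
            raise WiringError(f"unknown pair {name!r}")
        p = network.pairs[name]
        preserved.update((p.species_0, p.species_1))
    new_reactions = []
    for r in network.reactions:
        extra = tuple(s for s in r.reactants if s in preserved)
        new_reactions.append(
            replace(r, products=r.products + extra) if extra else r
        )
    return replace_network(network, reactions=new_reactions)


def replace_network(network: ReactionNetwork, **changes) -> ReactionNetwork:
    out = ReactionNetwork(
        reactions=list(network.reactions),
        pairs=dict(network.pairs),
        input_pairs=list(network.input_pairs),
        constant_pairs=list(network.constant_pairs),
        output_pair=network.output_pair,
    )
    for k, v in changes.items():
        setattr(out, k, v)
    return out
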