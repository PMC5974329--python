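"""DNA-strand-displacement emulation of bimolecular networks.

Each source reaction ``A + B -> products`` (rate k) is replaced by a
three-step toehold-mediated scheme over an enlarged species set:

    A + L_i  <->  H_i + G_i      (forward q_i, backward q_max)
    H_i + B   ->  O_i            (q_max)
    O_i + T_i ->  products       (q_max)

The link gate ``L_i``, backward-release strand ``G_i`` and translator
gate ``T_i`` are auxiliary complexes buffered at concentration c_max;
``H_i`` and ``O_i`` are transient intermediates.  With the buffers
large relative to the signal scale, quasi-steady-state analysis of
``H_i`` gives an effective flux q_i*[A]*[B]*c_max/(c_max+[B]), so
setting q_i = k_i reproduces the source kinetics with relative error
O(signal/c_max) + O(k_i/q_max); both vanish as the buffers and the
displacement rate grow.  Signal species map one-to-one to CRN species,
so decoding is unchanged.  No nucleotide sequences are involved:
species are abstract strands with role tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .crn import Reaction, ReactionNetwork
from .kinetics import RateModel, Trajectory, integrate

__all__ = [
    "DsdNetwork",
    "TranslationError",
    "translate_bimolecular",
    "simulate_dsd",
    "fidelity_sweep",
]

#: default buffering concentration, in units of the signal pair total
DEFAULT_C_MAX = 1e4
#: default maximum strand-displacement rate constant
DEFAULT_Q_MAX = 1e3


class TranslationError(ValueError):
    """A source rate constant exceeds what the scheme can emulate."""


@dataclass
class DsdNetwork:
    """Translated network plus the translation bookkeeping."""

    network: ReactionNetwork
    c_max: float
    q_max: float
    #: DSD reaction index -> source CRN reaction index
    origin_map: Dict[int, int] = field(default_factory=dict)
    #: species name -> role (signal | link_gate | release | intermediate |
    #: output_translator)
    roles: Dict[str, str] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [self.network.to_text().rstrip()]
        lines.append(f"# c_max={self.c_max!r} q_max={self.q_max!r}")
        for s in sorted(self.roles):
            lines.append(f"role: {s} {self.roles[s]}")
        return "\n".join(lines) + "\n"

    def origin_table(self) -> str:
        """Two-column DSD-reaction -> source-reaction mapping."""
        return "\n".join(f"{d}\t{s}" for d, s in sorted(self.origin_map.items())) + "\n"


def translate_bimolecular(network: ReactionNetwork,
                          c_max: float = DEFAULT_C_MAX,
                          q_max: float = DEFAULT_Q_MAX) -> DsdNetwork:
    """Translate every source reaction into its three-step DSD scheme."""
    network.validate()
    for idx, rx in enumerate(network.reactions):
        if rx.rate_constant / c_max > q_max:
            raise TranslationError(
                f"reaction {idx}: k={rx.rate_constant} needs k/c_max <= "
                f"q_max; increase c_max"
            )
        if rx.rate_constant > q_max:
            raise TranslationError(
                f"reaction {idx}: emulated rate q_i = k = {rx.rate_constant} "
                f"exceeds q_max={q_max}; increase q_max"
            )

    out = ReactionNetwork(
        pairs=dict(network.pairs),
        input_pairs=list(network.input_pairs),
        constant_pairs=list(network.constant_pairs),
        output_pair=network.output_pair,
    )
    roles: Dict[str, str] = {s: "signal" for s in network.species}
    origin: Dict[int, int] = {}
    extra: Dict[str, float] = {}
    for i, rx in enumerate(network.reactions):
        a, b = rx.reactants
        L, G, H, O, T = (f"{tag}{i}" for tag in ("L", "G", "H", "O", "T"))
        roles[L] = "link_gate"
        roles[G] = f"release:{a}"
        roles[H] = "intermediate"
        roles[O] = "intermediate"
        roles[T] = "output_translator"
        extra[L] = c_max
        extra[G] = c_max
        extra[T] = c_max
        extra[H] = 0.0
        extra[O] = 0.0
        steps = [
            Reaction((a, L), (H, G), rx.rate_constant),
            Reaction((H, G), (a, L), q_max),
            Reaction((H, b), (O,), q_max),
            Reaction((O, T), rx.products, q_max),
        ]
        for step in steps:
            origin[len(out.reactions)] = i
            out.reactions.append(step)
    out.extra_initial = extra
    out.validate()
    return DsdNetwork(network=out, c_max=c_max, q_max=q_max,
                      origin_map=origin, roles=roles)


def simulate_dsd(dsd: DsdNetwork, t_end: float = 1e3, **kwargs) -> Trajectory:
    """Integrate the translated system; decoding reads signal pairs only."""
    return integrate(dsd.network, t_end, **kwargs)


def _trajectory_distance(ref: Trajectory, traj: Trajectory,
                         pair_name: str) -> float:
    """Sup-norm distance of the output pair between two runs.

    Compares both members' concentration trajectories (normalized by
    the pair's final total) as well as the decoded reading.  The
    concentration comparison is the sensitive part: in cascades built
    here the decoded ratio is time-invariant, so only the completion
    kinetics reveal the emulation's O(1/c_max) lag.
    """
    p = ref.network.pairs[pair_name]
    scale = max(ref.species_series(p.species_0)[-1]
                + ref.species_series(p.species_1)[-1], 1e-30)
    err = 0.0
    for s in (p.species_0, p.species_1):
        err = max(err, float(np.max(np.abs(
            ref.species_series(s) - traj.species_series(s)))) / scale)
    mask = (~np.isnan(ref.decoded_output)) & (~np.isnan(traj.decoded_output))
    if mask.any():
        err = max(err, float(np.max(np.abs(
            ref.decoded_output[mask] - traj.decoded_output[mask]))))
    return err


def fidelity_sweep(network: ReactionNetwork, c_max_ladder: Sequence[float],
                   t_end: float = 1e3, q_max: float = DEFAULT_Q_MAX
                   ) -> List[dict]:
    """Emulation error of the translated system per buffering level."""
    if list(c_max_ladder) != sorted(c_max_ladder):
        raise ValueError("c_max ladder must be increasing")
    ref = integrate(network, t_end)
    rows = []
    for c_max in c_max_ladder:
        dsd = translate_bimolecular(network, c_max=c_max, q_max=q_max)
        traj = simulate_dsd(dsd, t_end)
        err = _trajectory_distance(ref, traj, network.output_pair)
        rows.append({"c_max": float(c_max), "sup_error": err})
    return rows
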