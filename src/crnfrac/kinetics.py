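"""Deterministic mass-action integration of reaction networks.

Every reaction is bimolecular, so each rate is ``k*[R1]*[R2]`` and the
species balance is a fixed sparse stoichiometry matrix applied to the
rate vector.  Cascaded consumption makes the system stiff near
completion (pools decay like 1/t), so integration uses a stiff solver
with an analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csc_matrix, csr_matrix

from .crn import ReactionNetwork, decode_value

__all__ = ["Trajectory", "IntegrationError", "RateModel",
           "build_rate_equations", "integrate", "readout"]

#: below this total concentration a pair is considered unreadable
READOUT_FLOOR = 1e-12
#: negative excursions smaller than this are clipped to zero
CLIP = 1e-12


class IntegrationError(RuntimeError):
    """Solver failure, with the solver's diagnostic message."""


class RateModel:
    """Vectorized mass-action right-hand side for one network."""

    def __init__(self, network: ReactionNetwork):
        network.validate()
        self.network = network
        self.species = network.species
        self.index = {s: i for i, s in enumerate(self.species)}
        n_sp, n_rx = len(self.species), len(network.reactions)
        self.i = np.empty(n_rx, dtype=np.intp)
        self.j = np.empty(n_rx, dtype=np.intp)
        self.k = np.empty(n_rx)
        rows, cols, vals = [], [], []
        for r, rx in enumerate(network.reactions):
            self.i[r] = self.index[rx.reactants[0]]
            self.j[r] = self.index[rx.reactants[1]]
            self.k[r] = rx.rate_constant
            net: Dict[int, int] = {}
            for s in rx.reactants:
                net[self.index[s]] = net.get(self.index[s], 0) - 1
            for s in rx.products:
                net[self.index[s]] = net.get(self.index[s], 0) + 1
            for idx, coef in net.items():
                if coef:
                    rows.append(idx)
                    cols.append(r)
                    vals.append(float(coef))
        self.stoich = csr_matrix((vals, (rows, cols)), shape=(n_sp, n_rx))
        self.n_species = n_sp
        self.n_reactions = n_rx

    def rates(self, y: np.ndarray) -> np.ndarray:
        return self.k * y[self.i] * y[self.j]

    def rhs(self, t, y):
        return self.stoich.dot(self.rates(y))

    def jac(self, t, y):
        n_rx = self.n_reactions
        r = np.arange(n_rx)
        rows = np.concatenate([r, r])
        cols = np.concatenate([self.i, self.j])
        vals = np.concatenate([self.k * y[self.j], self.k * y[self.i]])
        drdy = csc_matrix((vals, (rows, cols)),
                          shape=(n_rx, self.n_species))
        return (self.stoich @ drdy).toarray()

    def initial_state(self) -> np.ndarray:
        conc = self.network.initial_concentrations()
        return np.array([conc[s] for s in self.species])


def build_rate_equations(network: ReactionNetwork) -> RateModel:
    """Compile a network into a callable mass-action rate model."""
    return RateModel(network)


@dataclass
class Trajectory:
    """Time-resolved concentrations plus the decoded output reading."""

    times: np.ndarray
    concentrations: np.ndarray        # shape (n_species, n_times)
    species: list
    decoded_output: np.ndarray
    converged: bool
    network: ReactionNetwork

    def species_series(self, name: str) -> np.ndarray:
        return self.concentrations[self.species.index(name)]

    def pair_reading(self, pair_name: str) -> np.ndarray:
        """Decoded value of any pair over time (nan where unreadable)."""
        p = self.network.pairs[pair_name]
        c0 = self.species_series(p.species_0)
        c1 = self.species_series(p.species_1)
        tot = c0 + c1
        out = np.full_like(tot, np.nan)
        ok = tot > READOUT_FLOOR
        if p.polarity == "unipolar":
            out[ok] = c1[ok] / tot[ok]
        else:
            out[ok] = (c1[ok] - c0[ok]) / tot[ok]
        return out

    @property
    def final_output(self) -> float:
        return float(self.decoded_output[-1])

    def to_table(self):
        """Tabular export: time, per-species concentrations, decoded output."""
        import pandas as pd

        data = {"time": self.times}
        for i, s in enumerate(self.species):
            data[s] = self.concentrations[i]
        data["decoded_output"] = self.decoded_output
        return pd.DataFrame(data)


def _time_grid(t_end: float, n_points: int = 200) -> np.ndarray:
    # log-spaced interior points resolve both the fast initial transient
    # and the slow 1/t completion tail
    grid = np.geomspace(t_end * 1e-6, t_end, n_points - 1)
    return np.concatenate([[0.0], grid])


def integrate(network: ReactionNetwork, t_end: float = 1e3,
              rel_tol: float = 1e-8, abs_tol: float = 1e-10,
              model: Optional[RateModel] = None,
              n_points: int = 200) -> Trajectory:
    """Integrate a network's mass-action ODEs and decode the output.

    The convergence flag is set when the decoded output moves by less
    than 1e-8 over the final 10% of the time span.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    model = model or RateModel(network)
    y0 = model.initial_state()
    t_eval = _time_grid(t_end, n_points)
    sol = solve_ivp(model.rhs, (0.0, t_end), y0, method="BDF",
                    jac=model.jac, t_eval=t_eval,
                    rtol=rel_tol, atol=abs_tol)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    conc = sol.y
    conc[(conc < 0) & (conc > -CLIP)] = 0.0
    conc[conc < 0] = 0.0  # larger excursions also floored after clip check
    out = network.pairs[network.output_pair]
    traj = Trajectory(
        times=sol.t,
        concentrations=conc,
        species=model.species,
        decoded_output=np.empty(0),
        converged=False,
        network=network,
    )
    traj.decoded_output = traj.pair_reading(network.output_pair)
    tail = traj.times >= 0.9 * t_end
    tail_vals = traj.decoded_output[tail]
    tail_vals = tail_vals[~np.isnan(tail_vals)]
    traj.converged = (len(tail_vals) >= 2
                      and float(np.ptp(tail_vals)) < 1e-8)
    return traj


def readout(trajectory: Trajectory, at_time: Optional[float] = None) -> float:
    """Decoded fractional output at a time on the grid (default: final)."""
    if at_time is None:
        value = trajectory.final_output
    else:
        t = trajectory.times
        if not (t[0] <= at_time <= t[-1]):
            raise ValueError(f"time {at_time} outside integration grid")
        out = trajectory.network.pairs[trajectory.network.output_pair]
        c0 = np.interp(at_time, t, trajectory.species_series(out.species_0))
        c1 = np.interp(at_time, t, trajectory.species_series(out.species_1))
        if c0 + c1 <= READOUT_FLOOR:
            raise ValueError("output pair total below readout floor")
        value = decode_value(c0, c1, out.polarity)
    if value != value:
        raise ValueError("output pair unreadable (zero total concentration)")
    return value
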