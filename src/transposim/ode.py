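"""Deterministic (ODE) engine.

Assembles mass-action fluxes from a :class:`~transposim.network.ReactionNetwork`
and integrates copy-number trajectories with a stiff-capable adaptive
solver.  The system is deliberately transient — genomic TE copies never
decay — so runs are integrated to a fixed horizon (two years by default)
rather than to steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .network import CompiledNetwork, ModelVariant, ReactionNetwork
from .params import ParameterSet

__all__ = [
    "Trajectory",
    "TerminalOutcome",
    "IntegrationError",
    "initial_state",
    "flux_vector",
    "ode_rhs",
    "integrate_ode",
    "terminal_outcome",
    "HORIZON_HOURS",
    "OVERFLOW_LIMIT",
]

#: Default simulation horizon: two years, in hours.
HORIZON_HOURS = 2 * 365 * 24  # 17 520

#: Any species exceeding this count marks the run as diverged.
OVERFLOW_LIMIT = 1e12


class IntegrationError(RuntimeError):
    """Solver failure; carries the last accepted state and time."""

    def __init__(self, message: str, t_last: float, state_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@njit(cache=True)
def _fluxes_det(y, law_type, law_k, law_s1, law_s2, law_c, out):
    # Negative entries (solver undershoot) contribute zero flux, which
    # also guarantees the analytic non-negativity of the ODE system.
    for r in range(law_type.size):
        x1 = y[law_s1[r]]
        if x1 < 0.0:
            x1 = 0.0
        t = law_type[r]
        if t == 0:  # linear
            out[r] = law_k[r] * x1
        elif t == 1:  # bilinear
            x2 = y[law_s2[r]]
            if x2 < 0.0:
                x2 = 0.0
            out[r] = law_k[r] * x1 * x2
        elif t == 2:  # second order, single species
            out[r] = law_k[r] * x1 * x1
        else:  # saturating: k * x1 * x2 / (c + x2)
            x2 = y[law_s2[r]]
            if x2 < 0.0:
                x2 = 0.0
            out[r] = law_k[r] * x1 * x2 / (law_c[r] + x2)
    return out


@njit(cache=True)
def _rhs_det(y, stoich, law_type, law_k, law_s1, law_s2, law_c):
    flux = np.empty(law_type.size, dtype=np.float64)
    _fluxes_det(y, law_type, law_k, law_s1, law_s2, law_c, flux)
    return stoich @ flux


def initial_state(
    network: ReactionNetwork, overrides: Mapping[str, float] | None = None
) -> np.ndarray:
    """Invasion initial condition: one active TE, everything else zero."""
    y0 = np.zeros(network.n_species, dtype=np.float64)
    y0[network.species_index("T_act")] = 1.0
    if overrides:
        y0[network.species_index("T_act")] = 0.0 if "T_act" in overrides else 1.0
        for name, value in overrides.items():
            y0[network.species_index(name)] = float(value)
    return y0


def _as_state(network: ReactionNetwork, state) -> np.ndarray:
    if isinstance(state, Mapping):
        y = np.zeros(network.n_species)
        for name, value in state.items():
            y[network.species_index(name)] = float(value)
        return y
    y = np.asarray(state, dtype=np.float64)
    if y.shape != (network.n_species,):
        raise ValueError(
            f"state has shape {y.shape}, expected ({network.n_species},) for the "
            f"{network.variant.value} network"
        )
    return y


def flux_vector(
    network: ReactionNetwork,
    state,
    params: ParameterSet,
    compiled: CompiledNetwork | None = None,
) -> np.ndarray:
    """Per-reaction fluxes (#mol/hr), ordered like ``network.reactions``."""
    y = _as_state(network, state)
    if np.any(y < 0):
        bad = network.species[int(np.argmin(y))]
        raise ValueError(f"negative copy number for species {bad!r}")
    c = compiled or network.compile(params)
    out = np.empty(len(c.reaction_ids), dtype=np.float64)
    _fluxes_det(y, c.law_type, c.law_k, c.law_s1, c.law_s2, c.law_c, out)
    return out


def ode_rhs(
    network: ReactionNetwork,
    state,
    params: ParameterSet,
    compiled: CompiledNetwork | None = None,
) -> np.ndarray:
    """Time derivative of every species: stoichiometry times flux."""
    y = _as_state(network, state)
    if np.any(y < 0):
        bad = network.species[int(np.argmin(y))]
        raise ValueError(f"negative copy number for species {bad!r}")
    c = compiled or network.compile(params)
    return _rhs_det(y, c.stoich, c.law_type, c.law_k, c.law_s1, c.law_s2, c.law_c)


@dataclass
class Trajectory:
    """Time course of one deterministic or stochastic run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    variant: ModelVariant
    params: ParameterSet
    species: tuple[str, ...]
    diverged: bool = False
    n_events: int | None = None  # stochastic runs only
    meta: dict = field(default_factory=dict)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def final(self, species: str) -> float:
        return float(self.final_state[self.species.index(species)])

    def to_dataframe(self, run_id: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time_hr", self.times)
        df["variant"] = self.variant.value
        if run_id is not None:
            df["run_id"] = run_id
        return df


@dataclass(frozen=True)
class TerminalOutcome:
    """Terminal observables of one run, plus the control verdict."""

    T_act: float
    T_sil: float
    VLP: float
    control: bool
    diverged: bool
    variant: ModelVariant
    params: ParameterSet

    @property
    def total_te(self) -> float:
        return self.T_act + self.T_sil


def integrate_ode(
    network: ReactionNetwork,
    params: ParameterSet,
    init=None,
    t_end: float = HORIZON_HOURS,
    output_grid: Sequence[float] | int | None = 200,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    overflow: float = OVERFLOW_LIMIT,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one trajectory from ``init`` to ``t_end``.

    Parameters
    ----------
    init :
        Initial state (array in species order, or a mapping of species
        names); defaults to the single-invader condition ``T_act = 1``.
    output_grid :
        Number of evenly spaced output points, or an explicit grid.
        Terminal classification only needs the final state, so ensemble
        callers pass a 2-point grid.
    overflow :
        Divergence guard: integration stops and the trajectory is marked
        ``diverged`` once any species exceeds this count.  Uncontrolled
        invasions blow up in finite time (VLP production is second order
        in the mRNA count), so this is an expected outcome, not an error.
    """
    y0 = initial_state(network) if init is None else _as_state(network, init)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    compiled = network.compile(params)
    if t_end == 0:
        return Trajectory(
            times=np.array([0.0]), states=y0[None, :].copy(),
            variant=network.variant, params=params, species=network.species,
        )
    if isinstance(output_grid, int):
        t_eval = np.linspace(0.0, t_end, output_grid)
    elif output_grid is None:
        t_eval = np.array([0.0, t_end])
    else:
        t_eval = np.asarray(output_grid, dtype=np.float64)

    c = compiled

    def rhs(t, y):
        return _rhs_det(y, c.stoich, c.law_type, c.law_k, c.law_s1, c.law_s2, c.law_c)

    def overflow_event(t, y):
        return overflow - np.max(y)

    overflow_event.terminal = True
    overflow_event.direction = -1

    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, events=overflow_event, dense_output=False,
    )
    diverged = sol.status == 1  # terminated by the overflow event
    if sol.status < 0:
        t_last = float(sol.t[-1]) if sol.t.size else 0.0
        y_last = sol.y[:, -1] if sol.t.size else y0
        raise IntegrationError(
            f"ODE solver failed at t={t_last:.3g} h: {sol.message}", t_last, y_last
        )
    times = sol.t
    states = sol.y.T
    if diverged and sol.t_events[0].size:
        times = np.append(times, sol.t_events[0][0])
        states = np.vstack([states, sol.y_events[0][0]])
    if times.size == 0 or times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        states = np.vstack([y0, states])

    undershoot = float(states.min(initial=0.0))
    scale = float(np.abs(states).max(initial=1.0))
    if undershoot < -(10 * atol + 1e-9 * scale):
        raise IntegrationError(
            f"solver produced negative copy numbers ({undershoot:.3g})",
            float(times[-1]), states[-1],
        )
    states = np.clip(states, 0.0, None)
    return Trajectory(
        times=times, states=states, variant=network.variant, params=params,
        species=network.species, diverged=diverged,
        meta={"rtol": rtol, "atol": atol, "method": method, "nfev": sol.nfev},
    )


def terminal_outcome(traj: Trajectory) -> TerminalOutcome:
    """Terminal (T_act, T_sil, VLP) and the control verdict (VLP < 1)."""
    t_act = traj.final("T_act")
    t_sil = traj.final("T_sil")
    vlp = traj.final("VLP")
    return TerminalOutcome(
        T_act=t_act, T_sil=t_sil, VLP=vlp,
        control=bool(vlp < 1.0), diverged=traj.diverged,
        variant=traj.variant, params=traj.params,
    )
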