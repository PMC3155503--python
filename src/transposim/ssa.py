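"""Exact stochastic simulation (Gillespie direct method).

The same reaction networks as the deterministic engine, simulated as a
continuous-time Markov jump process on integer copy numbers: waiting
times are exponential in the total propensity and the firing reaction is
chosen proportionally to its propensity.  Bimolecular reactions between
two copies of the same species (VLP packaging, second order in the
cytoplasmic mRNA) use the combinatorial count ``x*(x-1)`` in place of
the deterministic ``x**2``.

The integration success fraction ``f`` is realised by the two
integration channels of the network (success at ``f*j*VLP``, failure at
``(1-f)*j*VLP``); under the direct method this is identical in law to a
single attempt event at rate ``j*VLP`` whose outcome is a Bernoulli(f)
draw.

The inner loop is compiled with numba; a long two-year run of the
default model executes a few tens of millions of events.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numba import njit

from .network import CompiledNetwork, ReactionNetwork
from .ode import Trajectory, integrate_ode
from .params import ParameterSet

__all__ = ["propensities", "simulate_ssa", "ode_ssa_agreement", "SSABudgetExceeded"]


class SSABudgetExceeded(RuntimeError):
    """Event budget exhausted; carries the partial trajectory."""

    def __init__(self, message: str, trajectory: Trajectory):
        super().__init__(message)
        self.trajectory = trajectory


@njit(cache=True)
def _propensities_int(y, law_type, law_k, law_s1, law_s2, law_c, out):
    for r in range(law_type.size):
        x1 = y[law_s1[r]]
        t = law_type[r]
        if t == 0:
            out[r] = law_k[r] * x1
        elif t == 1:
            out[r] = law_k[r] * x1 * y[law_s2[r]]
        elif t == 2:  # combinatorial count of unordered pairs (x choose 2) * 2
            out[r] = law_k[r] * x1 * (x1 - 1)
        else:
            x2 = y[law_s2[r]]
            out[r] = law_k[r] * x1 * x2 / (law_c[r] + x2)
    return out


@njit(cache=True)
def _ssa_core(stoich, law_type, law_k, law_s1, law_s2, law_c,
              y0, t_end, t_grid, seed, max_events):
    """Direct-method core.

    Returns (grid_states, final_state, n_events, status) where status is
    0 = reached t_end, 1 = event budget exceeded.  ``grid_states`` holds
    the piecewise-constant state sampled at ``t_grid``.
    """
    np.random.seed(seed)
    ns = y0.size
    nr = law_type.size
    y = y0.copy()
    a = np.empty(nr, dtype=np.float64)
    grid_states = np.zeros((t_grid.size, ns), dtype=np.int64)
    gi = 0
    t = 0.0
    n_events = 0
    status = 0
    while True:
        _propensities_int(y, law_type, law_k, law_s1, law_s2, law_c, a)
        a_total = a.sum()
        if a_total <= 0.0:
            t_next = t_end + 1.0
        else:
            t_next = t + np.random.exponential(1.0 / a_total)
        while gi < t_grid.size and t_grid[gi] <= min(t_next, t_end):
            for s in range(ns):
                grid_states[gi, s] = y[s]
            gi += 1
        if t_next > t_end:
            t = t_end
            break
        t = t_next
        # propensity-proportional choice
        u = np.random.random() * a_total
        acc = 0.0
        r = nr - 1
        for k in range(nr):
            acc += a[k]
            if u < acc:
                r = k
                break
        for s in range(ns):
            y[s] += int(stoich[s, r])
        n_events += 1
        if n_events >= max_events:
            status = 1
            break
    while gi < t_grid.size and (status == 0 or t_grid[gi] <= t):
        for s in range(ns):
            grid_states[gi, s] = y[s]
        gi += 1
    return grid_states, y, n_events, status, t


def _int_state(network: ReactionNetwork, init) -> np.ndarray:
    from .ode import initial_state, _as_state

    y = initial_state(network) if init is None else _as_state(network, init)
    rounded = np.rint(y)
    if np.any(np.abs(y - rounded) > 1e-9):
        bad = network.species[int(np.argmax(np.abs(y - rounded)))]
        raise ValueError(f"stochastic initial state must be integer; species {bad!r} is {y[network.species_index(bad)]}")
    if np.any(rounded < 0):
        raise ValueError("stochastic initial state must be non-negative")
    return rounded.astype(np.int64)


def _int_stoich(network: ReactionNetwork, compiled: CompiledNetwork) -> np.ndarray:
    stoich = np.rint(compiled.stoich).astype(np.int64)
    if np.any(np.abs(compiled.stoich - stoich) > 1e-12):
        raise ValueError("non-integer stoichiometry; cannot simulate stochastically")
    return stoich


def propensities(
    network: ReactionNetwork,
    state,
    params: ParameterSet,
    compiled: CompiledNetwork | None = None,
) -> np.ndarray:
    """Per-reaction propensities (hr^-1) for an integer state."""
    y = _int_state(network, state)
    c = compiled or network.compile(params)
    out = np.empty(len(c.reaction_ids), dtype=np.float64)
    _propensities_int(y.astype(np.float64), c.law_type, c.law_k, c.law_s1, c.law_s2, c.law_c, out)
    return out


def simulate_ssa(
    network: ReactionNetwork,
    params: ParameterSet,
    init=None,
    t_end: float = 17_520.0,
    rng_seed: int = 0,
    output_grid: Sequence[float] | int | None = 200,
    max_events: int = 100_000_000,
) -> Trajectory:
    """One exact stochastic trajectory, reproducible for a fixed seed.

    Raises :class:`SSABudgetExceeded` (carrying the partial trajectory)
    if more than ``max_events`` reactions fire before ``t_end``.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    y0 = _int_state(network, init)
    c = network.compile(params)
    stoich = _int_stoich(network, c)
    if isinstance(output_grid, int):
        t_grid = np.linspace(0.0, t_end, output_grid)
    elif output_grid is None:
        t_grid = np.array([0.0, t_end])
    else:
        t_grid = np.asarray(output_grid, dtype=np.float64)
    grid_states, y_final, n_events, status, t_stop = _ssa_core(
        stoich, c.law_type, c.law_k, c.law_s1, c.law_s2, c.law_c,
        y0, float(t_end), t_grid, int(rng_seed) & 0x7FFFFFFF, int(max_events),
    )
    traj = Trajectory(
        times=t_grid.copy(), states=grid_states.astype(np.float64),
        variant=network.variant, params=params, species=network.species,
        diverged=False, n_events=int(n_events),
        meta={"seed": int(rng_seed), "engine": "ssa", "t_stop": float(t_stop)},
    )
    if status == 1:
        keep = traj.times <= t_stop
        partial = Trajectory(
            times=traj.times[keep], states=traj.states[keep],
            variant=traj.variant, params=traj.params, species=traj.species,
            diverged=True, n_events=int(n_events), meta=traj.meta,
        )
        raise SSABudgetExceeded(
            f"event budget of {max_events} exceeded at t={t_stop:.3g} h", partial
        )
    # final state at t_end (grid may not include t_end exactly)
    if t_grid.size == 0 or t_grid[-1] != t_end:
        traj.times = np.append(traj.times, t_end)
        traj.states = np.vstack([traj.states, y_final.astype(np.float64)])
    else:
        traj.states[-1] = y_final
    return traj


def ode_ssa_agreement(
    network: ReactionNetwork,
    params: ParameterSet,
    init_scale: float = 1.0,
    t_probe: float = 10.0,
    n_replicates: int = 8,
    rng_seed: int = 0,
    init=None,
) -> dict[str, float]:
    """Relative deviation between SSA replicate means and the ODE solution.

    The initial condition (single-invader by default, or ``init``) is
    multiplied by ``init_scale`` to push counts into the large-number
    regime where the jump process concentrates on the fluid limit.
    Deviations are normalised by ``max(|ODE value|, 0.01 * init_scale)``
    so that pools the dynamics have emptied (both descriptions near
    zero) do not register spurious relative error.
    """
    from .ode import initial_state, _as_state

    base = initial_state(network) if init is None else _as_state(network, init)
    y0 = np.rint(base * init_scale).astype(np.int64)
    ode_traj = integrate_ode(
        network, params, init=y0.astype(np.float64), t_end=t_probe, output_grid=None
    )
    ode_final = ode_traj.final_state
    acc = np.zeros(network.n_species)
    for rep in range(n_replicates):
        traj = simulate_ssa(
            network, params, init=y0, t_end=t_probe,
            rng_seed=rng_seed + rep, output_grid=None,
        )
        acc += traj.final_state
    mean = acc / n_replicates
    floor = 0.01 * max(init_scale, 1.0)
    return {
        sp: float(abs(mean[i] - ode_final[i]) / max(abs(ode_final[i]), floor))
        for i, sp in enumerate(network.species)
    }
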