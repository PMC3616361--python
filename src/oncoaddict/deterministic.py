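"""Mean-field engine: the same model with every draw replaced by its mean.

The expectation of each multinomial exit is ``n * K * dt`` and of each
binomial birth ``n * K_prolif * dt``, so the mean-field update is the
forward-Euler discretization of a linear system of delay differential
equations: for the apoptosis-committed compartment,

    dA/dt = phi(t) - phi(t - tau_apop),

where ``phi`` is the total apoptosis-commitment influx and ``phi(t) = 0``
for t < 0 (no pre-history of commitment).  The discrete delay indexing
mirrors the stochastic engine's cohort queue exactly, so the stochastic
model is an exact-expectation refinement of this engine: averaging many
stochastic runs converges to this trajectory.

Negative values from Euler undershoot are clamped to zero with a warning;
at dt = 0.02 d and the default rate table this never triggers.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .model_core import (
    STATES,
    STATE_INDEX,
    CellStateVector,
    MycSchedule,
    RateParameters,
    ValidationError,
    birth_rate,
    _exit_rates,
)
from .stochastic import Trajectory, _grid

__all__ = ["FluxHistory", "simulate_deterministic", "oracle_fine_grid"]

_A = STATE_INDEX["A"]


class FluxHistory:
    """Ring buffer of apoptosis-commitment fluxes over the last ``tau_apop``.

    ``push(flux)`` records the commitment flux of the current step and
    returns the flux that matures (dies) this step — the one recorded
    ``delay_steps - 1`` steps ago (the same step for delays of at most one
    step), matching the stochastic cohort queue.  Initialized to zero: no
    commitments predate t = 0.
    """

    __slots__ = ("_buf", "_pos")

    def __init__(self, delay_steps: int) -> None:
        lag = max(delay_steps - 1, 0)
        self._buf = np.zeros(lag) if lag else None
        self._pos = 0

    def push(self, flux: float) -> float:
        if self._buf is None:
            return flux
        matured = self._buf[self._pos]
        self._buf[self._pos] = flux
        self._pos = (self._pos + 1) % len(self._buf)
        return matured

    @property
    def total(self) -> float:
        return float(self._buf.sum()) if self._buf is not None else 0.0


def _compile_rate_tables(params: RateParameters):
    """(src, dest_idx[], rates[], birth_rate, a_slot) per MYC program."""
    tables = {}
    for program in ("on", "off"):
        entries = []
        for s in STATES:
            exits = _exit_rates(params, s, program)
            b = birth_rate(params, s)
            if not exits and b == 0.0:
                continue
            dests = np.array([STATE_INDEX[d] for d in exits], dtype=np.intp)
            rates = np.array(list(exits.values()), dtype=float)
            a_slot = list(exits).index("A") if "A" in exits else -1
            entries.append((STATE_INDEX[s], dests, rates, b, a_slot))
        tables[program] = entries
    return tables


def simulate_deterministic(
    params: RateParameters,
    initial: CellStateVector,
    schedule: MycSchedule,
    t_end: float,
    *,
    bli_states: tuple[str, ...] = STATES,
) -> Trajectory:
    """Integrate the mean-field delay system by forward Euler over [0, t_end]."""
    if t_end <= 0:
        raise ValidationError(f"t_end must be > 0, got {t_end}")
    times = _grid(t_end, params.dt)
    n_steps = len(times) - 1
    dt = params.dt
    tables = _compile_rate_tables(params)
    program_on = schedule.on_grid(times[:-1])
    delay_steps = params.delay_steps

    counts = np.zeros((n_steps + 1, len(STATES)))
    counts[0] = initial.as_array()
    history = FluxHistory(delay_steps)
    # pre-existing committed cells are treated as committing at t = 0
    pending_initial_a = float(counts[0, _A])

    clamped = False
    for i in range(n_steps):
        entries = tables["on"] if program_on[i] else tables["off"]
        c = counts[i]
        new = c.copy()
        commits = 0.0
        for src, dests, rates, b, a_slot in entries:
            x = c[src]
            if x == 0.0:
                continue
            flows = x * rates * dt
            new[src] -= flows.sum()
            new[dests] += flows
            if a_slot >= 0:
                commits += flows[a_slot]
            if b:
                new[src] += x * b * dt
        if i == 0:
            commits += pending_initial_a
        new[_A] -= history.push(commits)
        if np.any(new < 0):
            if np.any(new < -1e-9 * max(1.0, c.sum())):
                clamped = True
            new = np.maximum(new, 0.0)
        counts[i + 1] = new
    if clamped:
        warnings.warn("Euler undershoot produced negative counts; clamped to 0")

    bli_idx = np.array([STATE_INDEX[s] for s in bli_states], dtype=np.intp)
    return Trajectory(
        times=times,
        counts=counts,
        bli_signal=counts[:, bli_idx].sum(axis=1),
        params=params,
        schedule=schedule,
        seed=None,
        bli_states=tuple(bli_states),
        run_id="deterministic",
    )


def oracle_fine_grid(
    params: RateParameters,
    initial: CellStateVector,
    schedule: MycSchedule,
    t_end: float,
    refinement: int,
    *,
    bli_states: tuple[str, ...] = STATES,
) -> Trajectory:
    """Same model integrated at ``dt / refinement`` (method of steps).

    Verification aid: refining the grid shrinks the Euler discretization
    error toward the continuous-time solution.  ``refinement=1`` is
    identical to :func:`simulate_deterministic`.
    """
    if refinement < 1:
        raise ValidationError(f"refinement must be >= 1, got {refinement}")
    fine = replace(params, dt=params.dt / refinement)
    return simulate_deterministic(fine, initial, schedule, t_end, bli_states=bli_states)
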