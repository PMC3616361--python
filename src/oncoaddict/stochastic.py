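"""Stochastic engine: integer-count Euler steps with multinomial draws.

Each step of length ``dt`` draws, for every source state with ``n`` cells and
active exit probabilities ``p_1..p_k``, one multinomial sample
``(n; p_1..p_k, 1 - sum p)`` so the exits are mutually exclusive and can
never oversubscribe the state.  Proliferating states add a binomial
``(n, K_prolif * dt)`` number of daughters to themselves.  Cells entering A
are enqueued in a FIFO of integer cohorts and removed (actual death) once
the commitment-to-death delay ``tau_apop`` has elapsed.

Order of operations within a step (start-of-step counts everywhere):
transitions are drawn first, then births are applied, then matured apoptosis
cohorts are dequeued — so daughters born in a step are not eligible to
transition until the next step.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    STATES,
    STATE_INDEX,
    CellStateVector,
    MycSchedule,
    RateParameters,
    ValidationError,
    birth_probability,
    exit_probabilities,
)

__all__ = [
    "DelayQueue",
    "Trajectory",
    "step_stochastic",
    "simulate",
    "run_ensemble",
    "derive_run_seeds",
]

_A = STATE_INDEX["A"]

# counts beyond this would make int64 draws unsafe; the model has no carrying
# capacity, so unbounded post-relapse growth must be truncated by the caller
# (see the stop_above argument of simulate)
_COUNT_LIMIT = 2**62


class DelayQueue:
    """FIFO of apoptosis-committed cohorts awaiting actual death.

    Cohorts are keyed to the integration grid: a cohort committed during the
    step starting at grid index ``m`` matures (is removed from A) in the step
    with index ``m + K - 1`` where ``K = tau_apop / dt`` (same step for
    ``K <= 1``).  The queued total always equals the current A count.
    """

    __slots__ = ("_cohorts", "dt")

    def __init__(self, dt: float) -> None:
        self._cohorts: deque[list[int]] = deque()
        self.dt = dt

    def push(self, death_step: int, count: int) -> None:
        if count < 0:
            raise ValidationError(f"cohort count must be >= 0, got {count}")
        if count == 0:
            return
        if self._cohorts and self._cohorts[-1][0] > death_step:
            raise ValidationError("cohort death times must be non-decreasing")
        if self._cohorts and self._cohorts[-1][0] == death_step:
            self._cohorts[-1][1] += count
        else:
            self._cohorts.append([death_step, count])

    def pop_due(self, step: int) -> int:
        """Remove and total all cohorts with death_time <= (step + 1) * dt."""
        died = 0
        while self._cohorts and self._cohorts[0][0] <= step + 1:
            died += self._cohorts.popleft()[1]
        return died

    @property
    def total(self) -> int:
        return sum(c for _, c in self._cohorts)

    @property
    def cohorts(self) -> list[tuple[float, int]]:
        """(death_time_days, cell_count) pairs, earliest first."""
        return [(s * self.dt, c) for s, c in self._cohorts]

    def copy(self) -> "DelayQueue":
        q = DelayQueue(self.dt)
        q._cohorts = deque([list(c) for c in self._cohorts])
        return q


@dataclass
class Trajectory:
    """Time series of state counts on a uniform dt grid, plus the BLI proxy.

    ``bli_signal[i]`` is the sum of ``counts[i]`` over ``bli_states`` — by
    default all six states, since apoptosis-committed (and differentiated,
    senescent, escaped) cells still produce bioluminescence signal until
    actual death.
    """

    times: np.ndarray
    counts: np.ndarray  # shape (n_points, 6), column order = STATES
    bli_signal: np.ndarray
    params: RateParameters
    schedule: MycSchedule
    seed: int | None
    bli_states: tuple[str, ...]
    run_id: str = "0"

    @property
    def states(self) -> list[CellStateVector]:
        return [self.state_at(i) for i in range(len(self.times))]

    def state_at(self, i: int) -> CellStateVector:
        return CellStateVector.from_array(self.counts[i], t=float(self.times[i]))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(STATES))
        df.insert(0, "t", self.times)
        df["bli_signal"] = self.bli_signal
        df["run_id"] = self.run_id
        return df


def _compile_kernel(params: RateParameters):
    """Per-program step tables: (src_idx, dest_idx[], p_with_stay[], p_birth, a_slot)."""
    tables = {}
    for program in ("on", "off"):
        entries = []
        for s in STATES:
            exits = exit_probabilities(params, s, program)
            p_birth = birth_probability(params, s)
            if not exits and p_birth == 0.0:
                continue
            dests = np.array([STATE_INDEX[d] for d in exits], dtype=np.intp)
            probs = np.array(list(exits.values()), dtype=float)
            pvec = np.append(probs, 1.0 - probs.sum())
            a_slot = list(exits).index("A") if "A" in exits else -1
            entries.append((STATE_INDEX[s], dests, pvec, p_birth, a_slot))
        tables[program] = entries
    return tables


def _step_counts(counts, queue, entries, delay_steps, step_index, rng):
    """One Euler step on an int64 state array; returns (new_counts, commits)."""
    new = counts.copy()
    commits = 0
    for src, dests, pvec, p_birth, a_slot in entries:
        n = int(counts[src])
        if n == 0:
            continue
        if dests.size:
            moves = rng.multinomial(n, pvec)
            moved = moves[:-1]
            total_moved = int(n - moves[-1])
            if total_moved:
                new[src] -= total_moved
                new[dests] += moved
                if a_slot >= 0:
                    commits += int(moved[a_slot])
        if p_birth > 0.0:
            new[src] += rng.binomial(n, p_birth)
    if commits:
        queue.push(step_index + delay_steps, commits)
    died = queue.pop_due(step_index)
    if died:
        new[_A] -= died
    return new, commits


def step_stochastic(
    state: CellStateVector,
    queue: DelayQueue,
    params: RateParameters,
    program: str,
    rng: np.random.Generator,
) -> tuple[CellStateVector, DelayQueue]:
    """Advance one state vector by a single stochastic Euler step.

    Returns the state at ``t + dt`` and the updated (copied) delay queue.
    """
    arr = state.as_array(dtype=float)
    if np.any(arr != np.floor(arr)):
        raise ValidationError("stochastic engine requires integer counts")
    counts = arr.astype(np.int64)
    if int(counts[_A]) != queue.total:
        raise ValidationError(
            f"queue total {queue.total} does not match A count {counts[_A]}"
        )
    entries = _compile_kernel(params)[program]
    step_index = round(state.t / params.dt)
    q = queue.copy()
    new, _ = _step_counts(counts, q, entries, params.delay_steps, step_index, rng)
    return CellStateVector.from_array(new, t=state.t + params.dt), q


def _grid(t_end: float, dt: float) -> np.ndarray:
    n_steps = math.ceil(t_end / dt - 1e-9)
    if not math.isclose(n_steps * dt, t_end, rel_tol=0.0, abs_tol=1e-9):
        warnings.warn(
            f"t_end={t_end} is not a multiple of dt={dt}; rounded up to {n_steps * dt}",
            stacklevel=3,
        )
    return np.arange(n_steps + 1) * dt


def simulate(
    params: RateParameters,
    initial: CellStateVector,
    schedule: MycSchedule,
    t_end: float,
    seed,
    *,
    bli_states: tuple[str, ...] = STATES,
    stop_above: float | None = None,
    run_id: str = "0",
) -> Trajectory:
    """Run one seeded stochastic realization over ``[0, t_end]``.

    The result is a deterministic function of the inputs and ``seed``.  If
    ``stop_above`` is given, the run is truncated at the first grid point
    whose BLI signal reaches that ceiling (used for open-ended relapse
    growth, which otherwise increases without bound).
    """
    if t_end <= 0:
        raise ValidationError(f"t_end must be > 0, got {t_end}")
    init = initial.as_array(dtype=float)
    if np.any(init != np.floor(init)):
        raise ValidationError("stochastic engine requires integer initial counts")
    times = _grid(t_end, params.dt)
    n_steps = len(times) - 1
    rng = np.random.default_rng(seed)
    tables = _compile_kernel(params)
    program_on = schedule.on_grid(times[:-1])
    delay_steps = params.delay_steps

    counts = np.zeros((n_steps + 1, len(STATES)), dtype=np.int64)
    counts[0] = init.astype(np.int64)
    queue = DelayQueue(params.dt)
    if counts[0, _A]:
        # pre-existing committed cells are treated as committing at t = 0
        queue.push(delay_steps, int(counts[0, _A]))

    bli_idx = np.array([STATE_INDEX[s] for s in bli_states], dtype=np.intp)
    entries_on = tables["on"]
    entries_off = tables["off"]
    last = n_steps
    for i in range(n_steps):
        entries = entries_on if program_on[i] else entries_off
        counts[i + 1], _ = _step_counts(counts[i], queue, entries, delay_steps, i, rng)
        if counts[i + 1].max() > _COUNT_LIMIT:
            raise OverflowError(
                "cell counts exceed the safe 64-bit range; shorten t_end or "
                "pass stop_above to truncate unbounded growth"
            )
        if stop_above is not None and counts[i + 1, bli_idx].sum() >= stop_above:
            last = i + 1
            break
    times = times[: last + 1]
    counts = counts[: last + 1]
    bli = counts[:, bli_idx].sum(axis=1)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None
    return Trajectory(
        times=times,
        counts=counts,
        bli_signal=bli,
        params=params,
        schedule=schedule,
        seed=int(seed_repr) if seed_repr is not None else None,
        bli_states=tuple(bli_states),
        run_id=run_id,
    )


def derive_run_seeds(base_seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run seeds: first ``n_runs`` 32-bit words of
    ``SeedSequence(base_seed)``, masked to 31 bits.  Prefix-stable, so run
    ``i`` gets the same seed regardless of how many replicates follow it.
    """
    words = np.random.SeedSequence(base_seed).generate_state(n_runs, dtype=np.uint32)
    return [int(w) & 0x7FFFFFFF for w in words]


def run_ensemble(
    params: RateParameters,
    initial: CellStateVector,
    schedule: MycSchedule,
    t_end: float,
    n_runs: int,
    base_seed: int,
    *,
    bli_states: tuple[str, ...] = STATES,
    stop_above: float | None = None,
):
    """Run ``n_runs`` independent replicates and summarize them.

    Per-run seeds come from :func:`derive_run_seeds`, so replicate ``i`` is
    reproducible in isolation and independent of the others.  Returns an
    :class:`~oncoaddict.experiments.EnsembleResult` with per-run summary
    metrics and regression/relapse coefficients of variation.
    """
    if n_runs < 1:
        raise ValidationError(f"n_runs must be >= 1, got {n_runs}")
    seeds = derive_run_seeds(base_seed, n_runs)
    trajectories = [
        simulate(
            params,
            initial,
            schedule,
            t_end,
            s,
            bli_states=bli_states,
            stop_above=stop_above,
            run_id=str(i),
        )
        for i, s in enumerate(seeds)
    ]
    from .experiments import build_ensemble_result  # summaries live there

    return build_ensemble_result(trajectories)
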