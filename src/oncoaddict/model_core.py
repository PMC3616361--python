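"""State space, rate parameters, MYC schedule and per-step transition kernel.

The model tracks a tumor-cell population distributed over six states:

``M``
    Cells with the MYC oncogene transcriptionally active ("MYC on").
``N``
    Cells with MYC switched off but still under conditional (tetracycline)
    control ("MYC off").
``A``
    Cells irreversibly committed to apoptosis but not yet dead.  They keep
    producing bioluminescence signal until actual death, which lags the
    commitment by ``tau_apop`` days.
``D``
    Differentiated, quasi-normal cells; in some tumor types these are dormant
    and can reawaken to ``M`` upon MYC reactivation.
``S``
    Cells in oncogene-inactivation-induced senescence (OIIS): irreversible
    cell-cycle arrest, an absorbing state.
``E``
    Cells that escaped conditional MYC control (e.g. tTA mutation or
    activation of MYC-downstream pathways) and grow regardless of the
    doxycycline program.

All transitions are first-order with rate constants in day^-1.  The MYC
program (on/off) is an externally controlled, piecewise-constant independent
variable (doxycycline in the drinking water of the conditional mouse models);
it gates the M<->N switching edges, and the dormancy reawakening edge D->M,
so that each gated path is open in only one direction at a time.

Per Euler step of length ``dt`` the probability that a cell takes an
outgoing edge with rate constant K is ``p = K * dt`` (first order in dt; at
dt = 0.02 d and K <= 2 day^-1 this differs from 1 - exp(-K dt) by < 0.1% per
step).  Proliferation is a birth event — the mother stays in its state and a
daughter is added to the same state — not an exit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "STATES",
    "STATE_INDEX",
    "TUMOR_TYPES",
    "IMMUNE_STATUSES",
    "ConfigurationError",
    "ValidationError",
    "StepSizeError",
    "RateParameters",
    "CellStateVector",
    "MycSchedule",
    "ScenarioPreset",
    "build_parameters",
    "myc_program_at",
    "exit_probabilities",
    "birth_probability",
]

#: Canonical state ordering used by every array in the package.
STATES: tuple[str, ...] = ("M", "N", "A", "D", "S", "E")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

TUMOR_TYPES = ("lymphoma", "osteosarcoma", "hepatocellular")
IMMUNE_STATUSES = ("competent", "deficient")


class ConfigurationError(ValueError):
    """Unknown preset/tumor type/immune status or malformed configuration."""


class ValidationError(ValueError):
    """A parameter or state violates a model invariant."""


class StepSizeError(ValidationError):
    """Per-step exit probability of some state would exceed 1 at this dt."""


# Rate constants shared by every tumor type and immune background
# (estimated values, day^-1).
_BASE_RATES: dict[str, float] = {
    "k_M_prolif": 0.5,
    "k_M_apop": 0.05,
    "k_N_prolif": 0.1,
    "k_N_apop": 2.0,
    "k_diff": 0.02,
    "k_senesc": 0.001,
    "k_wake": 0.1,
    "k_E_prolif": 0.5,
    "k_E_apop": 0.01,
    "k_inactivation": 2.0,
    "k_activation": 2.0,
}

#: Differentiated-cell apoptosis rate, tumor-type dependent (day^-1).
K_D_APOP_BY_TUMOR = {"lymphoma": 0.05, "osteosarcoma": 0.002, "hepatocellular": 0.01}

#: MYC-off -> escaped mutation rate, immune-status dependent (day^-1).
K_RELAPSE_BY_IMMUNE = {"competent": 0.0, "deficient": 3e-8}

DEFAULT_DT = 0.02  # days per Euler step
DEFAULT_TAU_APOP = 4.5  # days; calibrated to the observed ~4-5 d apoptosis lag


@dataclass(frozen=True)
class RateParameters:
    """All rate constants plus the apoptosis delay and the Euler step.

    Rates are day^-1, durations in days.  The constructor validates
    non-negativity, rounds ``tau_apop`` to an exact multiple of ``dt`` (with
    a warning when the rounding is material), and checks that for every
    state, under either MYC program, the summed per-step exit probability
    ``sum(K_out) * dt`` does not exceed 1.
    """

    k_M_prolif: float = _BASE_RATES["k_M_prolif"]
    k_M_apop: float = _BASE_RATES["k_M_apop"]
    k_N_prolif: float = _BASE_RATES["k_N_prolif"]
    k_N_apop: float = _BASE_RATES["k_N_apop"]
    k_diff: float = _BASE_RATES["k_diff"]
    k_senesc: float = _BASE_RATES["k_senesc"]
    k_relapse: float = 0.0
    k_wake: float = _BASE_RATES["k_wake"]
    k_E_prolif: float = _BASE_RATES["k_E_prolif"]
    k_E_apop: float = _BASE_RATES["k_E_apop"]
    k_D_apop: float = K_D_APOP_BY_TUMOR["lymphoma"]
    k_inactivation: float = _BASE_RATES["k_inactivation"]
    k_activation: float = _BASE_RATES["k_activation"]
    tau_apop: float = DEFAULT_TAU_APOP
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValidationError(f"{f.name} must be a number, got {value!r}")
            if not math.isfinite(value):
                raise ValidationError(f"{f.name} must be finite, got {value!r}")
            object.__setattr__(self, f.name, float(value))
        if self.dt <= 0:
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        for f in fields(self):
            if f.name == "dt":
                continue
            if getattr(self, f.name) < 0:
                raise ValidationError(f"{f.name} must be >= 0, got {getattr(self, f.name)}")
        # snap the delay to the integration grid
        n_delay = round(self.tau_apop / self.dt)
        snapped = n_delay * self.dt
        if not math.isclose(snapped, self.tau_apop, rel_tol=0.0, abs_tol=1e-9):
            warnings.warn(
                f"tau_apop={self.tau_apop} is not a multiple of dt={self.dt}; "
                f"rounded to {snapped}",
                stacklevel=3,
            )
        object.__setattr__(self, "tau_apop", snapped)
        # per-step exit probabilities must be valid under both programs
        for program in ("on", "off"):
            for state in STATES:
                total = sum(_exit_rates(self, state, program).values()) * self.dt
                if total > 1.0 + 1e-12:
                    raise StepSizeError(
                        f"state {state} under MYC {program}: summed exit probability "
                        f"{total:.4g} exceeds 1; choose a smaller dt"
                    )

    @property
    def delay_steps(self) -> int:
        """Number of Euler steps spanning ``tau_apop``."""
        return round(self.tau_apop / self.dt)

    def with_overrides(self, **overrides: float) -> "RateParameters":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class CellStateVector:
    """Counts (stochastic: integers; mean-field: reals) of the six states at time ``t``."""

    M: float = 0
    N: float = 0
    A: float = 0
    D: float = 0
    S: float = 0
    E: float = 0
    t: float = 0.0

    def __post_init__(self) -> None:
        for s in STATES:
            if getattr(self, s) < 0:
                raise ValidationError(f"count {s} must be >= 0, got {getattr(self, s)}")

    def as_array(self, dtype=float) -> np.ndarray:
        return np.array([getattr(self, s) for s in STATES], dtype=dtype)

    @classmethod
    def from_array(cls, values, t: float = 0.0) -> "CellStateVector":
        return cls(**{s: v for s, v in zip(STATES, values)}, t=t)

    def total(self) -> float:
        """All cells in the system (live, i.e. pre-death; A included)."""
        return sum(getattr(self, s) for s in STATES)


@dataclass(frozen=True)
class MycSchedule:
    """Piecewise-constant MYC on/off program (the +/- dox independent variable).

    ``switch_events`` is an ordered sequence of ``(time_days, program)``
    pairs with strictly increasing times; each switch takes effect *at* its
    switch time (left-closed intervals).
    """

    initial_program: str = "on"
    switch_events: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        if self.initial_program not in ("on", "off"):
            raise ValidationError(f"initial_program must be 'on' or 'off', got {self.initial_program!r}")
        events = tuple((float(t), str(p)) for t, p in self.switch_events)
        for t, p in events:
            if p not in ("on", "off"):
                raise ValidationError(f"switch program must be 'on' or 'off', got {p!r}")
        times = [t for t, _ in events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("switch times must be strictly increasing")
        object.__setattr__(self, "switch_events", events)

    def program_at(self, t: float) -> str:
        """Program in force at time ``t`` (switch effective at the switch time)."""
        program = self.initial_program
        for t_switch, p in self.switch_events:
            if t >= t_switch:
                program = p
            else:
                break
        return program

    def on_grid(self, times: np.ndarray) -> np.ndarray:
        """Vectorized ``program_at``: boolean array, True where MYC is on."""
        programs = [self.initial_program] + [p for _, p in self.switch_events]
        switch_times = np.array([t for t, _ in self.switch_events])
        idx = np.searchsorted(switch_times, times, side="right")
        return np.array([programs[i] == "on" for i in idx])

    def first_switch_to(self, program: str) -> float | None:
        """Time of the first switch to ``program``, or None."""
        if self.initial_program == program:
            return 0.0
        for t, p in self.switch_events:
            if p == program:
                return t
        return None


@dataclass(frozen=True)
class ScenarioPreset:
    """A fully specified run: parameters, initial state, schedule, horizon."""

    name: str
    tumor_type: str
    immune_status: str
    params: RateParameters
    initial: CellStateVector
    schedule: MycSchedule
    t_end: float
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.tumor_type not in TUMOR_TYPES:
            raise ConfigurationError(f"unknown tumor_type {self.tumor_type!r}")
        if self.immune_status not in IMMUNE_STATUSES:
            raise ConfigurationError(f"unknown immune_status {self.immune_status!r}")
        if self.t_end <= 0:
            raise ValidationError(f"t_end must be > 0, got {self.t_end}")
        if self.n_replicates < 1:
            raise ValidationError(f"n_replicates must be >= 1, got {self.n_replicates}")


def build_parameters(
    tumor_type: str,
    immune_status: str,
    overrides: dict[str, float] | None = None,
) -> RateParameters:
    """Assemble the default rate table for a tumor type and immune background.

    The tumor type selects the differentiated-cell apoptosis rate
    (lymphoma 0.05, osteosarcoma 0.002, hepatocellular 0.01 day^-1); the
    immune status selects the MYC-off -> escaped mutation rate (0 in
    immunocompetent hosts, 3e-8 day^-1 in immunodeficient ones) and — as an
    interpretive choice, since OIIS requires intact host immunity (CD4+
    T cells) — zeroes the senescence entry rate in deficient hosts.
    ``overrides`` replaces individual fields after the presets are applied.
    """
    if tumor_type not in TUMOR_TYPES:
        raise ConfigurationError(
            f"unknown tumor_type {tumor_type!r}; expected one of {TUMOR_TYPES}"
        )
    if immune_status not in IMMUNE_STATUSES:
        raise ConfigurationError(
            f"unknown immune_status {immune_status!r}; expected one of {IMMUNE_STATUSES}"
        )
    values = dict(_BASE_RATES)
    values["k_D_apop"] = K_D_APOP_BY_TUMOR[tumor_type]
    values["k_relapse"] = K_RELAPSE_BY_IMMUNE[immune_status]
    if immune_status == "deficient":
        values["k_senesc"] = 0.0  # OIIS is immune-mediated
    values["tau_apop"] = DEFAULT_TAU_APOP
    values["dt"] = DEFAULT_DT
    if overrides:
        valid = {f.name for f in fields(RateParameters)}
        for key in overrides:
            if key not in valid:
                raise ConfigurationError(f"unknown parameter override {key!r}")
        values.update(overrides)
    return RateParameters(**values)


def myc_program_at(schedule: MycSchedule, t: float) -> str:
    """Program ('on'/'off') in force at time ``t`` under ``schedule``."""
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    return schedule.program_at(t)


def _exit_rates(params: RateParameters, state: str, program: str) -> dict[str, float]:
    """Outgoing rate constants (day^-1) per destination, under one MYC program.

    The engine-level delayed death of A is not an edge here; S is absorbing.
    """
    on = program == "on"
    if state == "M":
        edges = {"A": params.k_M_apop}
        if not on:
            edges["N"] = params.k_inactivation
    elif state == "N":
        edges = {
            "A": params.k_N_apop,
            "D": params.k_diff,
            "S": params.k_senesc,
            "E": params.k_relapse,
        }
        if on:
            edges["M"] = params.k_activation
    elif state == "A":
        edges = {}
    elif state == "D":
        edges = {"A": params.k_D_apop}
        if on:
            edges["M"] = params.k_wake
    elif state == "S":
        edges = {}
    elif state == "E":
        edges = {"A": params.k_E_apop}
    else:
        raise ValidationError(f"unknown state {state!r}")
    return {d: k for d, k in edges.items() if k > 0.0}


_BIRTH_RATE_FIELD = {"M": "k_M_prolif", "N": "k_N_prolif", "E": "k_E_prolif"}


def birth_rate(params: RateParameters, state: str) -> float:
    """Proliferation rate constant of ``state`` (0 for non-proliferating states)."""
    if state not in STATES:
        raise ValidationError(f"unknown state {state!r}")
    name = _BIRTH_RATE_FIELD.get(state)
    return getattr(params, name) if name else 0.0


def birth_probability(params: RateParameters, state: str) -> float:
    """Per-step probability that one cell of ``state`` produces a daughter."""
    return birth_rate(params, state) * params.dt


def exit_probabilities(
    params: RateParameters, state_label: str, myc_program: str
) -> dict[str, float]:
    """Per-step transition probabilities out of ``state_label``.

    Returns a mapping destination -> probability ``K * dt`` for every edge
    active under ``myc_program``.  Gating: M->N is open only with MYC off,
    N->M and D->M only with MYC on; S has no exits; A exits only through the
    engine's delayed-death queue, which is not part of this kernel.
    Proliferation is a birth event, reported by :func:`birth_probability`,
    not an exit.
    """
    if state_label not in STATES:
        raise ValidationError(f"unknown state {state_label!r}")
    if myc_program not in ("on", "off"):
        raise ValidationError(f"myc_program must be 'on' or 'off', got {myc_program!r}")
    probs = {d: k * params.dt for d, k in _exit_rates(params, state_label, myc_program).items()}
    total = sum(probs.values())
    if total > 1.0 + 1e-12:
        raise StepSizeError(
            f"exit probabilities of {state_label} sum to {total:.4g} > 1; "
            f"choose a smaller dt"
        )
    return probs
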