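"""Named scenario presets and the summary metrics for regression/relapse.

The four presets reproduce the canonical study conditions: a tumor grown
from 1e6 MYC-on cells for 10 days, then MYC inactivation —

``fig4``
    Immunocompetent lymphoma with the commitment-to-death delay removed
    (tau_apop = 0): the no-delay ablation, where tumor signal starts falling
    immediately upon inactivation.
``fig5``
    Immunocompetent lymphoma with the default 4.5 d delay: sustained
    regression, signal decline beginning ~4-5 d after inactivation.
``fig6``
    Immunodeficient lymphoma (escape mutation rate 3e-8 day^-1, no
    immune-mediated senescence), single stochastic run: regression followed
    by relapse with stochastic timing.
``fig7``
    Same as fig6 with 20 replicate runs: the relapse-variability ensemble.

Summary metrics are defined on the BLI-proxy signal: onset of decline
(first sustained drop below a fraction of the signal at inactivation),
regression half-time (fall to 50% of the signal at inactivation), nadir,
and relapse time (first re-crossing of a fraction of the pre-inactivation
peak after the nadir).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import (
    CellStateVector,
    ConfigurationError,
    MycSchedule,
    RateParameters,
    ScenarioPreset,
    ValidationError,
    build_parameters,
)
from .stochastic import Trajectory, derive_run_seeds, simulate
from .deterministic import simulate_deterministic

__all__ = [
    "RunSummary",
    "EnsembleResult",
    "VariabilityReport",
    "preset",
    "list_presets",
    "onset_of_decline",
    "regression_half_time",
    "relapse_time",
    "first_escape_time",
    "summarize_run",
    "build_ensemble_result",
    "variability_report",
    "relapse_rate_sensitivity",
]

DEFAULT_INITIAL_M = 1_000_000
DEFAULT_GROWTH_DAYS = 10.0


@dataclass(frozen=True)
class RunSummary:
    """Per-run scalar metrics of one trajectory (None where undefined)."""

    onset_of_decline: float | None
    nadir_signal: float
    nadir_time: float
    relapse_time: float | None
    regression_half_time: float | None


@dataclass(frozen=True)
class VariabilityReport:
    """CVs of regression half-time and relapse time over an ensemble.

    A CV is None when fewer than two runs define the underlying quantity;
    ``n_regression``/``n_relapse`` count the runs that do.
    """

    cv_regression: float | None
    cv_relapse: float | None
    n_regression: int
    n_relapse: int

    def __iter__(self):
        return iter((self.cv_regression, self.cv_relapse))


@dataclass(frozen=True)
class EnsembleResult:
    """Replicate trajectories with per-run summaries and variability CVs."""

    trajectories: list[Trajectory]
    summaries: list[RunSummary]
    cv_regression: float | None
    cv_relapse: float | None

    def __post_init__(self) -> None:
        if len(self.trajectories) != len(self.summaries):
            raise ValidationError("trajectories and summaries lengths differ")

    def summaries_frame(self) -> pd.DataFrame:
        rows = []
        for traj, s in zip(self.trajectories, self.summaries):
            rows.append(
                {
                    "run_id": traj.run_id,
                    "seed": traj.seed,
                    "onset_of_decline": s.onset_of_decline,
                    "nadir_signal": s.nadir_signal,
                    "nadir_time": s.nadir_time,
                    "relapse_time": s.relapse_time,
                    "regression_half_time": s.regression_half_time,
                }
            )
        return pd.DataFrame(rows)


def _scenario(
    name: str,
    tumor_type: str,
    immune_status: str,
    *,
    overrides: dict | None = None,
    t_end: float,
    n_replicates: int,
) -> ScenarioPreset:
    params = build_parameters(tumor_type, immune_status, overrides or {})
    return ScenarioPreset(
        name=name,
        tumor_type=tumor_type,
        immune_status=immune_status,
        params=params,
        initial=CellStateVector(M=DEFAULT_INITIAL_M),
        schedule=MycSchedule("on", ((DEFAULT_GROWTH_DAYS, "off"),)),
        t_end=t_end,
        n_replicates=n_replicates,
    )


_PRESET_BUILDERS = {
    "fig4": lambda: _scenario(
        "fig4", "lymphoma", "competent", overrides={"tau_apop": 0.0}, t_end=30.0, n_replicates=1
    ),
    "fig5": lambda: _scenario("fig5", "lymphoma", "competent", t_end=30.0, n_replicates=1),
    "fig6": lambda: _scenario("fig6", "lymphoma", "deficient", t_end=70.0, n_replicates=1),
    "fig7": lambda: _scenario("fig7", "lymphoma", "deficient", t_end=70.0, n_replicates=20),
}

_PRESET_DESCRIPTIONS = {
    "fig4": "lymphoma, immunocompetent, no apoptosis delay (ablation)",
    "fig5": "lymphoma, immunocompetent, 4.5 d apoptosis delay (sustained regression)",
    "fig6": "lymphoma, immunodeficient, single run (relapse)",
    "fig7": "lymphoma, immunodeficient, 20-run relapse-variability ensemble",
}


def preset(name: str) -> ScenarioPreset:
    """Resolve a named scenario preset (fig4/fig5/fig6/fig7)."""
    try:
        return _PRESET_BUILDERS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(_PRESET_BUILDERS)}"
        ) from None


def list_presets() -> dict[str, str]:
    return dict(_PRESET_DESCRIPTIONS)


def _t_switch_from(traj: Trajectory) -> float | None:
    return traj.schedule.first_switch_to("off")


def _index_at(traj: Trajectory, t: float) -> int:
    idx = int(np.searchsorted(traj.times, t - 1e-9))
    if idx >= len(traj.times):
        raise ValidationError(f"t={t} is beyond the trajectory grid")
    return idx


def onset_of_decline(
    traj: Trajectory,
    t_switch: float,
    *,
    fraction: float = 0.99,
    persistence: float = 1.0,
) -> float | None:
    """Days after ``t_switch`` until the signal first drops *and stays* low.

    The onset is the first grid time after ``t_switch`` where the BLI signal
    falls below ``fraction`` of its value at ``t_switch`` and remains below
    for ``persistence`` days (a guard against stochastic dips); returns the
    lag in days, or None if the signal never sustains a decline.
    """
    i0 = _index_at(traj, t_switch)
    baseline = float(traj.bli_signal[i0])
    if baseline <= 0:
        return None
    below = traj.bli_signal < fraction * baseline
    window = max(int(round(persistence / traj.params.dt)), 1)
    n = len(below)
    for i in range(i0 + 1, n):
        if below[i] and bool(np.all(below[i : min(i + window, n)])):
            return float(traj.times[i] - t_switch)
    return None


def regression_half_time(traj: Trajectory, t_switch: float) -> float | None:
    """Days after ``t_switch`` for the signal to halve from its value there."""
    i0 = _index_at(traj, t_switch)
    half = 0.5 * float(traj.bli_signal[i0])
    after = np.nonzero(traj.bli_signal[i0 + 1 :] <= half)[0]
    if after.size == 0:
        return None
    return float(traj.times[i0 + 1 + after[0]] - t_switch)


def relapse_time(traj: Trajectory, threshold_fraction: float = 0.5) -> float | None:
    """First re-crossing of ``threshold_fraction`` x pre-inactivation peak.

    The peak is the maximum signal up to MYC inactivation; the nadir is the
    (first) minimum after it.  Returns the first time after the nadir at
    which the signal climbs back to the threshold, None if the tumor never
    regressed below the threshold or never re-crossed it (sustained
    regression, or no inactivation in the schedule).
    """
    if not 0 < threshold_fraction <= 1:
        raise ValidationError(
            f"threshold_fraction must be in (0, 1], got {threshold_fraction}"
        )
    t_switch = _t_switch_from(traj)
    if t_switch is None or t_switch >= traj.times[-1]:
        return None
    i0 = _index_at(traj, t_switch)
    peak = float(traj.bli_signal[: i0 + 1].max())
    threshold = threshold_fraction * peak
    post = traj.bli_signal[i0:]
    nadir_rel = int(np.argmin(post))
    if float(post[nadir_rel]) >= threshold:
        return None
    recross = np.nonzero(post[nadir_rel:] >= threshold)[0]
    if recross.size == 0:
        return None
    return float(traj.times[i0 + nadir_rel + recross[0]])


def first_escape_time(traj: Trajectory) -> float | None:
    """First grid time with a nonzero escaped-cell count, or None."""
    idx = np.nonzero(traj.counts[:, -1] > 0)[0]
    return float(traj.times[idx[0]]) if idx.size else None


def summarize_run(traj: Trajectory, t_switch: float | None = None) -> RunSummary:
    """Compute all per-run metrics; ``t_switch`` defaults to the schedule's
    first switch to 'off' (metrics needing it are None when there is none)."""
    if t_switch is None:
        t_switch = _t_switch_from(traj)
    if t_switch is not None and t_switch < traj.times[-1]:
        i0 = _index_at(traj, t_switch)
        onset = onset_of_decline(traj, t_switch)
        half = regression_half_time(traj, t_switch)
    else:
        i0 = 0
        onset = None
        half = None
    post = traj.bli_signal[i0:]
    nadir_rel = int(np.argmin(post))
    return RunSummary(
        onset_of_decline=onset,
        nadir_signal=float(post[nadir_rel]),
        nadir_time=float(traj.times[i0 + nadir_rel]),
        relapse_time=relapse_time(traj),
        regression_half_time=half,
    )


def _cv(values: list[float]) -> float | None:
    if len(values) < 2:
        return None
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return float(arr.std(ddof=1) / mean)


def build_ensemble_result(trajectories: list[Trajectory]) -> EnsembleResult:
    summaries = [summarize_run(t) for t in trajectories]
    report = _variability(summaries)
    return EnsembleResult(
        trajectories=list(trajectories),
        summaries=summaries,
        cv_regression=report.cv_regression,
        cv_relapse=report.cv_relapse,
    )


def _variability(summaries: list[RunSummary]) -> VariabilityReport:
    reg = [s.regression_half_time for s in summaries if s.regression_half_time is not None]
    rel = [s.relapse_time for s in summaries if s.relapse_time is not None]
    return VariabilityReport(_cv(reg), _cv(rel), len(reg), len(rel))


def variability_report(ensemble: EnsembleResult) -> VariabilityReport:
    """CVs of regression half-time and relapse time across the ensemble."""
    return _variability(ensemble.summaries)


def relapse_rate_sensitivity(
    scenario: ScenarioPreset,
    k_relapse_grid,
    k_E_prolif_grid,
    n_runs: int,
    *,
    base_seed: int = 0,
    threshold_fraction: float = 0.5,
) -> pd.DataFrame:
    """Median relapse time over stochastic replicates per (k_relapse, k_E_prolif).

    For each grid cell the scenario is rerun with the two rates overridden;
    the table enables the dominance comparison between the escape mutation
    rate (k_relapse) and the escaped-cell growth rate (k_E_prolif).  Runs are
    truncated once the signal reaches twice the deterministic
    pre-inactivation peak — far above the relapse threshold — because
    escaped-cell growth is unbounded.  Rows: k_relapse, k_E_prolif,
    median_relapse_time (NaN if no run relapsed), n_relapsed, n_runs.
    """
    k_relapse_grid = list(k_relapse_grid)
    k_E_prolif_grid = list(k_E_prolif_grid)
    if not k_relapse_grid or not k_E_prolif_grid:
        raise ValidationError("parameter grids must be non-empty")
    if n_runs < 1:
        raise ValidationError(f"n_runs must be >= 1, got {n_runs}")

    det = simulate_deterministic(
        scenario.params, scenario.initial, scenario.schedule, scenario.t_end
    )
    t_switch = scenario.schedule.first_switch_to("off")
    i0 = _index_at(det, t_switch) if t_switch is not None else len(det.times) - 1
    ceiling = 2.0 * float(det.bli_signal[: i0 + 1].max())

    rows = []
    for ci, k_rel in enumerate(k_relapse_grid):
        for cj, k_ep in enumerate(k_E_prolif_grid):
            params = scenario.params.with_overrides(k_relapse=k_rel, k_E_prolif=k_ep)
            cell_seed = int(
                np.random.SeedSequence((base_seed, ci, cj)).generate_state(1, np.uint32)[0]
            ) & 0x7FFFFFFF
            seeds = derive_run_seeds(cell_seed, n_runs)
            times = []
            for s in seeds:
                traj = simulate(
                    params,
                    scenario.initial,
                    scenario.schedule,
                    scenario.t_end,
                    s,
                    stop_above=ceiling,
                )
                rt = relapse_time(traj, threshold_fraction)
                if rt is not None:
                    times.append(rt)
            rows.append(
                {
                    "k_relapse": k_rel,
                    "k_E_prolif": k_ep,
                    "median_relapse_time": float(np.median(times)) if times else float("nan"),
                    "n_relapsed": len(times),
                    "n_runs": n_runs,
                }
            )
    return pd.DataFrame(rows)
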