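"""Stochastic engine: draws, delay queue, conservation, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoaddict import (
    STATE_INDEX,
    CellStateVector,
    DelayQueue,
    MycSchedule,
    ValidationError,
    derive_run_seeds,
    run_ensemble,
    simulate,
    step_stochastic,
)
from conftest import zeroed

ALWAYS_ON = MycSchedule("on")
ALWAYS_OFF = MycSchedule("off")


class TestStepStochastic:
    def test_all_zero_state_is_fixed_point(self, lymphoma_competent):
        rng = np.random.default_rng(0)
        state, queue = CellStateVector(), DelayQueue(lymphoma_competent.dt)
        new, q = step_stochastic(state, queue, lymphoma_competent, "off", rng)
        assert new.as_array().sum() == 0
        assert q.total == 0

    def test_all_rates_zero_state_unchanged(self):
        params = zeroed()
        rng = np.random.default_rng(1)
        state = CellStateVector(M=10, N=7, D=3, S=2, E=1)
        new, _ = step_stochastic(state, DelayQueue(params.dt), params, "off", rng)
        assert np.array_equal(new.as_array(), state.as_array())
        assert new.t == pytest.approx(params.dt)

    def test_non_integer_counts_rejected(self, lymphoma_competent):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            step_stochastic(
                CellStateVector(M=1.5), DelayQueue(lymphoma_competent.dt),
                lymphoma_competent, "on", rng,
            )

    def test_queue_must_match_a_count(self, lymphoma_competent):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError, match="queue"):
            step_stochastic(
                CellStateVector(A=5), DelayQueue(lymphoma_competent.dt),
                lymphoma_competent, "on", rng,
            )

    def test_queue_conservation_over_many_steps(self, lymphoma_competent):
        """A always equals the queued cohort total, step by step."""
        rng = np.random.default_rng(7)
        state = CellStateVector(M=20_000)
        queue = DelayQueue(lymphoma_competent.dt)
        for _ in range(300):
            program = "on" if state.t < 2.0 else "off"
            state, queue = step_stochastic(state, queue, lymphoma_competent, program, rng)
            assert state.A == queue.total
            assert all(c >= 0 for c in state.as_array())


class TestSimulate:
    def test_seeded_bit_exact_reproducibility(self, lymphoma_competent, million_m_cells):
        a = simulate(lymphoma_competent, million_m_cells, ALWAYS_ON, 5.0, seed=123)
        b = simulate(lymphoma_competent, million_m_cells, ALWAYS_ON, 5.0, seed=123)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.bli_signal, b.bli_signal)

    def test_no_escape_without_relapse_rate(self, lymphoma_competent, million_m_cells,
                                            growth_then_off):
        for seed in (0, 1, 2):
            traj = simulate(lymphoma_competent, million_m_cells, growth_then_off, 20.0, seed)
            assert np.all(traj.counts[:, STATE_INDEX["E"]] == 0)

    def test_counts_are_nonnegative_integers_and_s_monotone(
        self, lymphoma_deficient, million_m_cells, growth_then_off
    ):
        params = lymphoma_deficient.with_overrides(k_senesc=0.001)  # exercise S too
        traj = simulate(params, million_m_cells, growth_then_off, 25.0, seed=11)
        assert traj.counts.dtype == np.int64
        assert np.all(traj.counts >= 0)
        s = traj.counts[:, STATE_INDEX["S"]]
        assert np.all(np.diff(s) >= 0)

    def test_bli_signal_is_configured_live_state_sum(self, lymphoma_competent,
                                                     million_m_cells, growth_then_off):
        traj = simulate(lymphoma_competent, million_m_cells, growth_then_off, 15.0, seed=3)
        assert np.array_equal(traj.bli_signal, traj.counts.sum(axis=1))
        no_d = simulate(
            lymphoma_competent, million_m_cells, growth_then_off, 15.0, seed=3,
            bli_states=("M", "N", "A", "S", "E"),
        )
        d_col = no_d.counts[:, STATE_INDEX["D"]]
        assert np.array_equal(no_d.bli_signal, no_d.counts.sum(axis=1) - d_col)

    def test_pure_growth_matches_branching_process_expectation(self):
        """Mean of replicate birth-death runs agrees with the closed-form
        per-step expectation (1 + (b - d) dt)^n within 3 standard errors."""
        params = zeroed(k_M_prolif=0.5, k_M_apop=0.05)
        n0, t_end, n_runs = 500, 10.0, 200
        initial = CellStateVector(M=n0)
        finals = np.array([
            simulate(params, initial, ALWAYS_ON, t_end, seed).counts[-1, 0]
            for seed in derive_run_seeds(2024, n_runs)
        ], dtype=float)
        expected = n0 * (1 + (0.5 - 0.05) * params.dt) ** 500
        se = finals.std(ddof=1) / np.sqrt(n_runs)
        assert abs(finals.mean() - expected) < 3 * se
        # the continuous-time analytic value differs only by first-order
        # Euler discretization (~2% at dt = 0.02)
        assert finals.mean() == pytest.approx(n0 * np.exp(4.5), rel=0.05)

    def test_delay_queue_holds_live_signal_until_tau(self):
        """With apoptosis commitment as the only flow, N + A is conserved
        exactly until the first committed cohort matures at t = tau_apop."""
        params = zeroed(k_N_apop=2.0, tau_apop=4.5)
        traj = simulate(params, CellStateVector(N=1_000_000), ALWAYS_OFF, 8.0, seed=5)
        live = traj.counts[:, STATE_INDEX["N"]] + traj.counts[:, STATE_INDEX["A"]]
        i_tau = round(4.5 / params.dt)
        assert np.all(live[:i_tau] == 1_000_000)
        assert live[i_tau] < 1_000_000
        assert traj.counts[1, STATE_INDEX["A"]] > 0  # commitment starts immediately

    def test_zero_delay_kills_in_step(self):
        params = zeroed(k_N_apop=2.0, tau_apop=0.0)
        traj = simulate(params, CellStateVector(N=100_000), ALWAYS_OFF, 2.0, seed=5)
        assert np.all(traj.counts[:, STATE_INDEX["A"]] == 0)
        assert traj.counts[-1, STATE_INDEX["N"]] < 100_000

    def test_t_end_rounded_up_with_warning(self, lymphoma_competent, million_m_cells):
        with pytest.warns(UserWarning, match="t_end"):
            traj = simulate(lymphoma_competent, million_m_cells, ALWAYS_ON, 0.05, seed=0)
        assert traj.times[-1] == pytest.approx(0.06)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15)
    def test_invariants_hold_for_any_seed(self, seed):
        params = zeroed(k_M_prolif=0.3, k_M_apop=0.1, k_inactivation=1.0,
                        k_N_apop=0.5, k_senesc=0.2, tau_apop=0.1)
        traj = simulate(params, CellStateVector(M=5_000), ALWAYS_OFF, 3.0, seed)
        assert np.all(traj.counts >= 0)
        assert np.all(np.diff(traj.counts[:, STATE_INDEX["S"]]) >= 0)


class TestEnsemble:
    def test_same_base_seed_reproduces_ensemble(self, lymphoma_deficient,
                                                million_m_cells, growth_then_off):
        a = run_ensemble(lymphoma_deficient, million_m_cells, growth_then_off, 15.0, 4, 99)
        b = run_ensemble(lymphoma_deficient, million_m_cells, growth_then_off, 15.0, 4, 99)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.counts, tb.counts)

    def test_single_run_matches_simulate_with_derived_seed(
        self, lymphoma_competent, million_m_cells, growth_then_off
    ):
        ens = run_ensemble(lymphoma_competent, million_m_cells, growth_then_off, 12.0, 1, 7)
        solo = simulate(
            lymphoma_competent, million_m_cells, growth_then_off, 12.0,
            derive_run_seeds(7, 1)[0],
        )
        assert np.array_equal(ens.trajectories[0].counts, solo.counts)

    def test_run_seeds_are_prefix_stable(self):
        assert derive_run_seeds(42, 3) == derive_run_seeds(42, 8)[:3]
        assert all(0 <= s < 2**31 for s in derive_run_seeds(42, 8))

    def test_relapse_times_vary_across_replicates(self, million_m_cells):
        """Immunodeficient replicates relapse at different times (escape is
        a rare stochastic event amplified by exponential regrowth)."""
        from oncoaddict import preset

        p7 = preset("fig7")
        ens = run_ensemble(p7.params, million_m_cells, p7.schedule, p7.t_end, 8, 21)
        times = [s.relapse_time for s in ens.summaries if s.relapse_time is not None]
        assert len(times) >= 2
        assert len(set(times)) > 1
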