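"""Trajectory simulator: signal law fidelity, accounting invariants,
policy evaluation."""

import math

import numpy as np
import pytest

from fontan_listing import (
    ModelParams,
    compute_thresholds,
    evaluate_policy,
    generate_checklist_fixture,
    immediate_list_policy,
    never_list_policy,
    posterior_good,
    simulate_trajectory,
    threshold_policy,
)
from fontan_listing.belief import trans_down, trans_up
from fontan_listing.simulate import Terminal, signal_stream


class TestSignalLaw:
    def test_latent_bad_with_perfect_signals_is_monotone_down(self, example_params):
        p = ModelParams(mu=2, theta=1 - 1e-12, r=0.1, delta=0.5, lt=10, lnt=2)
        for seed in range(30):
            ks, moves = signal_stream(p, 50, np.random.default_rng(seed))
            rng = np.random.default_rng(seed)
            latent_good = rng.random() < 0.5
            if latent_good:
                assert np.all(moves == 1)
            else:
                assert np.all(moves == -1)

    def test_no_arrivals_freezes_the_decision(self):
        # mu ~ 0: no signals before any resolution; k stays at its start
        p = ModelParams(mu=1e-9, theta=0.8, r=0.1, delta=0.5, lt=10, lnt=2)
        th = compute_thresholds(ModelParams(mu=2, theta=0.8, r=0.1, delta=0.5, lt=10, lnt=2))
        traj = simulate_trajectory(p, threshold_policy(th), horizon=10.0, seed=3, k0=0)
        assert traj.k_path == [0]
        assert traj.event_times == []

    def test_transition_frequencies_match_model_coefficients(self, example_params):
        """Pooled over the latent outcome, the up/down frequencies at each
        count match the model's transition coefficients within 3 SE."""
        n_streams, n_events = 250, 40  # 10,000 events
        ups: dict[int, int] = {}
        tot: dict[int, int] = {}
        ss = np.random.SeedSequence(42).spawn(n_streams)
        for s in ss:
            ks, moves = signal_stream(example_params, n_events, np.random.default_rng(s))
            for k, m in zip(ks, moves):
                tot[k] = tot.get(k, 0) + 1
                if m == 1:
                    ups[k] = ups.get(k, 0) + 1
        checked = 0
        for k, n in tot.items():
            if n < 200:
                continue
            p = posterior_good(k, example_params.theta)
            q_up = trans_up(p, example_params.theta)
            q_dn = trans_down(p, example_params.theta)
            f_up = ups.get(k, 0) / n
            se = math.sqrt(q_up * q_dn / n)
            assert abs(f_up - q_up) <= 3 * se, (k, f_up, q_up, n)
            checked += 1
        assert checked >= 3

    def test_belief_path_consistent_with_counts(self, example_params, example_thresholds):
        traj = simulate_trajectory(
            example_params, threshold_policy(example_thresholds), horizon=10.0, seed=11
        )
        for k, b in zip(traj.k_path, traj.belief_path):
            assert b == pytest.approx(posterior_good(k, example_params.theta), abs=1e-12)
        assert all(abs(a - b) == 1 for a, b in zip(traj.k_path, traj.k_path[1:]))
        assert all(a < b for a, b in zip(traj.event_times, traj.event_times[1:]))


class TestAccounting:
    def test_discounted_life_years_bounds(self, example_params, example_thresholds):
        pol = threshold_policy(example_thresholds)
        ev = evaluate_policy(example_params, pol, n_reps=300, horizon=10.0, seed=5)
        assert np.all(ev.values >= 0.0)
        assert np.all(ev.values <= example_params.lt)

    def test_terminal_states_are_coherent(self, example_params, example_thresholds):
        pol = threshold_policy(example_thresholds)
        for seed in range(40):
            traj = simulate_trajectory(example_params, pol, horizon=10.0, seed=seed)
            if traj.terminal is Terminal.TRANSPLANTED:
                assert traj.listed_at is not None and traj.transplanted_at >= traj.listed_at
            if traj.terminal is Terminal.NEVER_LISTED:
                assert traj.listed_at is None
            if traj.terminal is Terminal.DIED_WAITING:
                assert traj.discounted_life_years == 0.0

    def test_never_list_value_is_deterministic_annuity(self, example_params):
        ev = evaluate_policy(example_params, never_list_policy, n_reps=50, horizon=10.0, seed=9)
        annuity = (1 - math.exp(-example_params.r * example_params.lnt)) / example_params.r
        assert ev.mean == pytest.approx(annuity, abs=1e-12)
        assert ev.se == pytest.approx(0.0, abs=1e-12)

    def test_down_only_listed_mode_never_moves_up_after_listing(self, example_params,
                                                                example_thresholds):
        pol = threshold_policy(example_thresholds)
        for seed in range(30):
            traj = simulate_trajectory(
                example_params, pol, horizon=10.0, seed=seed, listed_mode="down_only"
            )
            if traj.listed_at is None:
                continue
            listed_idx = next(
                i for i, lab in enumerate(traj.decision_path) if lab.value == "List"
            )
            tail = traj.k_path[listed_idx:]
            assert all(a > b for a, b in zip(tail, tail[1:]))


class TestPolicyEvaluation:
    def test_determinism_bit_for_bit(self, example_params, example_thresholds):
        pol = threshold_policy(example_thresholds)
        a = evaluate_policy(example_params, pol, n_reps=200, horizon=10.0, seed=123)
        b = evaluate_policy(example_params, pol, n_reps=200, horizon=10.0, seed=123)
        assert a.mean == b.mean and a.se == b.se
        assert a.terminal_counts == b.terminal_counts
        assert np.array_equal(a.values, b.values)

    def test_threshold_policy_dominates_baselines(self, example_params, example_thresholds):
        """The three-region rule beats never-listing and immediate listing
        (within Monte Carlo noise) at the worked-example parameters."""
        n = 2000
        pol = threshold_policy(example_thresholds)
        ev_thr = evaluate_policy(example_params, pol, n_reps=n, horizon=10.0, seed=77)
        ev_nev = evaluate_policy(example_params, never_list_policy, n_reps=n, horizon=10.0, seed=77)
        ev_imm = evaluate_policy(example_params, immediate_list_policy, n_reps=n, horizon=10.0, seed=77)
        assert ev_thr.mean >= ev_nev.mean - 2 * max(ev_thr.se, ev_nev.se)
        assert ev_thr.mean >= ev_imm.mean - 2 * max(ev_thr.se, ev_imm.se)

    def test_invalid_arguments(self, example_params, example_thresholds):
        pol = threshold_policy(example_thresholds)
        with pytest.raises(ValueError):
            evaluate_policy(example_params, pol, n_reps=1, horizon=10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_trajectory(example_params, pol, horizon=-1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_trajectory(example_params, pol, horizon=1.0, seed=0, listed_mode="x")


def test_trajectory_flat_export(example_params):
    from fontan_listing import trajectory_to_frame

    p = example_params
    th = compute_thresholds(p)
    traj = simulate_trajectory(p, threshold_policy(th), horizon=10.0, seed=21)
    df = trajectory_to_frame(traj)
    assert list(df.columns) == [
        "time", "k", "belief", "decision", "latent_outcome",
        "terminal", "discounted_life_years",
    ]
    assert len(df) == len(traj.k_path)
    assert df["time"].is_monotonic_increasing


class TestChecklistFixture:
    @pytest.mark.parametrize("ngood, nbad, k", [(5, 5, 0), (0, 0, 0), (7, 3, 4)])
    def test_composition(self, ngood, nbad, k):
        a = generate_checklist_fixture(ngood, nbad, seed=1)
        assert (a.n, a.k) == (ngood + nbad, k)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_checklist_fixture(-1, 2)
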