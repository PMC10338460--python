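import numpy as np
import pytest
from scipy import stats

from chromarl.collocation import ConfigurationError
from chromarl.env import (EPISODE_STEPS, N_FEATURES, OBS_WINDOW,
                          ChromatographyEnv, RandomizationSpec, RewardConfig,
                          TankMasses, apply_action, make_observation,
                          penalty_remaining, randomize_column, reward_clean,
                          reward_concentration, reward_mass, reward_purity,
                          total_reward)
from chromarl.flowsheet import MAX_FLOW, PRODUCT, WASTE
from chromarl.params import ColumnParameters


# ---------------------------------------------------------------------------
# column randomization
# ---------------------------------------------------------------------------

class _UnitDraw:
    """Stand-in generator whose uniform() always returns its fixed value."""

    def __init__(self, value):
        self.value = value

    def uniform(self, lo, hi):
        return self.value


class TestRandomization:
    def test_direct_evaluation_of_perturbation(self, nominal_params):
        # x = 0.4, S = 0.2, X = 1  ->  0.48
        out = randomize_column(nominal_params, RandomizationSpec(S=0.2),
                               _UnitDraw(1.0))
        assert out.eps_c == pytest.approx(0.48)
        assert np.allclose(out.D_ax, nominal_params.D_ax * 1.2)

    def test_zero_scale_limit_leaves_parameters_unchanged(self, nominal_params):
        out = randomize_column(nominal_params, RandomizationSpec(S=1e-12),
                               _UnitDraw(1.0))
        assert out.eps_c == pytest.approx(nominal_params.eps_c, rel=1e-9)

    def test_unperturbed_parameters_untouched(self, nominal_params):
        out = randomize_column(nominal_params, RandomizationSpec(S=0.2),
                               _UnitDraw(1.0))
        assert out.L == nominal_params.L
        assert np.all(out.k_a == nominal_params.k_a)
        assert out.h == nominal_params.h

    @pytest.mark.parametrize("S", [0.0, -0.1, 1.5])
    def test_invalid_scaling_factor_rejected(self, S):
        with pytest.raises(ConfigurationError):
            RandomizationSpec(S=S)

    def test_outputs_bounded_and_uniform(self, nominal_params):
        """Perturbations stay within [x(1-S), x(1+S)] and the relative error
        is uniform (Kolmogorov-Smirnov at n = 10,000)."""
        S = 0.2
        spec = RandomizationSpec(S=S)
        rng = np.random.default_rng(42)
        base = nominal_params.eps_p
        draws = np.array([randomize_column(nominal_params, spec, rng).eps_p
                          for _ in range(10_000)])
        assert draws.min() >= base * (1 - S)
        assert draws.max() <= base * (1 + S)
        rel = (draws / base - 1.0) / S            # should be U(-1, 1)
        ks = stats.kstest(rel, "uniform", args=(-1.0, 2.0))
        assert ks.pvalue > 1e-3

    def test_training_and_holdout_scales(self):
        assert RandomizationSpec().S == 0.2            # training condition
        assert RandomizationSpec(S=0.05).S == 0.05     # hold-out condition


# ---------------------------------------------------------------------------
# actions
# ---------------------------------------------------------------------------

class TestApplyAction:
    def test_lower_bound_maps_to_zero_flows_waste(self):
        a = apply_action(np.array([-1.0, -1.0, -1.0, -1.0]))
        assert a.F_feed == a.F_elute == a.F_wash == 0.0
        assert a.valve == WASTE

    def test_affine_map_endpoints_and_midpoint(self):
        a = apply_action(np.array([1.0, 0.0, -1.0, 1.0]))
        assert a.F_feed == pytest.approx(2e-6)
        assert a.F_elute == pytest.approx(1e-6)
        assert a.F_wash == 0.0
        assert a.valve == PRODUCT

    def test_out_of_box_entries_clipped(self):
        a = apply_action(np.array([5.0, -3.0, 0.5, -0.1]))
        assert a.F_feed == pytest.approx(MAX_FLOW)
        assert a.F_elute == 0.0
        assert a.valve == WASTE

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            apply_action(np.array([0.0, np.nan, 0.0, 0.0]))


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

class TestObservation:
    def test_first_step_padding_repeats_earliest_row(self):
        row = np.arange(1.0, N_FEATURES + 1)
        obs = make_observation([row], np.full(N_FEATURES, 20.0))
        assert obs.shape == (OBS_WINDOW, N_FEATURES)
        assert np.all(obs == obs[0])

    def test_feature_at_calibration_maximum_normalizes_to_one(self):
        cal = np.linspace(1.0, 2.0, N_FEATURES)
        obs = make_observation([cal.copy()], cal)
        assert np.allclose(obs, 1.0)

    def test_sliding_window_returns_last_ten_rows(self):
        history = [np.full(N_FEATURES, float(k)) for k in range(1, 13)]
        obs = make_observation(history, np.full(N_FEATURES, 100.0))
        assert np.allclose(obs[:, 0] * 100.0, np.arange(3, 13))

    def test_values_clipped_to_unit_interval(self):
        obs = make_observation([np.full(N_FEATURES, 50.0)],
                               np.full(N_FEATURES, 10.0))
        assert obs.max() == 1.0

    def test_missing_calibration_rejected(self):
        with pytest.raises(ConfigurationError):
            make_observation([np.ones(N_FEATURES)], np.zeros(N_FEATURES))


# ---------------------------------------------------------------------------
# reward terms
# ---------------------------------------------------------------------------

CFG = RewardConfig()


class TestRewardTerms:
    def test_empty_tanks_give_zero_mass_reward(self):
        assert reward_mass(TankMasses()) == 0.0

    def test_mass_reward_hand_value(self):
        t = TankMasses(mab_prod=1, mab_waste=0, sm_prod=0, sm_waste=2)
        assert reward_mass(t) == pytest.approx(5 * 1 + 2)

    def test_mass_reward_sign_symmetry(self):
        good = TankMasses(mab_prod=1, sm_waste=2)
        bad = TankMasses(mab_waste=1, sm_prod=2)
        assert reward_mass(good) == -reward_mass(bad)

    def test_concentration_floor_and_fraction(self):
        assert reward_concentration(TankMasses()) == pytest.approx(0.1)
        assert reward_concentration(TankMasses(mab_prod=3, sm_prod=1)) == 0.75
        assert reward_concentration(TankMasses(mab_prod=0.5)) == 1.0

    def test_clean_reward_clamp_and_subtraction(self):
        assert reward_clean(TankMasses(mab_prod=1, sm_prod=2)) == 0.0
        assert reward_clean(TankMasses(mab_prod=2, sm_prod=0.5)) == 1.5
        assert reward_clean(TankMasses()) == 0.0

    def test_column_penalty_gating(self):
        assert penalty_remaining(1.0, done=False, cfg=CFG) == 0.0
        assert penalty_remaining(CFG.mab_max / 2, done=True, cfg=CFG) == 0.0
        assert penalty_remaining(2 * CFG.mab_max, done=True, cfg=CFG) \
            == pytest.approx(2 * CFG.mab_max)

    def test_purity_bonus_knee_and_linearity(self):
        assert reward_purity(0.3) == 0.0
        assert reward_purity(1.0) == pytest.approx(1.0)
        assert reward_purity(0.65) == pytest.approx(0.5)

    def test_total_reward_term_by_term(self):
        t = TankMasses(mab_prod=1.0)
        b = total_reward(t, mab_col=0.0, done=False, cfg=CFG)
        assert b.R == pytest.approx(1e6 * (5 * 1 * 1 + 1 + 100 * 1))
        empty = total_reward(TankMasses(), 0.0, done=False, cfg=CFG)
        assert empty.R == 0.0

    def test_identical_states_give_zero_step_reward(self):
        t = TankMasses(mab_prod=0.4, sm_waste=1.0)
        b1 = total_reward(t, 0.0, done=False, cfg=CFG)
        b2 = total_reward(t, 0.0, done=False, prev_R=b1.R, cfg=CFG)
        assert b2.delta_R == 0.0

    def test_all_terms_match_direct_formulas_on_random_states(self):
        """Every reward term reproduces its defining arithmetic over many
        randomized tank/column states."""
        rng = np.random.default_rng(5)
        for _ in range(60):
            t = TankMasses(*rng.uniform(0, 10, size=4))
            mab_col = float(rng.uniform(0, 3))
            done = bool(rng.random() < 0.5)
            b = total_reward(t, mab_col, done, prev_R=float(rng.normal()),
                             cfg=CFG)
            r_mass = 5 * (t.mab_prod - t.mab_waste) + (t.sm_waste - t.sm_prod)
            denom = t.mab_prod + t.sm_prod
            r_conc = max(t.mab_prod / denom, 0.1) if denom > 0 else 0.1
            r_clean = max(t.mab_prod - t.sm_prod, 0.0)
            r_pur = max((r_conc - 0.3) / 0.7, 0.0)
            pen = mab_col if (done and mab_col > CFG.mab_max) else 0.0
            expected = 1e6 * (r_mass * r_conc + r_clean + 100 * r_pur
                              - pen * (1 if done else 0))
            assert b.R == pytest.approx(expected, rel=1e-12)
            assert 0.1 <= b.R_concentration <= 1.0
            assert 0.0 <= b.R_purity <= 1.0
            assert b.P_remaining >= 0.0

    def test_perfect_separation_dominates_all_routings(self):
        """For fixed processed masses, routing all mAb to product and all
        impurity to waste uniquely maximizes the cumulative reward over a
        discrete grid of alternative routings."""
        M, S = 1.0, 2.0
        fractions = np.linspace(0, 1, 5)
        best, best_R = None, -np.inf
        for fm in fractions:
            for fs in fractions:
                t = TankMasses(mab_prod=fm * M, mab_waste=(1 - fm) * M,
                               sm_prod=fs * S, sm_waste=(1 - fs) * S)
                R = total_reward(t, 0.0, done=True, cfg=CFG).R
                if R > best_R:
                    best, best_R = (fm, fs), R
        assert best == (1.0, 0.0)


# ---------------------------------------------------------------------------
# episode mechanics
# ---------------------------------------------------------------------------

class TestEpisode:
    def test_zero_actions_leave_everything_empty(self, tiny_params,
                                                 tiny_calibration):
        env = ChromatographyEnv(base_params=tiny_params, randomization=None,
                                calibration=tiny_calibration, episode_steps=30)
        env.reset(seed=0)
        done = False
        while not done:
            _, r, done, info = env.step(np.full(4, -1.0))
        t = info["tanks"]
        assert t.mab_prod == t.sm_prod == t.mab_waste == t.sm_waste == 0.0
        assert env.cumulative_reward == 0.0
        with pytest.raises(RuntimeError):
            env.step(np.full(4, -1.0))

    def test_default_episode_length_matches_schedule(self, tiny_env):
        # 3000 s at one 15 s control interval per step
        assert EPISODE_STEPS == 200
        assert tiny_env.episode_steps == 200
        assert tiny_env.base_params.h == 15.0

    def test_step_rewards_telescope_to_final_score(self, tiny_params,
                                                   tiny_calibration):
        env = ChromatographyEnv(base_params=tiny_params, randomization=None,
                                calibration=tiny_calibration, episode_steps=40)
        env.reset(seed=1)
        rng = np.random.default_rng(1)
        deltas = []
        done = False
        while not done:
            _, r, done, info = env.step(rng.uniform(-1, 1, 4))
            deltas.append(r)
        final_R = info["reward_breakdown"].R
        assert sum(deltas) == pytest.approx(final_R, abs=1e-9 + 1e-12 * abs(final_R))

    def test_fixed_seed_and_actions_reproduce_trajectory(self, tiny_params,
                                                         tiny_calibration):
        def run():
            env = ChromatographyEnv(base_params=tiny_params,
                                    randomization=RandomizationSpec(S=0.2),
                                    calibration=tiny_calibration,
                                    episode_steps=25)
            obs = env.reset(seed=77)
            rng = np.random.default_rng(9)
            traj = [obs]
            rewards = []
            done = False
            while not done:
                obs, r, done, _ = env.step(rng.uniform(-1, 1, 4))
                traj.append(obs)
                rewards.append(r)
            return np.array(traj), np.array(rewards), env.column_params

        t1, r1, p1 = run()
        t2, r2, p2 = run()
        assert np.array_equal(t1, t2)
        assert np.array_equal(r1, r2)
        assert p1.eps_c == p2.eps_c and np.all(p1.D_ax == p2.D_ax)

    def test_observations_stay_in_unit_box(self, tiny_params, tiny_calibration):
        env = ChromatographyEnv(base_params=tiny_params, randomization=None,
                                calibration=tiny_calibration, episode_steps=15)
        obs = env.reset(seed=3)
        rng = np.random.default_rng(3)
        done = False
        while not done:
            assert obs.shape == (OBS_WINDOW, N_FEATURES)
            assert obs.min() >= 0.0 and obs.max() <= 1.0
            obs, _, done, _ = env.step(rng.uniform(-1, 1, 4))
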