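import numpy as np
import pandas as pd
import pytest

import prosocial_motives as pm
from prosocial_motives.cohort import DEFAULT_PROFILE_COUNTS, cohort_params


class TestProfiles:
    def test_four_default_profiles(self):
        profs = pm.default_profiles()
        assert set(profs) == set(pm.Profile)

    def test_selfish_profile_rarely_prosocial(self, destroy_grid):
        """The unconditionally selfish signature: near-zero prosocial rate
        at every payoff level (deterministic expectation over the grid)."""
        spec = pm.default_profiles()[pm.Profile.UNCONDITIONALLY_SELFISH]
        params = _mean_params(spec)
        p = pm.prob_prosocial(pm.delta_u(params, destroy_grid), params.inv_temp)
        by_bonus = pd.Series(p).groupby(destroy_grid["bonus"].to_numpy()).mean()
        assert (by_bonus < 0.1).all()

    def test_efficiency_profile_deterministic_limit(self, destroy_grid):
        """In the deterministic limit the efficiency type is prosocial iff
        the prosocial action preserves total wealth (ties at 0.5)."""
        spec = pm.default_profiles()[pm.Profile.EFFICIENCY_SENSITIVE]
        mean = dict(spec.mean)
        params = pm.CRParams(bias=0.0, gamma=1.0, mu=0.0, delta1=1.0)
        p = pm.prob_prosocial(pm.delta_u(params, destroy_grid), 1e5)
        wins = destroy_grid["p_b"] > destroy_grid["bonus"]
        ties = destroy_grid["p_b"] == destroy_grid["bonus"]
        assert np.allclose(p[wins.to_numpy()], 1.0)
        assert np.allclose(p[ties.to_numpy()], 0.5)
        assert np.allclose(p[(~wins & ~ties).to_numpy()], 0.0)

    def test_harm_profile_rate_increases_with_pb(self, destroy_grid):
        spec = pm.default_profiles()[pm.Profile.HARM_SENSITIVE]
        params = _mean_params(spec)
        p = pm.prob_prosocial(pm.delta_u(params, destroy_grid), params.inv_temp)
        for bonus in (2, 4, 6):
            mask = (destroy_grid["bonus"] == bonus).to_numpy()
            rate_by_pb = pd.Series(p[mask]).groupby(
                destroy_grid.loc[mask, "p_b"].to_numpy()
            ).mean()
            assert (rate_by_pb.diff().dropna() >= -1e-12).all()

    def test_cost_profile_rate_decreases_with_bonus(self, destroy_grid):
        spec = pm.default_profiles()[pm.Profile.COST_SENSITIVE]
        params = _mean_params(spec)
        p = pm.prob_prosocial(pm.delta_u(params, destroy_grid), params.inv_temp)
        by_bonus = pd.Series(p).groupby(destroy_grid["bonus"].to_numpy()).mean()
        assert by_bonus.is_monotonic_decreasing
        assert by_bonus.iloc[0] - by_bonus.iloc[-1] > 0.2


def _mean_params(spec) -> pm.CRParams:
    from scipy.special import expit

    m = spec.mean
    return pm.CRParams(
        bias=m["bias"],
        gamma=float(expit(m["logit_gamma"])),
        mu=float(expit(m["logit_mu"])),
        delta1=float(expit(m["logit_delta1"])),
        inv_temp=float(np.exp(m["log_inv_temp"])),
    )


class TestSampleCohort:
    def test_empty_counts(self):
        cohort = pm.sample_cohort(counts={}, seed=1)
        assert len(cohort) == 0

    def test_seed_determinism(self):
        a = pm.sample_cohort(seed=42)
        b = pm.sample_cohort(seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = pm.sample_cohort(seed=43)
        assert not a.drop(columns=["participant_id", "profile"]).equals(
            c.drop(columns=["participant_id", "profile"])
        )

    def test_default_composition(self):
        cohort = pm.sample_cohort(seed=0)
        assert len(cohort) == 100
        shares = cohort["profile"].value_counts()
        assert shares[pm.Profile.UNCONDITIONALLY_SELFISH.value] == 20
        assert shares[pm.Profile.COST_SENSITIVE.value] == 25
        assert shares[pm.Profile.EFFICIENCY_SENSITIVE.value] == 39
        assert shares[pm.Profile.HARM_SENSITIVE.value] == 16

    def test_parameter_domains(self):
        cohort = pm.sample_cohort(seed=9)
        for col in ("gamma", "mu", "delta1", "j_gamma", "j_mu", "j_delta1"):
            assert cohort[col].between(0, 1).all()
        assert (cohort["inv_temp"] > 0).all()
        assert (cohort["j_scale"] > 0).all()
        thr = cohort[[f"thr_{i}" for i in range(1, 6)]].to_numpy()
        assert (np.diff(thr, axis=1) > 0).all()


class TestSimulateDataset:
    def test_empty_cohort(self, destroy_grid):
        data = pm.simulate_dataset(pm.sample_cohort(counts={}, seed=0),
                                   destroy_grid, "action", seed=1)
        assert data.empty

    def test_one_response_per_trial_and_reproducible(self, small_cohort, destroy_grid):
        a = pm.simulate_dataset(small_cohort, destroy_grid, "action", seed=3)
        b = pm.simulate_dataset(small_cohort, destroy_grid, "action", seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == len(small_cohort) * len(destroy_grid)

    def test_deterministic_efficiency_agent_rate(self, destroy_grid):
        """Empirical prosocial rate of a near-deterministic efficiency agent
        matches the enumerated expectation 0.70 up to binomial error."""
        cohort = pm.sample_cohort(seed=1).head(1).copy()
        cohort.loc[:, ["bias", "gamma", "mu", "delta1", "inv_temp"]] = \
            [0.0, 1.0, 0.0, 1.0, 1e5]
        reps = [
            pm.simulate_dataset(cohort, destroy_grid, "action", seed=s)["response"].mean()
            for s in range(20)
        ]
        # 20 x 75 trials; exact mean 0.70, sd ~ 0.0075
        assert np.mean(reps) == pytest.approx(0.70, abs=0.03)

    def test_zero_scale_judgments_match_threshold_simplex(self, judgment_grid):
        cohort = pm.sample_cohort(seed=1).head(1).copy()
        cohort.loc[:, "j_scale"] = 0.0
        data = pm.simulate_dataset(cohort, judgment_grid, "judgment", seed=2)
        thresholds = tuple(cohort.iloc[0][f"thr_{i}"] for i in range(1, 6))
        expected = pm.rating_probs(0.0, "prosocial", thresholds, 0.0)
        freq = data["response"].value_counts(normalize=True).reindex(
            range(1, 7), fill_value=0.0
        )
        assert np.abs(freq.to_numpy() - expected).max() < 0.08


class TestEnvironments:
    def test_unanimous_selfish_pool_gives_max_feedback(self, destroy_grid):
        pool = []
        for i in range(11):
            f = destroy_grid[["context", "p_a", "p_b", "bonus"]].copy()
            f["participant_id"] = f"d{i:02d}"
            f["phase"] = "na"
            f["kind"] = "action"
            f["judged_decision"] = ""
            f["response"] = 0
            pool.append(f)
        env = pm.build_environment(pd.concat(pool, ignore_index=True), "a_minus")
        assert (env.feedback["feedback"] == 6).all()
        assert len(env.donor_ids) == 11

    def test_unanimous_strict_judges_mode_is_one(self, judgment_grid):
        pool = []
        for i in range(11):
            f = judgment_grid[["context", "p_a", "p_b", "bonus", "judged_decision"]].copy()
            f["participant_id"] = f"d{i:02d}"
            f["phase"] = "na"
            f["kind"] = "judgment"
            f["response"] = np.where(f["judged_decision"] == "selfish", 1, 6)
            pool.append(f)
        env = pm.build_environment(pd.concat(pool, ignore_index=True), "j_plus")
        assert (env.feedback["feedback"] == 1).all()

    def test_a_plus_pool_more_prosocial_than_a_minus(self, destroy_grid):
        cohort = pm.sample_cohort(seed=21)
        actions = pm.simulate_dataset(cohort, destroy_grid, "action", seed=22)
        plus = pm.build_environment(actions, "a_plus")
        minus = pm.build_environment(actions, "a_minus")
        rate = actions.groupby("participant_id")["response"].mean()
        assert rate[list(plus.donor_ids)].mean() > rate.mean() > rate[list(minus.donor_ids)].mean()
        # A- feedback (selfish counts) dominates A+ feedback on average
        assert minus.feedback["feedback"].mean() >= plus.feedback["feedback"].mean()

    def test_pool_too_small(self, small_actions):
        with pytest.raises(ValueError, match="need 11"):
            pm.build_environment(small_actions, "a_plus")


class TestExposureShift:
    def test_zero_shift_is_identity(self, small_cohort):
        shifted = pm.apply_exposure_shift(small_cohort, {})
        pd.testing.assert_frame_equal(shifted, small_cohort)

    def test_negative_bias_shift_lowers_prosocial_rate(self, destroy_grid):
        cohort = pm.sample_cohort(
            counts={pm.Profile.COST_SENSITIVE: 5}, seed=31
        )
        shifted = pm.apply_exposure_shift(cohort, {"bias": -2.0})
        assert (shifted["bias"] == cohort["bias"] - 2.0).all()
        pre = pm.simulate_dataset(cohort, destroy_grid, "action", seed=32)
        post = pm.simulate_dataset(shifted, destroy_grid, "action", seed=32)
        assert post["response"].mean() < pre["response"].mean()

    def test_logit_shift_respects_domain(self, small_cohort):
        shifted = pm.apply_exposure_shift(small_cohort, {"logit_gamma": -50.0})
        assert shifted["gamma"].between(0, 1).all()
        assert (shifted["gamma"] < small_cohort["gamma"]).all()

    def test_per_profile_shift_targets_only_that_profile(self, small_cohort):
        shifted = pm.apply_exposure_shift(
            small_cohort, {pm.Profile.HARM_SENSITIVE.value: {"bias": -1.0}}
        )
        harm = small_cohort["profile"] == pm.Profile.HARM_SENSITIVE.value
        assert (shifted.loc[harm, "bias"] == small_cohort.loc[harm, "bias"] - 1).all()
        assert (shifted.loc[~harm, "bias"] == small_cohort.loc[~harm, "bias"]).all()


def test_cohort_params_roundtrip(small_cohort):
    row = small_cohort.iloc[0]
    ap = cohort_params(row, "action")
    jp = cohort_params(row, "judgment")
    assert ap.bias == row["bias"] and ap.inv_temp == row["inv_temp"]
    assert jp.scale == row["j_scale"] and len(jp.thresholds) == 5
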