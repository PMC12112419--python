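import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import prosocial_motives as pm
from prosocial_motives.models import (
    LOG_FLOOR,
    TrialDesign,
    spec_from_name,
)


def situation(p_a, p_b, bonus, context="destroy"):
    return pd.DataFrame(
        {"context": [context], "p_a": [p_a], "p_b": [p_b], "bonus": [bonus]}
    )


class TestDeltaU:
    def test_pure_harm_aversion_keeps_only_worst_off_term(self):
        p = pm.CRParams(bias=0, gamma=1, mu=1, delta1=1)
        assert pm.delta_u(p, situation(4, 6, 2)) == pytest.approx(4.0)

    def test_pure_selfish_weight_keeps_only_bonus_term(self):
        p = pm.CRParams(bias=0, gamma=0, mu=0.5, delta1=1)
        assert pm.delta_u(p, situation(2, 10, 6)) == pytest.approx(-6.0)

    def test_mixed_weights_hand_computed(self):
        # 0.25*min + 0.25*(p_b - b) - 0.5*b = 0.25*2 + 0.25*4 - 0.5*6 = -1.5
        p = pm.CRParams(bias=0, gamma=0.5, mu=0.5, delta1=1)
        assert pm.delta_u(p, situation(2, 10, 6)) == pytest.approx(-1.5)

    def test_full_discount_leaves_bias_only(self):
        p = pm.CRParams(bias=0.7, gamma=0, mu=0.5, delta1=0)
        assert pm.delta_u(p, situation(8, 4, 4)) == pytest.approx(0.7)

    def test_delta1_of_one_collapses_contexts(self):
        p = pm.CRParams(bias=0.3, gamma=0.6, mu=0.4, delta1=1.0)
        du_d = pm.delta_u(p, situation(4, 8, 6, "destroy"))
        du_h = pm.delta_u(p, situation(4, 8, 6, "help"))
        assert du_d == pytest.approx(du_h)

    def test_kw_needs_norm_table(self):
        p = pm.AltParams(family="kw", kw_phi=1.0)
        with pytest.raises(ValueError, match="NormTable"):
            pm.delta_u(p, situation(4, 6, 2))

    def test_kw_uses_norm_difference(self):
        stim = pm.build_judgment_grid(["destroy"])[
            ["context", "p_a", "p_b", "bonus", "judged_decision"]
        ].copy()
        # prosocial fully appropriate (+1), selfish fully inappropriate (-1)
        stim["norm"] = np.where(stim["judged_decision"] == "prosocial", 1.0, -1.0)
        table = pm.NormTable(stim)
        p = pm.AltParams(family="kw", kw_phi=2.0)
        assert pm.delta_u(p, situation(4, 6, 2), table) == pytest.approx(-2 + 2 * 2)

    def test_fehr_schmidt_equal_outcomes(self):
        # prosocial outcome (4, 4) has no inequity; selfish (4+b, 0) is all
        # advantageous inequity for A
        p = pm.AltParams(family="fs", fs_alpha=0.0, fs_beta=0.5)
        du = pm.delta_u(p, situation(4, 4, 2))
        assert du == pytest.approx(4 - (4 + 2) * 0.5)


class TestTransferFunctions:
    def test_indifference_gives_half(self):
        assert pm.prob_prosocial(0.0, 5.0) == pytest.approx(0.5)

    def test_deterministic_limit(self):
        assert pm.prob_prosocial(4.0, 1e3) == pytest.approx(1.0, abs=1e-9)

    def test_logistic_value(self):
        assert pm.prob_prosocial(-1.5, 1.0) == pytest.approx(1 / (1 + np.exp(1.5)))

    def test_negative_inv_temp_rejected(self):
        with pytest.raises(ValueError):
            pm.prob_prosocial(1.0, -0.5)

    def test_rating_probs_zero_scale_matches_normal_cdf(self):
        probs = pm.rating_probs(3.0, "prosocial", (-2, -1, 0, 1, 2), 0.0)
        assert probs[0] == pytest.approx(norm.cdf(-2))
        assert probs[-1] == pytest.approx(1 - norm.cdf(2))
        assert probs.sum() == pytest.approx(1.0)

    def test_rating_probs_sign_symmetry(self):
        t = (-2.0, -0.5, 0.1, 0.9, 2.2)
        a = pm.rating_probs(1.3, "prosocial", t, 0.7)
        b = pm.rating_probs(-1.3, "selfish", t, 0.7)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            pm.rating_probs(0.0, "prosocial", (0, -1, 1, 2, 3), 1.0)

    @given(
        du=st.floats(-30, 30),
        scale=st.floats(0, 5),
        gaps=st.lists(st.floats(0.05, 2.0), min_size=4, max_size=4),
        t0=st.floats(-4, 0),
        selfish=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_rating_probs_is_simplex(self, du, scale, gaps, t0, selfish):
        t = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
        probs = pm.rating_probs(
            du, "selfish" if selfish else "prosocial", t, scale
        )
        assert probs.shape == (6,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    @given(
        du=st.lists(st.integers(-15, 15), min_size=2, max_size=6, unique=True),
        inv_temp=st.floats(0.01, 2),
        bias_shift=st.floats(0.01, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_prob_prosocial_monotone_in_du_and_bias(self, du, inv_temp, bias_shift):
        du = np.sort(np.asarray(du, dtype=float))
        p = pm.prob_prosocial(du, inv_temp)
        assert np.all(np.diff(p) > 0)
        # an additive bias raises every choice probability
        assert np.all(pm.prob_prosocial(du + bias_shift, inv_temp) > p)


class TestRescaling:
    @pytest.mark.parametrize("rating, expected", [(1, 0.0), (3, 0.4), (6, 1.0)])
    def test_unit_rescale(self, rating, expected):
        assert pm.rescale_rating_unit(rating) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pm.rescale_rating_unit(7)


class TestNormTable:
    def _judgments(self, ratings_by_pid):
        stim = pm.build_judgment_grid(["destroy"])
        frames = []
        for pid, rating in ratings_by_pid.items():
            f = stim[["context", "p_a", "p_b", "bonus", "judged_decision"]].copy()
            f["participant_id"] = pid
            f["kind"] = "judgment"
            f["response"] = rating
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_unanimous_top_rating_maps_to_one(self):
        table = pm.build_norm_table(self._judgments({"a": 6}))
        assert table.table["norm"].eq(1.0).all()

    def test_opposite_raters_average_to_zero(self):
        table = pm.build_norm_table(self._judgments({"a": 1, "b": 6}))
        assert np.allclose(table.table["norm"], 0.0)

    def test_coverage_gap_reported(self):
        j = self._judgments({"a": 4}).iloc[:-5]
        with pytest.raises(ValueError, match="cover"):
            pm.build_norm_table(j)

    def test_individual_level(self):
        j = self._judgments({"a": 2, "b": 6})
        t = pm.build_norm_table(j, level="individual", participant_id="b")
        assert t.table["norm"].eq(1.0).all()
        assert t.level == "individual"


class TestLoglik:
    def test_single_indifferent_trial(self, destroy_grid):
        data = destroy_grid.head(1)[["context", "p_a", "p_b", "bonus"]].copy()
        data["participant_id"] = "x"
        data["kind"] = "action"
        data["judged_decision"] = ""
        data["response"] = 1
        params = {"x": dict(bias=0.0, gamma=0.0, mu=0.5, delta1=1.0, inv_temp=0.0)}
        spec = pm.ModelSpec(kind="action")
        total, pw = pm.loglik(data, params, spec)
        assert total == pytest.approx(np.log(0.5))

    def test_additivity_over_indifferent_trials(self, destroy_grid):
        n = 15
        data = destroy_grid.head(n)[["context", "p_a", "p_b", "bonus"]].copy()
        data["participant_id"] = "x"
        data["kind"] = "action"
        data["judged_decision"] = ""
        data["response"] = 0
        params = {"x": dict(bias=0.0, gamma=0.0, mu=0.5, delta1=1.0, inv_temp=0.0)}
        total, _ = pm.loglik(data, params, pm.ModelSpec(kind="action"))
        assert total == pytest.approx(n * np.log(0.5))

    def test_matches_bruteforce_product_oracle(self, small_cohort, destroy_grid):
        """Vectorized log-likelihood equals a per-trial enumeration oracle."""
        rng = np.random.default_rng(5)
        data = pm.simulate_dataset(small_cohort.head(2), destroy_grid.head(10),
                                   "action", seed=6)
        spec = pm.ModelSpec(kind="action")
        params = {}
        for _, row in small_cohort.head(2).iterrows():
            params[row["participant_id"]] = dict(
                bias=row["bias"], gamma=row["gamma"], mu=row["mu"],
                delta1=row["delta1"], inv_temp=row["inv_temp"],
            )
        total, pw = pm.loglik(data, params, spec)

        # brute force: per-trial probabilities one at a time
        expected = 0.0
        for _, r in data.iterrows():
            p = params[r["participant_id"]]
            cr = pm.CRParams(bias=p["bias"], gamma=p["gamma"], mu=p["mu"],
                             delta1=p["delta1"], inv_temp=p["inv_temp"])
            sit = situation(r["p_a"], r["p_b"], r["bonus"], r["context"])
            prob = pm.prob_prosocial(float(pm.delta_u(cr, sit)[0]), p["inv_temp"])
            expected += np.log(prob if r["response"] == 1 else 1 - prob)
        assert total == pytest.approx(expected, abs=1e-10)

    def test_judgment_loglik_matches_bruteforce(self, small_cohort, judgment_grid):
        data = pm.simulate_dataset(small_cohort.head(2), judgment_grid.head(12),
                                   "judgment", seed=7)
        spec = pm.ModelSpec(kind="judgment")
        params = {}
        for _, row in small_cohort.head(2).iterrows():
            params[row["participant_id"]] = dict(
                bias=row["j_bias"], gamma=row["j_gamma"], mu=row["j_mu"],
                delta1=row["j_delta1"], scale=row["j_scale"],
                thresholds=tuple(row[f"thr_{i}"] for i in range(1, 6)),
            )
        total, _ = pm.loglik(data, params, spec)
        expected = 0.0
        for _, r in data.iterrows():
            p = params[r["participant_id"]]
            cr = pm.CRParams(bias=p["bias"], gamma=p["gamma"], mu=p["mu"],
                             delta1=p["delta1"], scale=p["scale"],
                             thresholds=p["thresholds"])
            sit = situation(r["p_a"], r["p_b"], r["bonus"], r["context"])
            probs = pm.rating_probs(float(pm.delta_u(cr, sit)[0]),
                                    r["judged_decision"], p["thresholds"], p["scale"])
            expected += np.log(probs[int(r["response"]) - 1])
        assert total == pytest.approx(expected, abs=1e-10)

    def test_log_floor_under_extreme_parameters(self, destroy_grid):
        data = destroy_grid.head(1)[["context", "p_a", "p_b", "bonus"]].copy()
        data["participant_id"] = "x"
        data["kind"] = "action"
        data["judged_decision"] = ""
        data["response"] = 1  # prosocial despite overwhelming selfish utility
        params = {"x": dict(bias=-1000.0, gamma=0.0, mu=0.5, delta1=1.0, inv_temp=50.0)}
        total, _ = pm.loglik(data, params, pm.ModelSpec(kind="action"))
        assert total == pytest.approx(LOG_FLOOR)


class TestSpecPackUnpack:
    @pytest.mark.parametrize("kind", ["action", "judgment"])
    @pytest.mark.parametrize("name", ["cr_d1_bias", "cr_bias", "fs", "harm_bias", "kw_bias"])
    def test_roundtrip(self, name, kind):
        spec = spec_from_name(name, kind=kind)
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 1, spec.n_params)
        params = spec.unpack(theta)
        back = spec.pack(params)
        np.testing.assert_allclose(back, theta, atol=1e-9)

    def test_thresholds_sum_to_zero(self):
        spec = pm.ModelSpec(kind="judgment")
        theta = np.random.default_rng(4).normal(0, 1, spec.n_params)
        t = np.asarray(spec.unpack(theta)["thresholds"])
        assert t.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(t) > 0)


def test_efficiency_agent_grid_rate_is_070(destroy_grid):
    """A deterministic efficiency maximizer is prosocial on 45 strict wins
    plus half of the 15 ties: (45 + 7.5) / 75 = 0.70 by enumeration."""
    p = pm.CRParams(bias=0.0, gamma=1.0, mu=0.0, delta1=1.0)
    du = pm.delta_u(p, destroy_grid)
    probs = pm.prob_prosocial(du, 1e4)
    assert probs.mean() == pytest.approx(0.70, abs=1e-6)
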