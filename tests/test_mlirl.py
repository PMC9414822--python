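import itertools
import math

import numpy as np
import pytest

from adrofit import (
    Demonstration,
    FeedbackRecord,
    MlirlError,
    PreferenceModel,
    RewardWeights,
    build_action_space,
    expand_to_adro_bands,
    features,
    listener_from_scales,
    log_likelihood,
    maximize_likelihood,
    measure_standard_ct,
    policy,
    run_training_session,
    update_preference_model,
)
from adrofit.mlirl import personalized_profile_index


class FlatPreferences:
    """H identically 1 (for closed-form likelihood checks)."""

    def prob(self, s, a):
        return 1.0


def demo(records):
    return Demonstration((tuple(records),))


@pytest.fixture(scope="module")
def space_5x3():
    """Five training bands, three scales: the full 243-profile space."""
    return build_action_space([70.0] * 5, scales=(0.5, 0.75, 1.0))


@pytest.fixture(scope="module")
def toy_space():
    """Two bands, two scales: small enough for brute-force oracles."""
    return build_action_space([70.0, 70.0], scales=(0.5, 1.0))


class TestActionSpace:
    def test_scaling_follows_the_ct_rule(self):
        space = build_action_space([70.0, 70.0], scales=(0.5, 1.0))
        cts = {p.scales: p.ct_db for p in space.profiles}
        assert cts[(0.5, 0.5)] == (35.0, 35.0)
        assert cts[(1.0, 1.0)] == (70.0, 70.0)

    def test_identity_scale_set_gives_single_standard_profile(self):
        space = build_action_space([70.0, 75.0, 80.0], scales=(1.0,))
        assert space.n_profiles == 1
        assert space.profiles[0].ct_db == (70.0, 75.0, 80.0)
        assert space.standard_index == 0

    def test_factorial_enumeration_count(self):
        space = build_action_space([70.0] * 5, scales=(0.5, 0.75, 1.0))
        assert space.n_profiles == 3**5 == 243

    def test_entries_clamped_into_audible_range(self):
        space = build_action_space(
            [70.0, 70.0], scales=(0.5, 1.0), at_db=[40.0, 40.0], ldl_db=[65.0, 65.0]
        )
        for p in space.profiles:
            assert all(40.0 <= c <= 65.0 for c in p.ct_db)

    def test_bad_scale_sets_rejected(self):
        with pytest.raises(MlirlError):
            build_action_space([70.0], scales=())
        with pytest.raises(MlirlError):
            build_action_space([70.0], scales=(0.5, 0.75))  # no standard member
        with pytest.raises(MlirlError):
            build_action_space([70.0], scales=(0.5, 1.0, 2.0))


class TestFeatures:
    def test_standard_action_lights_the_unity_scale_slots(self, space_5x3):
        phi = features(space_5x3, 0, space_5x3.standard_index)
        assert phi.sum() == 5.0
        expected = np.zeros(15)
        expected[2::3] = 1.0  # scale 1.0 is the third scale of every band
        assert np.array_equal(phi, expected)

    def test_exactly_one_indicator_per_band(self, space_5x3):
        rng = np.random.default_rng(0)
        for a in rng.integers(0, space_5x3.n_profiles, 20):
            phi = features(space_5x3, 0, int(a))
            assert phi.sum() == 5.0
            assert np.all(phi.reshape(5, 3).sum(axis=1) == 1.0)

    def test_single_band_difference_flips_two_coordinates(self, space_5x3):
        rng = np.random.default_rng(1)
        pairs_checked = 0
        idx = rng.integers(0, space_5x3.n_profiles, 300)
        for a, b in zip(idx[::2], idx[1::2]):
            diff_bands = np.sum(space_5x3.scale_indices[a] != space_5x3.scale_indices[b])
            hamming = np.sum(features(space_5x3, 0, int(a)) != features(space_5x3, 0, int(b)))
            assert hamming == 2 * diff_bands
            pairs_checked += 1
        assert pairs_checked > 100

    def test_invalid_indices_rejected(self, space_5x3):
        with pytest.raises(MlirlError):
            features(space_5x3, 0, space_5x3.n_profiles)


class TestPolicy:
    def test_zero_reward_gives_uniform_distribution(self, toy_space):
        p = policy(toy_space, RewardWeights(np.zeros(toy_space.n_features)), 0)
        assert np.allclose(p, 1.0 / toy_space.n_profiles)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_dominant_reward_concentrates_probability(self, toy_space):
        w = np.zeros(toy_space.n_features)
        target = 2
        w[toy_space.features_matrix[target].astype(bool)] = 500.0
        p = policy(toy_space, RewardWeights(w), 0)
        assert p[target] == pytest.approx(1.0, abs=1e-12)

    def test_candidate_restriction(self, toy_space):
        p = policy(toy_space, RewardWeights(np.zeros(toy_space.n_features)), 0, candidates=[1, 3])
        assert p.shape == (2,)
        assert abs(p.sum() - 1.0) < 1e-12


class TestPreferenceModel:
    def test_symmetric_prior_is_one_half(self):
        assert PreferenceModel().prob(0, 1) == 0.5

    def test_three_positives_give_point_eight(self):
        h = PreferenceModel()
        for _ in range(3):
            h = update_preference_model(h, FeedbackRecord(0, 1, "positive"))
        assert h.prob(0, 1) == pytest.approx(0.8)

    def test_balanced_feedback_stays_at_one_half(self):
        h = PreferenceModel()
        h = update_preference_model(h, FeedbackRecord(0, 1, "positive"))
        h = update_preference_model(h, FeedbackRecord(0, 1, "negative"))
        assert h.prob(0, 1) == 0.5
        h = update_preference_model(h, FeedbackRecord(0, 1, "neutral"))
        assert h.prob(0, 1) == 0.5

    def test_probabilities_stay_strictly_inside_unit_interval(self):
        h = PreferenceModel()
        for _ in range(50):
            h = update_preference_model(h, FeedbackRecord(0, 1, "positive"))
        assert 0.0 < h.prob(0, 1) < 1.0


class TestLogLikelihood:
    def test_empty_demonstration_has_likelihood_one(self, toy_space):
        w = RewardWeights(np.zeros(toy_space.n_features))
        assert log_likelihood(Demonstration(()), w, PreferenceModel(), toy_space) == 0.0

    def test_uniform_policy_closed_form(self, toy_space):
        # H == 1 and w = 0: every record contributes log(1/k) with k the
        # presented candidate pair size (2)
        records = [FeedbackRecord(0, a, "positive") for a in (1, 2, 3, 1, 2)]
        w = RewardWeights(np.zeros(toy_space.n_features))
        ll = log_likelihood(demo(records), w, FlatPreferences(), toy_space)
        assert ll == pytest.approx(5 * math.log(1 / 2), abs=1e-12)

    def test_matches_brute_force_product_on_toy_demonstration(self, toy_space):
        rng = np.random.default_rng(7)
        w = RewardWeights(rng.normal(0, 1, toy_space.n_features))
        records = [FeedbackRecord(0, 2, "positive"), FeedbackRecord(2, 1, "negative")]
        h = PreferenceModel()
        for r in records:
            h = update_preference_model(h, r)
        ll = log_likelihood(demo(records), w, h, toy_space)

        # independent brute force: product over records of pi * H
        F = toy_space.features_matrix
        product = 1.0
        for rec in records:
            cand = (rec.state_index, rec.action_index)
            chosen = rec.action_index if rec.feedback == "positive" else rec.state_index
            logits = np.array([F[c] @ w.w for c in cand])
            pi = np.exp(logits) / np.exp(logits).sum()
            product *= pi[cand.index(chosen)] * h.prob(rec.state_index, chosen)
        assert ll == pytest.approx(math.log(product), abs=1e-9)

    def test_neutral_records_shape_only_the_preference_model(self, toy_space):
        w = RewardWeights(np.zeros(toy_space.n_features))
        neutral = demo([FeedbackRecord(0, 1, "neutral")])
        assert log_likelihood(neutral, w, PreferenceModel(), toy_space) == 0.0


class TestMaximizeLikelihood:
    def test_single_positive_record_ranks_that_action_first(self, toy_space):
        records = [FeedbackRecord(0, 2, "positive")]
        h = PreferenceModel()
        for r in records:
            h = update_preference_model(h, r)
        w = maximize_likelihood(demo(records), h, toy_space)
        rewards = toy_space.features_matrix @ w.w
        assert rewards[2] > rewards[0]

    def test_ascent_never_loses_likelihood(self, toy_space):
        rng = np.random.default_rng(3)
        records = []
        for _ in range(20):
            s, a = rng.choice(toy_space.n_profiles, 2, replace=False)
            fb = rng.choice(["positive", "negative", "neutral"])
            records.append(FeedbackRecord(int(s), int(a), str(fb)))
        h = PreferenceModel()
        for r in records:
            h = update_preference_model(h, r)
        d = demo(records)
        w0 = RewardWeights(np.zeros(toy_space.n_features))
        w_star = maximize_likelihood(d, h, toy_space)
        assert log_likelihood(d, w_star, h, toy_space) >= log_likelihood(d, w0, h, toy_space)

    def test_matches_grid_search_oracle_on_toy_space(self, toy_space):
        # consistent listener preferring scales (0.5, 1.0): positive whenever
        # the action agrees better with the preference than the state
        pref = {0: 0, 1: 1}  # band -> preferred scale index
        def quality(idx):
            return sum(toy_space.scale_indices[idx][b] == pref[b] for b in range(2))
        records = []
        rng = np.random.default_rng(11)
        state = toy_space.standard_index
        for _ in range(30):
            action = int(rng.choice([i for i in range(toy_space.n_profiles) if i != state]))
            fb = "positive" if quality(action) > quality(state) else "negative"
            records.append(FeedbackRecord(state, action, fb))
            if fb == "positive":
                state = action
        h = PreferenceModel()
        for r in records:
            h = update_preference_model(h, r)
        d = demo(records)
        w_star = maximize_likelihood(d, h, toy_space)

        # brute-force oracle: coarse lattice over the weight toy_space
        best_ll, best_w = -np.inf, None
        for w_vec in itertools.product([-2.0, -1.0, 0.0, 1.0, 2.0], repeat=toy_space.n_features):
            ll = log_likelihood(d, RewardWeights(np.array(w_vec)), h, toy_space)
            if ll > best_ll:
                best_ll, best_w = ll, np.array(w_vec)
        assert log_likelihood(d, w_star, h, toy_space) >= best_ll - 1e-6
        # both routes identify the same preferred profile
        grid_best = personalized_profile_index(toy_space, RewardWeights(best_w))
        ours = personalized_profile_index(toy_space, w_star)
        assert toy_space.scale_indices[ours].tolist() == [0, 1]
        assert grid_best == ours


class TestExpandToAdroBands:
    def test_uniform_within_pair_scaling_with_half_up_rounding(self):
        standard = (78, 78, 80, 82, 81, 80, 80, 80, 77, 75)
        out = expand_to_adro_bands((0.5, 0.5, 0.75, 0.75, 0.5), standard)
        assert out.tolist() == [39, 39, 40, 41, 61, 60, 60, 60, 39, 38]

    def test_identity_scales_reproduce_the_standard_vector(self):
        standard = (70, 70, 75, 80, 80, 80, 80, 80, 77, 75)
        assert expand_to_adro_bands((1.0,) * 5, standard).tolist() == list(standard)

    def test_half_scale_on_first_band_pair(self):
        out = expand_to_adro_bands((0.5, 1, 1, 1, 1), (70, 70, 70, 70, 72, 75, 77, 80, 75, 70))
        assert out[0] == 35 and out[1] == 35

    def test_length_mismatch_rejected(self):
        with pytest.raises(MlirlError):
            expand_to_adro_bands((0.5, 1.0), (70, 70, 70))


class TestMeasureStandardCt:
    def test_staircase_returns_one_step_below_the_boundary(self, profile):
        listener = listener_from_scales(profile, (1.0,) * 5)
        # boundary is the LDL of band 0 (95 dB): staircase lands at 90
        assert measure_standard_ct(listener, 0) == profile.map.ldl_db[0] - 5.0

    def test_result_always_on_the_step_grid(self, profile):
        listener = listener_from_scales(profile, (1.0,) * 5)
        for band in range(10):
            ct = measure_standard_ct(listener, band)
            assert (ct - 40.0) % 5.0 == 0.0

    def test_implausible_listener_raises(self, profile):
        class DeafListener:
            pass

        with pytest.raises(MlirlError):
            measure_standard_ct(
                DeafListener(), 0, too_loud_fn=lambda lv, b, l: False
            )


class TestTrainingSession:
    def test_all_same_feedback_keeps_the_standard_profile(self, profile):
        listener = listener_from_scales(profile, (1.0,) * 5)
        result = run_training_session(
            listener,
            profile,
            n_trajectories=1,
            n_pairs=8,
            seed=0,
            choose_fn=lambda a, b, l, r: "same",
        )
        assert all(r.feedback == "neutral" for r in result.demonstration.records())
        assert np.all(result.weights.w == 0.0)
        assert result.personalized.scales == (1.0,) * 5

    def test_sessions_are_deterministic_given_the_seed(self, profile):
        listener = listener_from_scales(profile, (0.5, 1.0, 0.75, 0.5, 1.0))
        kw = dict(n_trajectories=2, n_pairs=6, seed=9)
        r1 = run_training_session(listener, profile, **kw)
        r2 = run_training_session(listener, profile, **kw)
        assert r1.demonstration == r2.demonstration
        assert np.array_equal(r1.weights.w, r2.weights.w)
        assert r1.personalized == r2.personalized

    def test_noiseless_listener_profile_is_recovered(self, profile):
        true_scales = (0.5, 0.75, 1.0, 0.5, 0.75)
        listener = listener_from_scales(
            profile, true_scales, choice_noise_temperature=0.0
        )
        result = run_training_session(listener, profile, seed=3)
        correct = sum(a == b for a, b in zip(result.personalized.scales, true_scales))
        assert correct >= 4

    def test_personalized_cts_stay_inside_the_audible_range(self, profile):
        listener = listener_from_scales(profile, (0.5,) * 5)
        result = run_training_session(
            listener, profile, n_trajectories=2, n_pairs=10, seed=1
        )
        ct10 = result.personalized_ct_adro_db
        assert np.all(ct10 >= profile.map.at_db)
        assert np.all(ct10 <= profile.map.ldl_db)
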