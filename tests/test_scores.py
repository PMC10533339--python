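"""A' from rating counts and FADE/SAME scores against a young reference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fadesame import (RatingCounts, a_prime, fade_score, hit_fa_rates,
                      same_score, score_cohort)
from fadesame.reference import YoungReference


def ranksum_aprime(counts):
    """Independent oracle: P(old rating > new rating) + 0.5 P(tie)."""
    o, n = counts.old_counts, counts.new_counts
    total = 0.0
    for i in range(5):
        for j in range(5):
            if i > j:
                total += o[i] * n[j]
            elif i == j:
                total += 0.5 * o[i] * n[j]
    return total / (counts.n_old * counts.n_new)


count_vectors = st.lists(st.integers(0, 20), min_size=5, max_size=5)


class TestRocCurve:
    def test_boundary_points(self):
        pts = hit_fa_rates(RatingCounts([3, 1, 4, 1, 5], [2, 7, 1, 8, 2]))
        assert tuple(pts[0]) == (0.0, 0.0)    # t = 5
        assert tuple(pts[-1]) == (1.0, 1.0)   # t = 0
        assert np.all(np.diff(pts, axis=0) >= 0)

    def test_separated_counts(self):
        pts = hit_fa_rates(RatingCounts([0, 0, 0, 5, 5], [5, 5, 0, 0, 0]))
        fa3, h3 = pts[2]  # threshold t = 3
        assert h3 == 1.0 and fa3 == 0.0

    def test_identical_distributions_on_diagonal(self):
        pts = hit_fa_rates(RatingCounts([2, 4, 6, 4, 2], [1, 2, 3, 2, 1]))
        assert np.allclose(pts[:, 0], pts[:, 1])

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            hit_fa_rates(RatingCounts([0] * 5, [1, 1, 1, 1, 1]))


class TestAPrime:
    def test_chance_and_perfect_anchors(self):
        assert a_prime(RatingCounts([20] * 5, [20] * 5)) == 0.5
        assert a_prime(RatingCounts([0, 0, 0, 0, 88], [44, 0, 0, 0, 0])) == 1.0

    def test_worked_example(self):
        # rank-sum decomposition: P(o>n) = 0.60, P(o=n) = 0.20
        assert a_prime(RatingCounts([2] * 5, [4, 3, 2, 1, 0])) \
            == pytest.approx(0.70)

    @settings(deadline=None, max_examples=200)
    @given(old=count_vectors, new=count_vectors)
    def test_equals_ranksum_oracle(self, old, new):
        if sum(old) == 0 or sum(new) == 0:
            return
        rc = RatingCounts(old, new)
        assert a_prime(rc) == pytest.approx(ranksum_aprime(rc), abs=1e-12)

    def test_raising_an_old_rating_past_a_new_one_increases_aprime(self):
        before = RatingCounts([0, 5, 0, 0, 0], [0, 0, 5, 0, 0])
        after = RatingCounts([0, 4, 0, 1, 0], [0, 0, 5, 0, 0])
        assert a_prime(after) > a_prime(before)


def _ref(mask_n, j_plus_idx, j_minus_idx=(), beta=None, sigma=None):
    j_plus = np.zeros(mask_n, bool)
    j_plus[list(j_plus_idx)] = True
    j_minus = np.zeros(mask_n, bool)
    j_minus[list(j_minus_idx)] = True
    return YoungReference(
        contrast="memory", mask=np.ones((mask_n, 1, 1), bool),
        j_plus=j_plus, j_minus=j_minus,
        beta_hat=np.zeros(mask_n) if beta is None else np.asarray(beta, float),
        sigma_hat=np.ones(mask_n) if sigma is None else np.asarray(sigma,
                                                                   float))


class TestFade:
    def test_hand_arithmetic(self):
        # J+ t = (4, 6) -> mean 5; outside t = (1, 2, 3) -> mean 2
        ref = _ref(5, j_plus_idx=(0, 1))
        assert fade_score([4, 6, 1, 2, 3], ref) == pytest.approx(-3.0)

    def test_constant_map_scores_zero(self):
        ref = _ref(6, j_plus_idx=(0, 3))
        assert fade_score(np.full(6, 2.7), ref) == pytest.approx(0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        t_map = rng.normal(size=9)
        ref = _ref(9, j_plus_idx=(1, 4, 7))
        assert fade_score(t_map + 11.3, ref) == pytest.approx(
            fade_score(t_map, ref))

    def test_linear_in_t(self):
        rng = np.random.default_rng(1)
        ref = _ref(8, j_plus_idx=(0, 1, 2))
        t1, t2 = rng.normal(size=8), rng.normal(size=8)
        assert fade_score(2 * t1 + 3 * t2, ref) == pytest.approx(
            2 * fade_score(t1, ref) + 3 * fade_score(t2, ref))

    def test_empty_jplus_rejected(self):
        ref = _ref(4, j_plus_idx=())
        with pytest.raises(ValueError, match="J\\+"):
            fade_score(np.ones(4), ref)


class TestSame:
    def test_hand_arithmetic(self):
        ref = _ref(2, j_plus_idx=(0,), j_minus_idx=(1,),
                   beta=[2.0, -1.0], sigma=[1.0, 0.5])
        # (3-2)/1 + (-1 - (-2))/0.5 = 1 + 2
        assert same_score([3.0, -2.0], ref) == pytest.approx(3.0)

    def test_young_mean_map_scores_zero(self):
        rng = np.random.default_rng(2)
        beta = rng.normal(size=7)
        ref = _ref(7, j_plus_idx=(0, 1), j_minus_idx=(5, 6), beta=beta,
                   sigma=np.abs(rng.normal(size=7)) + 0.1)
        assert same_score(beta, ref) == pytest.approx(0.0)

    def test_doubling_sigma_halves_score(self):
        rng = np.random.default_rng(3)
        beta, gamma = rng.normal(size=6), rng.normal(size=6)
        sigma = np.abs(rng.normal(size=6)) + 0.1
        lo = _ref(6, (0, 1), (4, 5), beta=beta, sigma=sigma)
        hi = _ref(6, (0, 1), (4, 5), beta=beta, sigma=2 * sigma)
        assert same_score(gamma, hi) == pytest.approx(
            same_score(gamma, lo) / 2)

    def test_linear_in_gamma(self):
        rng = np.random.default_rng(4)
        ref = _ref(6, (0, 1), (4, 5), beta=np.zeros(6),
                   sigma=np.ones(6))
        g1, g2 = rng.normal(size=6), rng.normal(size=6)
        assert same_score(g1 + g2, ref) == pytest.approx(
            same_score(g1, ref) + same_score(g2, ref))

    def test_degenerate_sigma_excluded_with_warning(self):
        ref = _ref(3, (0, 1), (), beta=[0, 0, 0], sigma=[1.0, 0.0, 1.0])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            val = same_score([2.0, 99.0, 0.0], ref)
        assert val == pytest.approx(2.0)  # only the sane voxel counts


class TestScoreCohort:
    def test_output_contract(self, tiny_cohort, tiny_references):
        df = score_cohort(tiny_cohort.maps, ratings=tiny_cohort.ratings,
                          references=tiny_references)
        assert list(df.columns) == ["subject_id", "group", "a_prime",
                                    "fade_novelty", "same_novelty",
                                    "fade_memory", "same_memory"]
        assert len(df) == len(tiny_cohort.subjects)
        assert df["a_prime"].between(0, 1).all()

    def test_young_in_sample_same_mean_near_zero(self, small_cohort):
        df = score_cohort(small_cohort.maps, ratings=small_cohort.ratings)
        young = df[df["group"] == "young"]["same_memory"]
        assert abs(young.mean()) < 3 * young.std() / np.sqrt(len(young))

    def test_older_less_young_like_than_young(self, small_cohort):
        df = score_cohort(small_cohort.maps, ratings=small_cohort.ratings)
        g = df.groupby("group")
        assert g["same_memory"].mean()["older"] < \
            g["same_memory"].mean()["young"]
        assert g["fade_memory"].mean()["older"] > \
            g["fade_memory"].mean()["young"]

    def test_fade_same_negatively_correlated(self, small_cohort):
        df = score_cohort(small_cohort.maps, ratings=small_cohort.ratings)
        r = np.corrcoef(df["fade_memory"], df["same_memory"])[0, 1]
        assert r < -0.3

    def test_missing_ratings_give_missing_aprime(self, tiny_cohort,
                                                 tiny_references):
        ratings = dict(tiny_cohort.ratings)
        dropped = tiny_cohort.maps[0].subject_id
        del ratings[dropped]
        df = score_cohort(tiny_cohort.maps, ratings=ratings,
                          references=tiny_references)
        row = df[df["subject_id"] == dropped].iloc[0]
        assert np.isnan(row["a_prime"])
        assert np.isfinite(row["same_memory"])

    def test_leave_one_out_differs_from_in_sample_for_young(
            self, tiny_cohort, tiny_references):
        in_s = score_cohort(tiny_cohort.maps, references=tiny_references)
        loo = score_cohort(tiny_cohort.maps, references=tiny_references,
                           young_mode="leave_one_out")
        young = in_s["group"] == "young"
        assert not np.allclose(in_s.loc[young, "same_memory"],
                               loo.loc[young, "same_memory"])
        older = ~young
        assert np.allclose(in_s.loc[older, "same_memory"],
                           loo.loc[older, "same_memory"])
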