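import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frlf import (
    FusionParams,
    InvalidScoreError,
    ScoreMatrix,
    frlf_fuse,
    frlf_fuse_batch,
    fuzzy_rank,
    fuzzy_rank_matrix,
    normalize_scores,
    top_k_classes,
)
from conftest import random_normalized_matrix
from oracle_frlf import frlf_scalar


class TestScoreMatrix:
    def test_rejects_negative_entry_naming_offender(self):
        with pytest.raises(InvalidScoreError, match="M2.*cB"):
            ScoreMatrix(np.array([[0.5, 0.5], [0.5, -0.1]]), ["M1", "M2"], ["cA", "cB"])

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidScoreError):
            ScoreMatrix(np.array([[np.nan, 1.0]]))

    @pytest.mark.parametrize("shape", [(0, 2), (1, 1)])
    def test_rejects_degenerate_shapes(self, shape):
        with pytest.raises(InvalidScoreError):
            ScoreMatrix(np.ones(shape))


class TestNormalizeScores:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([2.0, 2.0], [0.5, 0.5]),
            ([0.6, 0.4], [0.6, 0.4]),
            ([0.0, 0.0], [0.5, 0.5]),  # all-zero row -> uniform
        ],
    )
    def test_examples(self, row, expected):
        out = normalize_scores(ScoreMatrix(np.array([row])))
        np.testing.assert_allclose(out.scores[0], expected)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=6))
    def test_rows_sum_to_one_and_preserve_proportions(self, row):
        out = normalize_scores(ScoreMatrix(np.array([row])))
        assert abs(out.scores.sum() - 1.0) < 1e-9
        total = sum(row)
        if total > 0:
            np.testing.assert_allclose(out.scores[0], np.array(row) / total, atol=1e-12)


class TestFuzzyRank:
    def test_boundary_and_derived_values(self):
        assert fuzzy_rank(1.0) == 0.0
        assert fuzzy_rank(0.0) == pytest.approx(1 - math.exp(-0.5), abs=1e-12)
        assert fuzzy_rank(0.9) == pytest.approx(0.00498752080731768, abs=1e-12)

    def test_strictly_decreasing_on_unit_interval(self):
        grid = np.linspace(0.0, 1.0, 1001)
        vals = fuzzy_rank(grid)
        assert np.all(np.diff(vals) < 0)

    def test_variance_must_be_positive(self):
        with pytest.raises(ValueError):
            fuzzy_rank(0.5, variance=0.0)

    def test_matrix_rows(self):
        sm = ScoreMatrix(np.array([[0.9, 0.1], [1.0, 0.0], [0.5, 0.5]]))
        rm = fuzzy_rank_matrix(sm)
        np.testing.assert_allclose(
            rm.ranks[0], [1 - math.exp(-0.005), 1 - math.exp(-0.405)], atol=1e-12
        )
        np.testing.assert_allclose(rm.ranks[1], [0.0, 1 - math.exp(-0.5)], atol=1e-12)
        assert rm.ranks[2][0] == rm.ranks[2][1]  # uniform row -> equal ranks

    def test_range_bound_for_unit_scores(self, rng):
        sm = random_normalized_matrix(rng, 5, 4)
        rm = fuzzy_rank_matrix(sm)
        assert np.all(rm.ranks >= 0)
        assert np.all(rm.ranks <= 1 - math.exp(-0.5) + 1e-15)


class TestTopK:
    def test_unique_minimum_and_tie_break(self):
        rm = fuzzy_rank_matrix(ScoreMatrix(np.array([[0.9, 0.1], [0.5, 0.5]])))
        assert top_k_classes(rm, 1) == [[0], [0]]  # second row ties -> lowest index

    def test_k_two_orders_by_rank(self):
        # scores (0.7, 0.9, 0.8) give ranks ordered class1 < class2 < class0
        rm = fuzzy_rank_matrix(ScoreMatrix(np.array([[0.7, 0.9, 0.8]]) / 2.4))
        assert top_k_classes(rm, 2) == [[1, 2]]

    def test_k_out_of_range(self):
        rm = fuzzy_rank_matrix(ScoreMatrix(np.array([[0.5, 0.5]])))
        with pytest.raises(ValueError):
            top_k_classes(rm, 3)


class TestFrlfFuse:
    def test_worked_example(self, worked_example):
        r = frlf_fuse(worked_example)
        np.testing.assert_allclose(r.rank_sums[0], 0.08187117442068192, atol=1e-12)
        np.testing.assert_allclose(r.conf_complements, [0.25, 0.95], atol=1e-12)
        np.testing.assert_allclose(r.final_scores, [0.02046779360517048, 0.627], atol=1e-12)
        assert r.predicted_class == 0
        assert r.predicted_class_id == "pd"
        assert r.top_k_sets == [[0], [0]]

    def test_final_score_is_product_of_factors(self, rng):
        for _ in range(20):
            sm = random_normalized_matrix(rng, 3, 4)
            r = frlf_fuse(sm, FusionParams(k=2))
            np.testing.assert_allclose(
                r.final_scores, r.rank_sums * r.conf_complements, atol=0
            )
            assert r.predicted_class == int(np.argmin(r.final_scores))

    def test_unanimous_certainty_scores_zero(self):
        sm = ScoreMatrix(np.tile([1.0, 0.0], (3, 1)))
        r = frlf_fuse(sm)
        assert r.predicted_class == 0
        assert r.final_scores[0] == 0.0

    def test_single_model_k_equals_c_reduces_to_argmax(self, rng):
        for _ in range(20):
            sm = random_normalized_matrix(rng, 1, 4)
            r = frlf_fuse(sm, FusionParams(k=4))
            assert r.predicted_class == int(np.argmax(sm.scores[0]))

    def test_rejects_unnormalized_unless_flagged(self):
        sm = ScoreMatrix(np.array([[2.0, 2.0]]))
        with pytest.raises(InvalidScoreError):
            frlf_fuse(sm)
        assert frlf_fuse(sm, auto_normalize=True).predicted_class == 0

    def test_unanimity_binary_grid(self):
        """If every model puts its larger confidence on one class, that
        class wins (winner confidences swept densely over (0.5, 1])."""
        for w in np.linspace(0.501, 1.0, 500):
            for n in (1, 2, 4):
                sm = ScoreMatrix(np.tile([1 - w, w], (n, 1)))
                assert frlf_fuse(sm).predicted_class == 1

    def test_permutation_equivariance(self, rng):
        for _ in range(25):
            n, c = int(rng.integers(1, 5)), int(rng.integers(2, 6))
            sm = random_normalized_matrix(rng, n, c)
            perm = rng.permutation(c)
            permuted = ScoreMatrix(sm.scores[:, perm])
            r, rp = frlf_fuse(sm), frlf_fuse(permuted)
            np.testing.assert_allclose(rp.final_scores, r.final_scores[perm], atol=1e-15)
            assert perm[rp.predicted_class] == r.predicted_class

    def test_agrees_with_scalar_oracle(self, rng):
        for _ in range(200):
            n, c = int(rng.integers(1, 6)), int(rng.integers(2, 7))
            k = int(rng.integers(1, c + 1))
            sm = random_normalized_matrix(rng, n, c)
            rs, css, fs, pred = frlf_scalar(sm.scores.tolist(), k=k)
            r = frlf_fuse(sm, FusionParams(k=k))
            np.testing.assert_allclose(r.rank_sums, rs, atol=1e-12)
            np.testing.assert_allclose(r.conf_complements, css, atol=1e-12)
            np.testing.assert_allclose(r.final_scores, fs, atol=1e-12)
            assert r.predicted_class == pred


class TestFrlfBatch:
    def test_empty_and_singleton(self, worked_example):
        assert frlf_fuse_batch([]) == []
        batch = frlf_fuse_batch([worked_example])
        single = frlf_fuse(worked_example)
        np.testing.assert_array_equal(batch[0].final_scores, single.final_scores)

    def test_rejects_heterogeneous_shapes(self, rng):
        a = random_normalized_matrix(rng, 2, 2)
        b = random_normalized_matrix(rng, 2, 3)
        with pytest.raises(InvalidScoreError):
            frlf_fuse_batch([a, b])

    def test_order_preserved(self, rng):
        samples = [random_normalized_matrix(rng, 2, 3) for _ in range(10)]
        batch = frlf_fuse_batch(samples)
        for s, r in zip(samples, batch):
            np.testing.assert_array_equal(r.final_scores, frlf_fuse(s).final_scores)


class TestFusionParams:
    @pytest.mark.parametrize(
        "kwargs", [{"k": 0}, {"variance": 0.0}, {"rank_penalty": -1.0}, {"conf_penalty": np.inf}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FusionParams(**kwargs)

    def test_defaults_match_published_hyperparameters(self):
        p = FusionParams()
        assert (p.k, p.rank_penalty, p.conf_penalty, p.variance) == (1, 0.33, 0.05, 1.0)
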