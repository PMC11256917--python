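"""Cross-attention token selection: oracles, tie-breaks, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsdti._tensor import Tensor
from bsdti.cass import (CASS, cass_forward, cross_attention_weights,
                        n_elected, score_tokens, top_k_select)


def sort_oracle(scores, k_percent):
    """Independent election oracle: exhaustive stable sort on (-score, idx)."""
    k = max(1, int(np.ceil(k_percent / 100.0 * len(scores))))
    ranked = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return np.array(sorted(ranked[:k]))


class TestTopKSelect:
    def test_matches_sort_oracle_on_random_vectors_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            t = int(rng.integers(1, 65))
            scores = rng.random(t)
            if t > 2 and rng.random() < 0.5:   # inject ties
                j = rng.integers(0, t, size=2)
                scores[j[0]] = scores[j[1]]
            scores = scores / scores.sum()
            k = float(rng.uniform(1, 100))
            tokens = rng.normal(size=(t, 5))
            res = top_k_select(tokens, scores, k)
            np.testing.assert_array_equal(res.selected_idx,
                                          sort_oracle(scores, k))

    def test_stage_vector_is_exact_column_sum(self):
        rng = np.random.default_rng(8)
        tokens = rng.normal(size=(10, 16))
        scores = rng.dirichlet(np.ones(10))
        res = top_k_select(tokens, scores, 40)
        np.testing.assert_array_equal(
            res.stage_vector, tokens[res.selected_idx].sum(axis=0))
        res.validate()

    def test_worked_example_half(self):
        res = top_k_select(np.eye(4), np.array([0.4, 0.3, 0.2, 0.1]), 50)
        np.testing.assert_array_equal(res.selected_idx, [0, 1])

    def test_k100_selects_everything(self):
        tokens = np.arange(12.0).reshape(4, 3)
        res = top_k_select(tokens, np.full(4, 0.25), 100)
        np.testing.assert_array_equal(res.selected_idx, [0, 1, 2, 3])
        np.testing.assert_allclose(res.stage_vector, tokens.sum(axis=0))

    def test_uniform_scores_tie_break_to_low_index(self):
        res = top_k_select(np.zeros((8, 2)), np.full(8, 1 / 8), 25)
        np.testing.assert_array_equal(res.selected_idx, [0, 1])

    @pytest.mark.parametrize("bad_k", [0, -5, 101])
    def test_invalid_k_rejected(self, bad_k):
        with pytest.raises(ValueError):
            top_k_select(np.zeros((3, 2)), np.full(3, 1 / 3), bad_k)

    def test_minimum_one_token(self):
        res = top_k_select(np.ones((1, 4)), np.array([1.0]), 1)
        np.testing.assert_array_equal(res.selected_idx, [0])

    @given(st.integers(1, 40), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_permutation_equivariance_distinct_scores(self, t, seed):
        """Permuting tokens+scores permutes the election accordingly."""
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.linspace(0.1, 1.0, t))
        scores /= scores.sum()
        tokens = rng.normal(size=(t, 3))
        perm = rng.permutation(t)
        base = top_k_select(tokens, scores, 30)
        permed = top_k_select(tokens[perm], scores[perm], 30)
        inv = np.empty(t, dtype=int)
        inv[perm] = np.arange(t)
        np.testing.assert_array_equal(
            sorted(inv[base.selected_idx]), permed.selected_idx)
        np.testing.assert_allclose(permed.stage_vector, base.stage_vector,
                                   atol=1e-12)


class TestScoreNetwork:
    def test_identical_rows_give_uniform_scores(self):
        mod = np.tile(np.arange(6.0), (5, 1))
        s = score_tokens(mod, seed=3)
        np.testing.assert_allclose(s, np.full(5, 0.2), atol=1e-12)

    def test_scores_normalized(self, rng):
        s = score_tokens(rng.normal(size=(9, 8)), seed=1)
        assert abs(s.sum() - 1.0) < 1e-6
        assert (s > 0).all()

    def test_closed_form_two_token_softmax(self):
        """FFD outputs (1, 0) must softmax to (e/(e+1), 1/(e+1))."""
        cass = CASS(2, np.random.default_rng(0))
        # overwrite the selection network to output the first feature
        cass.ffd.fc1.W.data = np.eye(2)
        cass.ffd.fc1.b.data = np.zeros(2)
        cass.ffd.fc2.W.data = np.array([[1.0], [0.0]])
        cass.ffd.fc2.b.data = np.zeros(1)
        s = cass.score(Tensor(np.array([[[1.0, 0.0], [0.0, 1.0]]])))
        e = np.e
        np.testing.assert_allclose(s.data[0], [e / (e + 1), 1 / (e + 1)],
                                   atol=1e-12)


class TestCrossAttention:
    def test_single_reference_token_gets_full_weight(self):
        """With one reference token the attended context is exactly its
        value projection, regardless of the query."""
        cass = CASS(3, np.random.default_rng(5))
        main = np.array([[0.3, -1.0, 2.0]])
        ref = np.array([[1.0, 1.0, 1.0]])
        out = cass.modulate(Tensor(main[None]), Tensor(ref[None])).data[0]
        v = ref @ cass.Wv.W.data + cass.Wv.b.data
        np.testing.assert_allclose(out, main * v, atol=1e-12)

    def test_saturated_softmax_picks_aligned_reference(self):
        """With identity projections and a large scale, the attention limit
        puts all weight on the aligned reference token."""
        d = 4
        cass = CASS(d, np.random.default_rng(0))
        for lin in (cass.Wq, cass.Wk, cass.Wv):
            lin.W.data = np.eye(d) * 50.0
            lin.b.data = np.zeros(d)
        cass.Wv.W.data = np.eye(d)
        ref = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        main = np.array([[1.0, 0, 0, 0]])
        out = cass.modulate(Tensor(main[None]), Tensor(ref[None])).data[0]
        np.testing.assert_allclose(out, main * ref[0], atol=1e-8)

    def test_output_shape_and_empty_reference(self, rng):
        out = cross_attention_weights(rng.normal(size=(4, 80)),
                                      rng.normal(size=(8, 80)), seed=0)
        assert out.shape == (4, 80)
        with pytest.raises(ValueError):
            cross_attention_weights(rng.normal(size=(4, 8)),
                                    np.zeros((0, 8)))


class TestCassForward:
    def test_default_k_elects_30_percent(self, rng):
        res = cass_forward(rng.normal(size=(10, 8)),
                           rng.normal(size=(4, 8)), 30)
        assert len(res.selected_idx) == int(np.ceil(0.3 * 10)) == 3

    def test_single_main_token_always_elected(self, rng):
        res = cass_forward(rng.normal(size=(1, 8)),
                           rng.normal(size=(4, 8)), 10)
        np.testing.assert_array_equal(res.selected_idx, [0])

    def test_deterministic_under_fixed_seed(self, rng):
        main = rng.normal(size=(6, 8))
        ref = rng.normal(size=(3, 8))
        a = cass_forward(main, ref, 50, seed=9)
        b = cass_forward(main, ref, 50, seed=9)
        np.testing.assert_array_equal(a.selected_idx, b.selected_idx)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_n_elected_ceiling(self):
        assert n_elected(8, 25) == 2
        assert n_elected(8, 30) == 3      # ceil(2.4)
        assert n_elected(3, 1) == 1
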