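import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnbmla.scoring import (
    DAGStructure,
    FamilyCountCache,
    ScoreConfig,
    dag_log_score,
    family_log_marginal,
    score_delta,
)
from helpers import sequential_predictive_log_prob


def cache_for(codes, arities, **kwargs):
    return FamilyCountCache((np.asarray(codes), arities), ScoreConfig(**kwargs))


class TestFamilyScore:
    def test_two_identical_binary_observations(self):
        # sequential predictive product (1/2) * (2/3) = 1/3
        c = cache_for([[1], [1]], [2])
        assert c.family_score(0, ()) == pytest.approx(math.log(1 / 3))

    def test_empty_dataset_scores_zero(self):
        c = cache_for(np.zeros((0, 2), dtype=int), [2, 3])
        assert c.family_score(0, ()) == 0.0
        assert c.family_score(1, (0,)) == 0.0

    @pytest.mark.parametrize("arity", [2, 3])
    def test_matches_sequential_predictive_oracle(self, arity):
        rng = np.random.default_rng(arity)
        seq = rng.integers(0, arity, 30)
        c = cache_for(seq.reshape(-1, 1), [arity])
        assert c.family_score(0, ()) == pytest.approx(
            sequential_predictive_log_prob(seq, arity)
        )

    def test_parent_conditioning_decomposes_by_configuration(self):
        rng = np.random.default_rng(1)
        parent = rng.integers(0, 2, 40)
        child = rng.integers(0, 2, 40)
        c = cache_for(np.column_stack([parent, child]), [2, 2])
        expected = sum(
            sequential_predictive_log_prob(child[parent == v], 2) for v in (0, 1)
        )
        assert c.family_score(1, (0,)) == pytest.approx(expected)

    def test_parent_limit_enforced(self):
        c = cache_for(np.zeros((4, 4), dtype=int), [1, 1, 1, 1], max_parents=2)
        with pytest.raises(ValueError, match="limit"):
            c.family_score(0, (1, 2, 3))

    def test_bdeu_prior_finite_and_distinct_from_ch(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 2, (50, 2))
        ch = cache_for(codes, [2, 2])
        bdeu = cache_for(codes, [2, 2], prior_kind="BDeu", ess=1.0)
        a, b = ch.family_score(1, (0,)), bdeu.family_score(1, (0,))
        assert np.isfinite(a) and np.isfinite(b) and a != b


class TestDagScore:
    def data(self, n=60):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, n)
        y = (x ^ (rng.random(n) < 0.2)).astype(int)
        return np.column_stack([x, y]), [2, 2]

    def test_empty_graph_is_sum_of_no_parent_families(self):
        codes, ar = self.data()
        c = cache_for(codes, ar)
        g = DAGStructure(2)
        assert dag_log_score(g, None, cache=c) == pytest.approx(
            c.family_score(0, ()) + c.family_score(1, ())
        )

    def test_both_orientations_match_oracle(self):
        codes, ar = self.data()
        c = cache_for(codes, ar)
        x, y = codes[:, 0], codes[:, 1]
        fwd = DAGStructure.from_edges(2, [(0, 1)])
        rev = DAGStructure.from_edges(2, [(1, 0)])
        expect_fwd = sequential_predictive_log_prob(x, 2) + sum(
            sequential_predictive_log_prob(y[x == v], 2) for v in (0, 1)
        )
        expect_rev = sequential_predictive_log_prob(y, 2) + sum(
            sequential_predictive_log_prob(x[y == v], 2) for v in (0, 1)
        )
        assert dag_log_score(fwd, None, cache=c) == pytest.approx(expect_fwd)
        assert dag_log_score(rev, None, cache=c) == pytest.approx(expect_rev)

    def test_posterior_ratio_is_exp_score_difference(self):
        codes, ar = self.data()
        c = cache_for(codes, ar)
        g1 = DAGStructure.from_edges(2, [(0, 1)])
        g0 = DAGStructure(2)
        s1, s0 = dag_log_score(g1, None, cache=c), dag_log_score(g0, None, cache=c)
        # dependent data should favor the connected structure
        assert math.exp(s1 - s0) > 1.0

    def test_row_order_invariance(self):
        codes, ar = self.data()
        rng = np.random.default_rng(0)
        perm = rng.permutation(codes.shape[0])
        c1, c2 = cache_for(codes, ar), cache_for(codes[perm], ar)
        g = DAGStructure.from_edges(2, [(0, 1)])
        assert dag_log_score(g, None, cache=c1) == pytest.approx(
            dag_log_score(g, None, cache=c2)
        )

    def test_replicating_rows_sharpens_the_true_structure(self):
        # planted v-structure x0 -> y <- x1
        rng = np.random.default_rng(3)
        x0, x1 = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        y = (x0 ^ x1).astype(int)
        codes = np.column_stack([x0, x1, y])
        truth = DAGStructure.from_edges(3, [(0, 2), (1, 2)])
        null = DAGStructure(3)
        margins = []
        for reps in (1, 2):
            c = cache_for(np.tile(codes, (reps, 1)), [2, 2, 2])
            margins.append(
                dag_log_score(truth, None, cache=c) - dag_log_score(null, None, cache=c)
            )
        assert margins[1] > margins[0] > 0


class TestScoreDelta:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_delta_equals_full_rescore(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 2, (30, 4))
        c = cache_for(codes, [2, 2, 2, 2])
        g = DAGStructure.from_edges(4, [(0, 1), (2, 1)])
        moves = [("add", 0, 2), ("add", 3, 1), ("delete", 0, 1), ("reverse", 2, 1)]
        move = moves[rng.integers(len(moves))]
        before = dag_log_score(g, None, cache=c)
        delta = score_delta(g, move, cache=c)
        g2 = g.copy()
        g2.apply_move(move)
        after = dag_log_score(g2, None, cache=c)
        assert delta == pytest.approx(after - before, abs=1e-10)

    def test_add_then_delete_cancels(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, (20, 3))
        c = cache_for(codes, [3, 3, 3])
        g = DAGStructure(3)
        d1 = score_delta(g, ("add", 0, 1), cache=c)
        g.apply_move(("add", 0, 1))
        d2 = score_delta(g, ("delete", 0, 1), cache=c)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)

    def test_cache_consistency_with_recomputation(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 2, (40, 3))
        cached = cache_for(codes, [2, 2, 2])
        g = DAGStructure.from_edges(3, [(0, 1), (1, 2)])
        first = dag_log_score(g, None, cache=cached)
        again = dag_log_score(g, None, cache=cached)  # all hits
        fresh = dag_log_score(g, None, cache=cache_for(codes, [2, 2, 2]))
        assert abs(first - again) < 1e-10
        assert abs(first - fresh) < 1e-10


def test_module_level_wrappers_agree():
    rng = np.random.default_rng(4)
    codes = rng.integers(0, 2, (25, 2))
    data = (codes, [2, 2])
    g = DAGStructure.from_edges(2, [(0, 1)])
    assert family_log_marginal(1, (0,), data) + family_log_marginal(0, (), data) == \
        pytest.approx(dag_log_score(g, data))
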