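import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnbmla.aggregation import (
    MBSTable,
    ap_approximation,
    estimate_feature_posterior,
    k_mbs_aggregate,
    mbs_posterior_table,
    multitarget_report,
    peakness_curve,
    relevance_call,
    relevance_report,
    report_tables,
)
from bnbmla.features import markov_blanket
from bnbmla.mcmc import MCMCConfig, mc3_run
from bnbmla.scoring import ScoreConfig
from helpers import make_dataset


class TestFeaturePosterior:
    def test_constant_indicator_gives_certainty(self, small_stream):
        fp = estimate_feature_posterior(small_stream, lambda g: True, "always")
        assert fp.estimate == 1.0
        assert fp.mc_standard_error == 0.0

    def test_no_data_edge_posterior_analytic(self):
        data = (np.zeros((0, 2), dtype=int), [2, 2])
        cfg = MCMCConfig(burn_in=2000, n_steps=50_000, n_chains=1,
                         feature_eval_interval=1, seed=2)
        s = mc3_run(data, ScoreConfig(), cfg)
        fp = estimate_feature_posterior(s, lambda g: g.n_edges > 0, "edge")
        assert fp.estimate == pytest.approx(2 / 3, abs=0.02)


class TestMBSTable:
    def test_probabilities_sum_to_one(self, small_stream):
        table = mbs_posterior_table(small_stream, small_stream.var_names.index("y"))
        assert table.total_mass == pytest.approx(1.0)

    def test_identical_structure_stream_is_a_point_mass(self, small_stream):
        # restrict to the single most frequent structure by reusing its id
        from bnbmla.mcmc import StructureSampleStream

        top = int(np.argmax(small_stream.weights()))
        point = StructureSampleStream(
            n_vars=small_stream.n_vars,
            var_names=small_stream.var_names,
            packed=[small_stream.packed[top]],
            sample_ids=np.zeros(10, dtype=np.int32),
            accept_rates=[0.0],
        )
        table = mbs_posterior_table(point, small_stream.var_names.index("y"))
        assert len(table.probs) == 1
        assert next(iter(table.probs.values())) == pytest.approx(1.0)


class TestKMBS:
    def make_table(self):
        return MBSTable(
            (9,),
            {frozenset({0, 1}): 0.6, frozenset({0}): 0.3, frozenset({1, 2}): 0.1},
        )

    def test_singleton_aggregation_arithmetic(self):
        k1 = k_mbs_aggregate(self.make_table(), 1)
        assert k1.probs[frozenset({0})] == pytest.approx(0.9)
        assert k1.probs[frozenset({1})] == pytest.approx(0.7)
        assert k1.probs[frozenset({2})] == pytest.approx(0.1)

    def test_pair_aggregation_arithmetic(self):
        k2 = k_mbs_aggregate(self.make_table(), 2)
        assert k2.probs[frozenset({0, 1})] == pytest.approx(0.6)
        assert k2.probs[frozenset({1, 2})] == pytest.approx(0.1)
        assert len(k2.probs) == 2

    def test_k1_equals_direct_membership_frequency(self, small_stream):
        y = small_stream.var_names.index("y")
        table = mbs_posterior_table(small_stream, y)
        k1 = k_mbs_aggregate(table, 1)
        w = small_stream.weights()
        for x in range(small_stream.n_vars):
            if x == y:
                continue
            member = np.array(
                [x in markov_blanket(g, y) for g, _ in small_stream.structures()],
                dtype=float,
            )
            direct = float(member @ w)
            assert k1.probs.get(frozenset({x}), 0.0) == pytest.approx(direct)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_subset_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        sets = [frozenset(np.flatnonzero(rng.random(5) < 0.5).tolist())
                for _ in range(6)]
        raw = rng.random(len(sets))
        probs = {}
        for s, p in zip(sets, raw / raw.sum()):
            probs[s] = probs.get(s, 0.0) + p
        table = MBSTable((9,), probs)
        k1 = k_mbs_aggregate(table, 1)
        k2 = k_mbs_aggregate(table, 2)
        for pair, p2 in k2.probs.items():
            for x in pair:
                assert k1.probs[frozenset({x})] >= p2 - 1e-12


class TestAP:
    @pytest.mark.parametrize(
        "posteriors,expected",
        [
            ((0.09, 0.04, 0.05, 0.61), 0.68),
            ((0.31, 0.47, 0.37, 0.43), 0.87),
        ],
    )
    def test_published_rows(self, posteriors, expected):
        assert round(ap_approximation(posteriors), 2) == expected

    def test_single_target_identity(self):
        assert ap_approximation([0.37]) == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ap_approximation([1.2])


class TestRelevanceCall:
    @pytest.mark.parametrize("p,expected", [(0.5, True), (0.49, False), (1.0, True)])
    def test_threshold_is_inclusive(self, p, expected):
        assert relevance_call(p) is expected


class TestPeakness:
    def test_point_mass_gives_single_rank(self):
        table = MBSTable((0,), {frozenset({1}): 1.0})
        curve = peakness_curve(table)
        assert curve.shape == (1, 2)
        assert curve[0, 1] == pytest.approx(1.0)

    def test_curve_is_non_increasing(self, small_stream):
        y = small_stream.var_names.index("y")
        curve = peakness_curve(mbs_posterior_table(small_stream, y))
        assert (np.diff(curve[:, 1]) <= 1e-12).all()

    def test_larger_sample_concentrates_the_posterior(self):
        def run(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, n)
            y = (x ^ (rng.random(n) < 0.1)).astype(int)
            z = rng.integers(0, 2, n)
            ds = make_dataset({"x": x, "z": z, "y": y}, targets=("y",))
            cfg = MCMCConfig(burn_in=2000, n_steps=30_000, n_chains=2,
                             feature_eval_interval=1, seed=seed)
            s = mc3_run(ds, ScoreConfig(), cfg)
            return peakness_curve(mbs_posterior_table(s, ds.index("y")))

        small, large = run(60, 21), run(1200, 22)
        assert large[0, 1] > small[0, 1]


class TestReports:
    def test_single_target_report_identities(self, small_stream):
        rep = relevance_report(small_stream, "y")
        assert ((rep["strong"] - (rep["direct"] + rep["interaction"])).abs()
                < 1e-9).all()
        assert (rep["associated"] >= rep["direct"] - 1e-12).all()
        assert ((rep >= -1e-12) & (rep <= 1 + 1e-12)).all().all()

    def test_multitarget_report_identities(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.integers(0, 3, n)
        y1 = (rng.random(n) < 0.3 + 0.2 * (x > 0)).astype(int)
        y2 = (y1 ^ (rng.random(n) < 0.3)).astype(int)
        ds = make_dataset({"x": x, "y1": y1, "y2": y2}, targets=("y1", "y2"))
        cfg = MCMCConfig(burn_in=2000, n_steps=30_000, n_chains=2,
                         feature_eval_interval=1, seed=8)
        s = mc3_run(ds, ScoreConfig(), cfg)
        rep = multitarget_report(s, ["y1", "y2"])
        row = rep.loc["x"]
        # only[y] <= exist[y]; mt >= each exist; mt <= sum of exists
        for t in ("y1", "y2"):
            assert row[f"only_{t}"] <= row[f"exist_{t}"] + 1e-12
            assert row["mt"] >= row[f"exist_{t}"] - 1e-12
        assert row["mt"] <= row["exist_y1"] + row["exist_y2"] + 1e-12
        tables = report_tables(s, ["y1", "y2"])
        assert set(tables) == {"relevance_y1", "relevance_y2", "multi_target"}

    def test_unknown_target_rejected(self, small_stream):
        with pytest.raises(KeyError):
            report_tables(small_stream, ["nope"])
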