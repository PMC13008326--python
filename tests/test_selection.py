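"""Training sets, forest rankings and round-robin feature selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from angiotop import (DomainConfig, SimulatorSettings, build_training_set,
                      default_prior, rank_features, select_top_features,
                      summarize_selection)
from angiotop.selection import FeatureRanking, Selection


def tiny_training(model="ac", n=8, seed=3):
    config = DomainConfig(lattice_resolution=17, n_initial_tips=3,
                          n_timesteps=40)
    return build_training_set(model, default_prior(model), n, config, seed,
                              SimulatorSettings(max_tips=16))


class TestBuildTrainingSet:
    def test_reproducible(self):
        t1, t2 = tiny_training(n=5, seed=9), tiny_training(n=5, seed=9)
        pd.testing.assert_frame_equal(t1.features, t2.features)
        pd.testing.assert_frame_equal(t1.thetas, t2.thetas)

    def test_thetas_inside_prior_and_uniform(self):
        prior = default_prior("ac")
        rng = np.random.default_rng(0)
        draws = prior.rvs(2000, rng)
        assert np.all(draws >= prior.lower) and np.all(draws <= prior.upper)
        for k in range(4):
            u = (draws[:, k] - prior.lower[k]) / (prior.upper[k] - prior.lower[k])
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_row_alignment(self):
        t = tiny_training(n=6)
        assert t.n == len(t.features) == len(t.thetas)


def planted_frame(rng, n=200, n_noise=30, slope=3.0, noise=0.3):
    X = pd.DataFrame(rng.random((n, n_noise + 1)),
                     columns=[f"f{i:02d}" for i in range(n_noise + 1)])
    y = slope * X["f07"].to_numpy() + noise * rng.standard_normal(n)
    return X, y


class TestRankFeatures:
    def test_planted_feature_ranks_first(self):
        rng = np.random.default_rng(21)
        hits = 0
        for rep in range(10):
            X, y = planted_frame(rng)
            r = rank_features(X, y, n_trees=100, seed=rep)
            hits += r.ordered_features[0] == "f07"
        assert hits >= 9

    def test_importances_normalized_sorted(self):
        rng = np.random.default_rng(22)
        X, y = planted_frame(rng)
        r = rank_features(X, y, n_trees=100, seed=0)
        imp = r.table["importance"].to_numpy()
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(1.0)
        assert np.all(np.diff(imp) <= 1e-12)

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(23)
        X, _ = planted_frame(rng)
        with pytest.raises(ValueError, match="constant"):
            rank_features(X, np.ones(len(X)))

    def test_too_few_records_rejected(self):
        rng = np.random.default_rng(24)
        X, y = planted_frame(rng, n=30)
        with pytest.raises(ValueError, match="50"):
            rank_features(X, y)


def fake_ranking(param, names):
    table = pd.DataFrame({"feature": names,
                          "importance": np.linspace(1, 0, len(names))})
    return FeatureRanking(model_id="ac", parameter=param, table=table)


class TestSelectTopFeatures:
    def test_disjoint_rankings_take_equal_shares(self):
        rankings = {p: fake_ranking(p, [f"{p}_{i}" for i in range(40)])
                    for p in ("a", "b", "c", "d")}
        sel = select_top_features(rankings, ns=100)
        assert len(sel.selected) == len(set(sel.selected)) == 100
        for p in rankings:
            assert len(sel.per_parameter[p]) == 25
            assert sel.per_parameter[p] == [f"{p}_{i}" for i in range(25)]

    def test_identical_rankings_reduce_to_common_top(self):
        names = [f"f{i:03d}" for i in range(150)]
        rankings = {p: fake_ranking(p, names) for p in ("a", "b", "c", "d")}
        sel = select_top_features(rankings, ns=100)
        assert sel.selected == names[:100]

    def test_partial_overlap_matches_bruteforce_roundrobin(self):
        rng = np.random.default_rng(31)
        pool = [f"g{i:03d}" for i in range(60)]
        rankings = {}
        for p in ("a", "b", "c", "d"):
            order = list(rng.permutation(pool))
            rankings[p] = fake_ranking(p, order)
        ns = 40
        sel = select_top_features(rankings, ns=ns)

        # independent brute-force round-robin enumeration
        cursors = {p: 0 for p in rankings}
        expected, seen = [], set()
        while len(expected) < ns:
            for p in rankings:
                if len(expected) >= ns:
                    break
                lst = rankings[p].ordered_features
                while cursors[p] < len(lst) and lst[cursors[p]] in seen:
                    cursors[p] += 1
                if cursors[p] < len(lst):
                    expected.append(lst[cursors[p]])
                    seen.add(lst[cursors[p]])
                    cursors[p] += 1
        assert sel.selected == expected

    def test_not_enough_features_rejected(self):
        rankings = {p: fake_ranking(p, ["x", "y", "z"])
                    for p in ("a", "b", "c", "d")}
        with pytest.raises(ValueError, match="fewer"):
            select_top_features(rankings, ns=100)

    def test_indivisible_ns_rejected(self):
        rankings = {p: fake_ranking(p, ["x"]) for p in ("a", "b", "c")}
        with pytest.raises(ValueError, match="divisible"):
            select_top_features(rankings, ns=100)

    def test_deterministic(self):
        rng = np.random.default_rng(33)
        pool = [f"g{i:03d}" for i in range(80)]
        rankings = {p: fake_ranking(p, list(rng.permutation(pool)))
                    for p in ("a", "b", "c", "d")}
        s1 = select_top_features(rankings, ns=40)
        s2 = select_top_features(rankings, ns=40)
        assert s1.selected == s2.selected


class TestSummarizeSelection:
    def test_counts_partition_selection(self):
        sel = Selection(model_id="ac",
                        selected=["sx_mean", "sy_p90", "t_v_ext1_im00",
                                  "t_h_ord0_life_mean"],
                        per_parameter={"chi": ["sx_mean", "t_v_ext1_im00"],
                                       "rho": ["sy_p90", "t_h_ord0_life_mean"]})
        table = summarize_selection(sel)
        assert table["count"].sum() == 4
        spatial_x = table.query(
            "parameter == 'chi' and type == 'spatial' and direction == 'x'")
        assert spatial_x["count"].iloc[0] == 1

    def test_all_spatial_has_zero_topological(self):
        sel = Selection(model_id="ac", selected=["sx_mean", "sy_std"],
                        per_parameter={"chi": ["sx_mean", "sy_std"]})
        table = summarize_selection(sel)
        assert table.query("type == 'topological'")["count"].sum() == 0
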