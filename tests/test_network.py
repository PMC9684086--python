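import numpy as np
import pandas as pd
import pytest

import networkx as nx

from crowdome.io import AbundanceTable, MetadataTable
from crowdome.network import (
    ConsensusConfig,
    build_network,
    consensus_edges,
    export_network,
    lasso_edge_scores,
    preprocess,
    replicate_edges,
    rf_edge_scores,
    spearman_edges,
)
from crowdome.simulate import generate_cohort, planted_demo_config


@pytest.fixture
def config():
    return ConsensusConfig(rf_trees=50, n_boot=20, k_folds=3)


def _meta(df, kinds):
    return MetadataTable(df, kinds)


class TestPreprocess:
    def _abund(self, n):
        rng = np.random.default_rng(0)
        data = rng.dirichlet(np.ones(5), size=n)
        return AbundanceTable(
            pd.DataFrame(data, index=[f"s{i}" for i in range(n)],
                         columns=[f"T{j}" for j in range(5)])
        )

    def test_high_missingness_sample_dropped(self, config):
        idx = [f"s{i}" for i in range(10)]
        df = pd.DataFrame(
            {"a": [1.0] * 10, "b": [2.0] * 5 + [np.nan] * 5,
             "c": [3.0] * 9 + [np.nan], "d": [1.0, 2.0] * 5,
             "e": [0.0, 1.0] * 5},
            index=idx,
        )
        df.iloc[0, 1:] = np.nan  # s0: 4/5 missing
        kinds = dict.fromkeys("abcde", "continuous")
        coded, _, log = preprocess(_meta(df, kinds), self._abund(10), config)
        assert "s0" not in coded.index
        assert log["samples_dropped_missing"] == ["s0"]

    def test_constant_column_dropped(self, config):
        idx = [f"s{i}" for i in range(10)]
        df = pd.DataFrame({"const": [5.0] * 10, "var": np.arange(10.0)}, index=idx)
        coded, _, log = preprocess(
            _meta(df, {"const": "continuous", "var": "continuous"}),
            self._abund(10), config,
        )
        assert "const" not in coded.columns
        assert "const" in log["near_zero_variance_dropped"]

    def test_outlier_masked_then_median_imputed(self, config):
        n = 100
        idx = [f"s{i}" for i in range(n)]
        vals = np.arange(n, dtype=float)
        vals[0] = 1e6  # single extreme outlier
        df = pd.DataFrame({"x": vals, "y": np.arange(n, dtype=float) % 7}, index=idx)
        coded, _, log = preprocess(
            _meta(df, {"x": "continuous", "y": "continuous"}),
            self._abund(n), config,
        )
        clean = np.sort(vals[1:])
        lo, hi = np.percentile(vals, [2.5, 97.5])
        inside = vals[(vals >= lo) & (vals <= hi)]
        assert coded.loc["s0", "x"] == pytest.approx(np.median(inside))
        assert log["outliers_masked"] >= 1

    def test_nominal_dummy_coding(self, config, mixed_metadata):
        rng = np.random.default_rng(1)
        abund = AbundanceTable(
            pd.DataFrame(rng.dirichlet(np.ones(4), size=4),
                         index=mixed_metadata.sample_ids, columns=list("WXYZ"))
        )
        coded, _, _ = preprocess(mixed_metadata, abund, config)
        assert {"region=north", "region=south", "region=east"} <= set(coded.columns)

    def test_idempotent_on_own_output(self):
        # rank-based outlier masking re-trims tails on every pass, so
        # idempotence is checked with the masking stage disabled
        config = ConsensusConfig(central_interval=1.0, k_folds=3)
        n = 50
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.integers(0, 3, n).astype(float)},
            index=idx,
        )
        df.iloc[3, 0] = np.nan
        meta = _meta(df, {"a": "continuous", "b": "ordinal"})
        abund = self._abund(n)
        coded1, trans1, _ = preprocess(meta, abund, config)
        meta2 = _meta(coded1, dict.fromkeys(coded1.columns, "continuous"))
        abund2 = AbundanceTable(
            pd.DataFrame(np.sin(trans1.to_numpy()) ** 2, index=trans1.index,
                         columns=trans1.columns)
        )
        coded2, trans2, _ = preprocess(meta2, abund2, config)
        pd.testing.assert_frame_equal(coded1, coded2, check_like=True)
        np.testing.assert_allclose(trans1.to_numpy(), trans2.to_numpy(), atol=1e-12)

    def test_all_samples_dropped_rejected(self, config):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [np.nan, np.nan]},
                          index=["s0", "s1"])
        with pytest.raises(ValueError):
            preprocess(_meta(df, {"a": "continuous", "b": "continuous"}),
                       self._abund(2), config)


class TestSpearmanEdges:
    def test_self_correlation(self, rng):
        A = pd.DataFrame({"x": rng.normal(size=30)})
        out = spearman_edges(A, A.rename(columns={"x": "y"}))
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-10

    def test_perfect_anticorrelation(self):
        A = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        B = pd.DataFrame({"y": [4.0, 3.0, 2.0, 1.0]})
        assert spearman_edges(A, B)["rho"].iloc[0] == pytest.approx(-1.0)

    def test_too_few_pairs_na(self):
        A = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan, 5.0]})
        B = pd.DataFrame({"y": [1.0, np.nan, 3.0, 4.0, 5.0]})
        out = spearman_edges(A, B)
        assert np.isnan(out["rho"].iloc[0])

    def test_null_p_uniform(self, rng):
        A = pd.DataFrame(rng.normal(size=(100, 8)), columns=[f"a{i}" for i in range(8)])
        B = pd.DataFrame(rng.normal(size=(100, 8)), columns=[f"b{i}" for i in range(8)])
        out = spearman_edges(A, B)
        from scipy.stats import kstest

        assert kstest(out["p"], "uniform").pvalue > 0.01
        assert (out["q"] < 0.1).sum() == 0


class TestRfEdgeScores:
    def test_informative_feature_top(self, config):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(200, 10)),
                             columns=[f"f{i}" for i in range(10)])
            y = X["f4"] * 2 + r.normal(scale=0.5, size=200)
            scores = rf_edge_scores(X, y, config, seed=seed)
            hits += scores.idxmax() == "f4"
        assert hits >= 4

    def test_constant_feature_importance_zero(self, config, rng):
        X = pd.DataFrame({"c": np.ones(60), "v": rng.normal(size=60)})
        y = rng.normal(size=60)
        assert rf_edge_scores(X, y, config, seed=0)["c"] == 0.0

    def test_nonnegative(self, config, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)))
        assert (rf_edge_scores(X, rng.normal(size=50), config, seed=0) >= 0).all()


class TestLassoEdgeScores:
    def test_constructed_signal(self, config):
        r = np.random.default_rng(0)
        X = pd.DataFrame(r.normal(size=(200, 8)), columns=[f"f{i}" for i in range(8)])
        y = 2 * X["f2"] + r.normal(scale=0.1, size=200)
        out = lasso_edge_scores(X, y, config, seed=0)
        assert out["score"].idxmax() == "f2"
        assert out.loc["f2", "freq"] == 1.0

    def test_pure_noise_mostly_zero(self, config):
        # under the null the median-aggregated score dies for most features
        zeros = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(100, 10)))
            out = lasso_edge_scores(X, r.normal(size=100), config, seed=seed)
            zeros += (out["score_median"].median() == 0.0)
        assert zeros >= 3

    def test_single_bootstrap_identity(self, rng):
        config = ConsensusConfig(n_boot=1, k_folds=3)
        X = pd.DataFrame(rng.normal(size=(80, 5)), columns=[f"f{i}" for i in range(5)])
        y = X["f0"] + rng.normal(scale=0.3, size=80)
        out = lasso_edge_scores(X, y, config, seed=0)
        # with one bootstrap the score is that single fit's |coefficient|
        assert ((out["freq"] == 0) | (out["freq"] == 1)).all()
        assert (out.loc[out["freq"] == 0, "score"] == 0).all()


class TestConsensusEdges:
    @staticmethod
    def _grid(ps, rhos, preds=None):
        preds = preds or [f"p{i}" for i in range(len(ps))]
        df = pd.DataFrame({"target": "t", "predictor": preds, "rho": rhos, "p": ps})
        from crowdome.stats import bh_adjust

        df["q"] = bh_adjust(df["p"].to_numpy())
        return df

    def test_unanimous_ordering_keeps_top_k(self):
        n = 10
        rhos = np.linspace(0.9, 0.05, n)
        sp = self._grid([1e-6] * n, rhos)
        scores = pd.Series(rhos, index=sp["predictor"])
        edges = consensus_edges(sp, {"t": scores}, {"t": scores},
                               ConsensusConfig(top_k=5))
        assert list(edges["predictor"]) == [f"p{i}" for i in range(5)]

    def test_q_gate_excludes(self):
        sp = self._grid([0.9, 1e-6], [0.8, 0.5])
        scores = pd.Series([0.8, 0.5], index=["p0", "p1"])
        edges = consensus_edges(sp, {"t": scores}, {"t": scores}, ConsensusConfig())
        assert "p0" not in set(edges["predictor"])
        assert "p1" in set(edges["predictor"])

    def test_at_most_top_k_per_target(self, rng):
        n = 12
        sp = self._grid(rng.random(n) * 1e-4, rng.uniform(-1, 1, n))
        scores = pd.Series(rng.random(n), index=sp["predictor"])
        edges = consensus_edges(sp, {"t": scores}, {"t": scores},
                               ConsensusConfig(top_k=5))
        assert len(edges) <= 5

    def test_monotone_score_transform_invariance(self, rng):
        n = 8
        sp = self._grid(rng.random(n) * 1e-4, rng.uniform(0.2, 0.9, n))
        scores = pd.Series(rng.random(n) + 0.1, index=sp["predictor"])
        e1 = consensus_edges(sp, {"t": scores}, {"t": scores}, ConsensusConfig())
        e2 = consensus_edges(sp, {"t": scores**3}, {"t": np.log(scores)},
                             ConsensusConfig())
        assert set(e1["predictor"]) == set(e2["predictor"])

    def test_sign_from_rho(self):
        sp = self._grid([1e-6, 1e-6], [0.7, -0.7])
        scores = pd.Series([0.7, 0.7], index=["p0", "p1"])
        edges = consensus_edges(sp, {"t": scores}, {"t": scores}, ConsensusConfig())
        signs = dict(zip(edges["predictor"], edges["sign"]))
        assert signs == {"p0": "+", "p1": "-"}


class TestReplication:
    @staticmethod
    def _edges(pairs, p, sign="+"):
        return pd.DataFrame(
            {
                "target": [t for t, _ in pairs],
                "predictor": [q for _, q in pairs],
                "avg_rank": 1.0,
                "rho": 0.5 if sign == "+" else -0.5,
                "p": p,
                "q": p,
                "sign": sign,
            }
        )

    def test_combined_p_closed_form(self):
        e1 = self._edges([("t", "x")], 0.01)
        e2 = self._edges([("t", "x")], 0.01)
        rep = replicate_edges(e1, e2, ConsensusConfig())
        assert rep["p_combined"].iloc[0] == pytest.approx(0.0002)
        assert bool(rep["replicated"].iloc[0])

    def test_opposite_signs_not_replicated(self):
        e1 = self._edges([("t", "x")], 0.01, "+")
        e2 = self._edges([("t", "x")], 0.01, "-")
        rep = replicate_edges(e1, e2, ConsensusConfig())
        assert not bool(rep["replicated"].iloc[0])

    def test_empty_intersection(self):
        e1 = self._edges([("t", "x")], 0.01)
        e2 = self._edges([("t", "y")], 0.01)
        assert replicate_edges(e1, e2, ConsensusConfig()).empty

    def test_planted_pair_pipeline(self):
        from crowdome.simulate import generate_replicate_cohort

        cfg = planted_demo_config(n_samples=200, n_factors=6, n_taxa=10,
                                  n_effects=3, seed=31)
        config = ConsensusConfig(rf_trees=30, n_boot=10, k_folds=3)
        abund1, meta1, truth = generate_cohort(cfg)
        abund2, meta2 = generate_replicate_cohort(cfg, truth, seed2=32)
        tables = []
        for abund, meta in ((abund1, meta1), (abund2, meta2)):
            coded, trans, _ = preprocess(meta, abund, config)
            edges, _ = build_network(coded, trans, config, seed=1)
            tables.append(edges)
        rep = replicate_edges(tables[0], tables[1], config)
        planted = {(f, t) for f, t, _ in truth.edges}
        in_both = {(r.target, r.predictor) for r in tables[0].itertuples()} & {
            (r.target, r.predictor) for r in tables[1].itertuples()
        }
        replicated = {
            (r.target, r.predictor) for r in rep.itertuples() if r.replicated
        }
        # every planted edge surviving both cohorts' gates must replicate
        assert planted & in_both <= replicated


class TestExportNetwork:
    def test_graphml_parseable(self, tmp_path):
        edges = pd.DataFrame(
            {"target": ["t"], "predictor": ["p"], "avg_rank": [1.0],
             "rho": [0.5], "p": [0.001], "q": [0.01], "sign": ["+"]}
        )
        path = tmp_path / "net.graphml"
        export_network(edges, graphml_path=path)
        G = nx.read_graphml(path)
        assert G.number_of_edges() == 1
        assert G.edges["t", "p"]["color"] == "cyan"

    def test_large_network_written_quickly(self, tmp_path, rng):
        import time

        n = 13_425
        edges = pd.DataFrame(
            {
                "target": [f"t{i % 150}" for i in range(n)],
                "predictor": [f"p{i}" for i in range(n)],
                "avg_rank": rng.random(n),
                "rho": rng.uniform(-1, 1, n),
                "p": rng.random(n) * 0.01,
                "q": rng.random(n) * 0.1,
            }
        )
        edges["sign"] = np.where(edges["rho"] >= 0, "+", "-")
        t0 = time.monotonic()
        export_network(edges, graphml_path=tmp_path / "big.graphml",
                       tsv_path=tmp_path / "big.tsv")
        assert time.monotonic() - t0 < 10.0

    def test_tsv_round_trip(self, tmp_path, rng):
        edges = pd.DataFrame(
            {
                "target": [f"t{i}" for i in range(6)],
                "predictor": [f"p{i}" for i in range(6)],
                "avg_rank": rng.random(6),
                "rho": rng.uniform(-1, 1, 6),
                "p": rng.random(6) * 0.01,
                "q": rng.random(6) * 0.1,
            }
        )
        edges["sign"] = np.where(edges["rho"] >= 0, "+", "-")
        path = tmp_path / "edges.tsv"
        export_network(edges, tsv_path=path)
        back = pd.read_csv(path, sep="\t")
        assert set(zip(back["target"], back["predictor"])) == set(
            zip(edges["target"], edges["predictor"])
        )
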