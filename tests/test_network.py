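"""Spearman coexpression network, permutation null, q-values, Leiden clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import expr_matrix, expressed_config, flat_design
from ipmndsp import (
    CoexpressionNetwork,
    ValidationError,
    build_network,
    filter_clusters,
    leiden_communities,
    permutation_null,
    simulate_dataset,
    spearman_matrix,
)
from ipmndsp.network import annotate_overlays, edge_qvalues, empirical_pvalues, storey_qvalues
from ipmndsp.normalize import normalize_pipeline
from ipmndsp.qc import run_qc


def normalized_log_dataset(seed, n_genes, modules=(), n_aois=60):
    config = expressed_config(
        subtype_design=flat_design(n_aois // 6, 6),
        n_genes=n_genes,
        probes_per_gene=1,
        planted_modules=list(modules),
        seed=seed,
    )
    pcm, ann, truth = simulate_dataset(config)
    expr, pcm_f, _, _ = run_qc(pcm)
    return normalize_pipeline(expr, pcm_f)["log"], truth


class TestSpearman:
    def test_hand_examples(self):
        e = expr_matrix([[1, 2, 3], [2, 4, 9], [3, 2, 1]])
        rho = spearman_matrix(e)
        assert rho.iloc[0, 1] == pytest.approx(1.0)  # same rank order
        assert rho.iloc[0, 2] == pytest.approx(-1.0)  # reversal
        e2 = expr_matrix([[1, 2, 3, 4], [2, 1, 4, 3]])
        assert spearman_matrix(e2).iloc[0, 1] == pytest.approx(0.6)

    def test_constant_gene_is_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            rho = spearman_matrix(expr_matrix([[1, 2, 3], [5, 5, 5]]))
        assert np.isnan(rho.iloc[0, 1]) and rho.iloc[1, 1] == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 15))
        rho = spearman_matrix(expr_matrix(x))
        expected = stats.spearmanr(x.T).statistic
        np.testing.assert_allclose(rho.values, expected, atol=1e-12)


class TestPermutationNull:
    def test_deterministic_under_seed(self):
        e = expr_matrix(np.random.default_rng(0).normal(size=(30, 20)))
        a = permutation_null(e, n_perm=1000, seed=5, max_null_size=50_000)
        b = permutation_null(e, n_perm=1000, seed=5, max_null_size=50_000)
        np.testing.assert_array_equal(a, b)

    def test_minimum_permutations_enforced(self):
        e = expr_matrix(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ValidationError):
            permutation_null(e, n_perm=500)

    def test_tail_matches_analytic_spearman_null(self):
        # for independent Gaussian data at n=40, |rho| at the 95th pct follows
        # the t-approximation t = rho * sqrt((n-2)/(1-rho^2)) with df=n-2
        n = 40
        e = expr_matrix(np.random.default_rng(3).normal(size=(60, n)))
        null = permutation_null(e, n_perm=2000, seed=1, max_null_size=400_000)
        observed = np.quantile(null, 0.95)
        t_crit = stats.t.ppf(0.975, n - 2)
        analytic = t_crit / np.sqrt(n - 2 + t_crit**2)
        assert observed == pytest.approx(analytic, abs=0.02)


class TestQvalues:
    def test_monotone_in_p_and_smallest_for_largest_rho(self):
        rng = np.random.default_rng(4)
        e = expr_matrix(rng.normal(size=(25, 30)))
        rho = spearman_matrix(e)
        null = permutation_null(e, n_perm=1000, seed=0, max_null_size=100_000)
        pairs = edge_qvalues(rho, null)
        top = pairs.loc[pairs["rho"].abs().idxmax()]
        assert top["qvalue"] == pairs["qvalue"].min()
        srt = pairs.sort_values("pvalue")
        assert (np.diff(srt["qvalue"]) >= -1e-12).all()

    def test_storey_qvalues_bounded_and_monotone(self):
        p = np.random.default_rng(1).uniform(size=400)
        q = storey_qvalues(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_weak_correlations_get_q_near_one(self):
        rng = np.random.default_rng(6)
        e = expr_matrix(rng.normal(size=(40, 50)))
        rho = spearman_matrix(e)
        null = permutation_null(e, n_perm=1000, seed=2, max_null_size=100_000)
        pairs = edge_qvalues(rho, null)
        weak = pairs[pairs["rho"].abs() < 0.05]
        assert (weak["qvalue"] > 0.5).all()


class TestBuildNetwork:
    def test_edge_thresholds_and_weights(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=30)
        x = np.vstack([z + rng.normal(0, 0.1, 30) for _ in range(3)] + [rng.normal(size=(20, 30))])
        net = build_network(expr_matrix(x), n_perm=1000, seed=0, max_null_size=100_000)
        assert net.n_edges >= 3  # the three correlated genes interconnect
        assert (net.edges["rho"].abs() >= 0.7).all()
        assert (net.edges["qvalue"] < 0.01).all()
        np.testing.assert_allclose(net.edges["weight"], net.edges["rho"] ** 4)
        assert set(net.edges["gene_a"]) | set(net.edges["gene_b"]) == set(net.nodes)

    def test_empty_network_warning(self):
        rng = np.random.default_rng(12)
        with pytest.warns(UserWarning, match="no gene pairs"):
            net = build_network(expr_matrix(rng.normal(size=(10, 40))), n_perm=1000, seed=0,
                                max_null_size=50_000)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_invariant_to_gene_and_aoi_order(self):
        rng = np.random.default_rng(13)
        z = rng.normal(size=24)
        x = np.vstack([z + rng.normal(0, 0.15, 24) for _ in range(4)] + [rng.normal(size=(12, 24))])
        e = expr_matrix(x)
        net = build_network(e, n_perm=1000, seed=3, max_null_size=50_000)
        shuffled = e.values.iloc[rng.permutation(e.values.shape[0]), rng.permutation(e.values.shape[1])]
        from ipmndsp.containers import GeneExpressionMatrix

        net2 = build_network(GeneExpressionMatrix(shuffled, "log"), n_perm=1000, seed=3,
                             max_null_size=50_000)

        def canon(n):
            return {tuple(sorted(p)) for p in zip(n.edges["gene_a"], n.edges["gene_b"])}

        assert canon(net) == canon(net2)


def clique_network(sizes, labels_prefix="c"):
    rows = []
    nodes = []
    for ci, size in enumerate(sizes):
        members = [f"{labels_prefix}{ci}_{i}" for i in range(size)]
        nodes.extend(members)
        for i in range(size):
            for j in range(i + 1, size):
                rows.append((members[i], members[j], 0.9, 1e-4, 1e-4, 0.9**4))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "pvalue", "qvalue", "weight"])
    return CoexpressionNetwork(edges, pd.Index(nodes, name="gene"))


class TestLeiden:
    def test_disconnected_cliques_give_two_clusters(self):
        net = clique_network([10, 10])
        labels = leiden_communities(net, seed=0)
        assert labels.nunique() == 2
        for ci in range(2):
            members = labels[labels.index.str.startswith(f"c{ci}_")]
            assert members.nunique() == 1

    def test_single_node(self):
        net = CoexpressionNetwork(
            pd.DataFrame(columns=["gene_a", "gene_b", "rho", "pvalue", "qvalue", "weight"]),
            pd.Index(["solo"], name="gene"),
        )
        labels = leiden_communities(net, seed=0)
        assert labels.tolist() == [0]

    def test_planted_partition_recovery(self):
        from sklearn.metrics import rand_score

        rng = np.random.default_rng(21)
        for seed in range(10):
            rows = []
            names = [f"n{i}" for i in range(60)]
            block = np.array([0] * 30 + [1] * 30)
            for i in range(60):
                for j in range(i + 1, 60):
                    p = 0.9 if block[i] == block[j] else 0.02
                    if rng.uniform() < p:
                        rows.append((names[i], names[j], 0.8, 1e-4, 1e-4, 0.8**4))
            edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "pvalue", "qvalue", "weight"])
            net = CoexpressionNetwork(edges, pd.Index(names, name="gene"))
            labels = leiden_communities(net, seed=seed)
            assert rand_score(block, labels.loc[names]) >= 0.95

    def test_same_seed_reproduces_labels(self):
        net = clique_network([8, 12, 6])
        a = leiden_communities(net, seed=7)
        b = leiden_communities(net, seed=7)
        pd.testing.assert_series_equal(a, b)


class TestFilterClusters:
    def test_size_boundary(self):
        labels = pd.Series([0] * 9 + [1] * 10, index=[f"g{i}" for i in range(19)])
        out = filter_clusters(labels, min_size=10)
        assert not out[out["cluster"] == 0]["retained"].any()  # 9 genes: discarded
        assert out[out["cluster"] == 1]["retained"].all()  # 10 genes: retained
        assert set(out.index) == set(labels.index)  # labels kept, only flagged

    def test_all_small_warns(self):
        labels = pd.Series([0, 1, 2])
        with pytest.warns(UserWarning, match="none retained"):
            out = filter_clusters(labels, min_size=10)
        assert not out["retained"].any()


class TestOverlays:
    def test_zscores_fold_changes_and_membership(self):
        from conftest import annotation_frame
        from ipmndsp import GeneSet

        net = clique_network([3])
        x = np.array([[1.0, 1.0, 5.0, 5.0], [2.0, 2.0, 2.0, 2.0], [0.0, 1.0, 8.0, 9.0]])
        e = expr_matrix(x, genes=list(net.nodes), aois=["a0", "a1", "a2", "a3"])
        ann = annotation_frame(
            {"a0": ("PB", "LGD"), "a1": ("PB", "LGD"), "a2": ("PB", "HGD"), "a3": ("PB", "HGD")}
        )
        lfc = pd.Series([4.0, 0.0, 8.0], index=net.nodes)
        out = annotate_overlays(
            net, e, ann, {"HGD": {"grade": "HGD"}}, [GeneSet("EXT", "", (net.nodes[0],))], lfc
        )
        # equal-expression gene in the group mean sits at its z position; a
        # flat overall profile across groups gives z relative to other genes
        z = out.node_attrs["z_HGD"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(out.node_attrs["log2fc_hgd_vs_lgd"], lfc)
        assert out.node_attrs["in_EXT"].tolist() == [True, False, False]

    def test_unknown_group_errors(self):
        from conftest import annotation_frame

        net = clique_network([2])
        e = expr_matrix(np.ones((2, 2)), genes=list(net.nodes), aois=["a0", "a1"])
        ann = annotation_frame({"a0": ("PB", "LGD"), "a1": ("PB", "LGD")})
        with pytest.raises(ValidationError, match="no AOIs"):
            annotate_overlays(net, e, ann, {"HGD": {"grade": "HGD"}})


class TestNullCalibrationSmall:
    def test_independent_genes_produce_no_edges(self):
        empty = 0
        for seed in range(3):
            log, _ = normalized_log_dataset(seed + 50, n_genes=200, n_aois=60)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = build_network(log, n_perm=1000, seed=seed, max_null_size=200_000)
            empty += net.n_edges == 0
        assert empty == 3

    def test_empirical_pvalues_super_uniform(self):
        log, _ = normalized_log_dataset(99, n_genes=200, n_aois=60)
        rho = spearman_matrix(log)
        null = permutation_null(log, n_perm=1000, seed=7, max_null_size=200_000)
        genes = np.arange(len(log.genes))
        pairs_i, pairs_j = genes[:-1:2], genes[1::2]  # disjoint pairs: independent
        obs = np.abs(rho.values[pairs_i, pairs_j])
        ge = null.size - np.searchsorted(null, obs, side="left")
        p = (1.0 + ge) / (1.0 + null.size)
        ks = stats.kstest(p, "uniform", alternative="greater")
        assert ks.pvalue > 0.01
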