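"""Signed adjacency, TOM, module detection, eigengenes, export."""

import numpy as np
import pandas as pd
import pytest

from mirnet import network as net
from mirnet.network import ModuleAssignment


def _expr(mat, genes=None):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=genes, columns=[f"s{j}" for j in range(mat.shape[1])])


class TestGeneSelection:
    def test_robust_range_beats_plain_range(self):
        """(0,0,10,10) has robust range 10; (0,9,9,9) has robust range 0
        despite a plain range of 9."""
        df = _expr([[0, 0, 10, 10], [0, 9, 9, 9]], genes=["spread", "spike"])
        got = net.select_network_genes(
            df, min_cpm=0.001, min_samples=1, top_n=1, name_exclude_prefixes=()
        )
        assert got == ["spread"]

    def test_noncoding_prefixes_excluded(self):
        rng = np.random.default_rng(0)
        df = _expr(rng.normal(5, 2, size=(3, 6)), genes=["MIR200C", "SNORD1", "CDH1"])
        got = net.select_network_genes(df, min_cpm=0.001, min_samples=1, top_n=3)
        assert got == ["CDH1"]

    def test_top_n_covering_everything_is_identity(self):
        rng = np.random.default_rng(1)
        df = _expr(rng.normal(5, 2, size=(10, 6)))
        got = net.select_network_genes(df, min_cpm=0.001, min_samples=1, top_n=10)
        assert got == list(df.index)


class TestAdjacency:
    def test_extreme_correlations(self):
        x = np.arange(6.0)
        df = _expr([x, x, -x])
        a = net.signed_adjacency(df, beta=16)
        assert a.iloc[0, 1] == pytest.approx(1.0)
        assert a.iloc[0, 2] == pytest.approx(0.0, abs=1e-30)

    def test_zero_correlation_gives_two_to_minus_beta(self):
        df = _expr([[1, 1, -1, -1], [1, -1, 1, -1]])
        a = net.signed_adjacency(df, beta=16)
        assert a.iloc[0, 1] == pytest.approx(2.0**-16)

    def test_zero_variance_gene_rejected(self):
        df = _expr([[1, 1, 1, 1], [1, 2, 3, 4]], genes=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            net.signed_adjacency(df)


class TestTom:
    def test_two_genes_tom_equals_adjacency(self):
        a = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]])
        tom = net.tom_similarity(a)
        assert tom.iloc[0, 1] == pytest.approx(0.3)

    def test_complete_graph_gives_unit_tom(self):
        a = pd.DataFrame(np.ones((3, 3)))
        assert np.allclose(net.tom_similarity(a), 1.0)

    def test_bounds_on_random_adjacencies(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.uniform(0, 1, size=(15, 15))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = net.tom_similarity(pd.DataFrame(a)).to_numpy()
            assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
            assert np.allclose(tom, tom.T, atol=1e-12)

    def test_asymmetric_adjacency_rejected(self):
        a = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError):
            net.tom_similarity(a)


def _two_block_diss(n1=40, n2=40, within=0.1, between=0.9):
    n = n1 + n2
    d = np.full((n, n), between)
    d[:n1, :n1] = within
    d[n1:, n1:] = within
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=[f"g{i}" for i in range(n)],
                        columns=[f"g{i}" for i in range(n)])


class TestTreeAndCut:
    def test_two_planted_blocks_recovered_exactly(self):
        diss = _two_block_diss()
        tree = net.average_linkage_tree(diss)
        assign = net.dynamic_cut(tree, diss, min_size=10)
        labels = assign.labels
        assert labels.nunique() == 2
        assert labels.iloc[:40].nunique() == 1
        assert labels.iloc[40:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[40]

    def test_block_below_min_size_dissolved(self):
        diss = _two_block_diss(n1=9, n2=40)
        tree = net.average_linkage_tree(diss)
        assign = net.dynamic_cut(tree, diss, min_size=10)
        assert (assign.labels.iloc[:9] == 0).all()

    def test_uniform_zero_dissimilarity_is_one_module(self):
        d = pd.DataFrame(np.zeros((30, 30)))
        tree = net.average_linkage_tree(d)
        assign = net.dynamic_cut(tree, d, min_size=10)
        assert assign.labels.nunique() == 1

    def test_nan_dissimilarity_rejected(self):
        d = _two_block_diss()
        tree = net.average_linkage_tree(d)
        d.iloc[0, 1] = np.nan
        d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError):
            net.dynamic_cut(tree, d)

    def test_deep_split_not_implemented_beyond_zero(self):
        d = _two_block_diss()
        tree = net.average_linkage_tree(d)
        with pytest.raises(NotImplementedError):
            net.dynamic_cut(tree, d, deep_split=2)


def _module_expr(seed=3):
    """Two modules driven by orthogonal sample profiles."""
    rng = np.random.default_rng(seed)
    n_s = 12
    u1 = np.sin(np.linspace(0, 2 * np.pi, n_s))
    u2 = np.cos(np.linspace(0, 2 * np.pi, n_s))
    rows, labels = [], []
    for i in range(30):
        rows.append(3 * u1 + rng.normal(0, 0.1, n_s))
        labels.append(1)
    for i in range(25):
        rows.append(3 * u2 + rng.normal(0, 0.1, n_s))
        labels.append(2)
    expr = _expr(rows)
    return expr, pd.Series(labels, index=expr.index)


class TestEigengenes:
    def test_identical_genes_fully_explained(self):
        profile = np.array([1.0, 2, 3, 4, 2, 1])
        expr = _expr(np.tile(profile, (5, 1)))
        labels = pd.Series(1, index=expr.index)
        es = net.eigengenes(expr, labels)
        assert es.variance_explained[1] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        me = es.me.loc[1].to_numpy()
        assert np.allclose(me / np.linalg.norm(me), z / np.linalg.norm(z))

    def test_orientation_follows_the_module_mean(self):
        expr, labels = _module_expr()
        es = net.eigengenes(expr, labels)
        for mod in (1, 2):
            mean_profile = expr.loc[labels == mod].mean(axis=0)
            r = np.corrcoef(es.me.loc[mod], mean_profile)[0, 1]
            assert r >= 0

    def test_flipping_every_gene_flips_the_oriented_eigengene(self):
        expr, labels = _module_expr(seed=4)
        es1 = net.eigengenes(expr, labels)
        es2 = net.eigengenes(-expr, labels)
        for mod in (1, 2):
            r = np.corrcoef(es1.me.loc[mod], es2.me.loc[mod])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-10)

    def test_orthogonal_drivers_give_uncorrelated_eigengenes(self):
        expr, labels = _module_expr(seed=5)
        es = net.eigengenes(expr, labels)
        r = np.corrcoef(es.me.loc[1], es.me.loc[2])[0, 1]
        assert abs(r) < 0.1


class TestMergeAndDiscard:
    def test_near_duplicate_modules_merge(self):
        expr, labels = _module_expr(seed=6)
        # split module 1 artificially into 1 and 3
        labels = labels.copy()
        labels.iloc[:15] = 3
        merged = net.merge_close_modules(expr, ModuleAssignment(labels), 0.25)
        assert merged.labels[labels.isin([1, 3]).to_numpy()].nunique() == 1
        assert len(merged.merge_history) == 1

    def test_zero_threshold_merges_nothing(self):
        expr, labels = _module_expr(seed=7)
        merged = net.merge_close_modules(expr, ModuleAssignment(labels), 0.0)
        pd.testing.assert_series_equal(merged.labels, labels)

    def test_manual_map_applied_verbatim(self):
        expr, labels = _module_expr(seed=8)
        merged = net.merge_close_modules(
            expr, ModuleAssignment(labels), 0.0, manual_map={2: 1}
        )
        assert set(merged.labels) == {1}
        with pytest.raises(ValueError):
            net.merge_close_modules(
                expr, ModuleAssignment(labels), 0.0, manual_map={99: 1}
            )

    def test_small_modules_discarded(self):
        labels = pd.Series([1] * 60 + [2] * 20, index=[f"g{i}" for i in range(80)])
        out = net.discard_small_modules(ModuleAssignment(labels), min_size=50)
        assert (out.labels[labels == 2] == 0).all()
        assert (out.labels[labels == 1] == 1).all()


class TestMembershipAndSignificance:
    def test_gene_equal_to_eigengene_has_unit_kme(self):
        expr, labels = _module_expr(seed=9)
        es = net.eigengenes(expr, labels)
        probe = pd.DataFrame([es.me.loc[1]], index=["probe"])
        kme = net.kme_matrix(probe, es)
        assert kme.loc["probe", 1] == pytest.approx(1.0)

    def test_gene_orthogonal_to_trait_has_zero_gs(self):
        expr = _expr([[1, -1, 1, -1, 1, -1]])
        trait = pd.Series([0, 0, 1, 1, 2, 2.0], index=expr.columns)
        gs = net.gene_significance(expr, trait)
        assert gs.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_zeb_responsive_gene_has_unit_gs(self):
        trait = pd.Series([0, 0, 1, 1, 2, 2.0], index=[f"s{j}" for j in range(6)])
        expr = _expr([trait.to_numpy() * 1.7 + 3])
        gs = net.gene_significance(expr, trait)
        assert gs.iloc[0] == pytest.approx(1.0)

    def test_constant_trait_rejected(self):
        expr = _expr([[1, 2, 3.0]])
        with pytest.raises(ValueError):
            net.gene_significance(expr, pd.Series([1, 1, 1.0], index=expr.columns))


class TestEdgesAndPca:
    def test_no_edges_below_threshold(self):
        tom = pd.DataFrame(np.full((3, 3), 0.05))
        np.fill_diagonal(tom.to_numpy(), 1.0)
        labels = ModuleAssignment(pd.Series([1, 1, 1], index=tom.index))
        assert len(net.edge_export(tom, labels, 0.1)) == 0

    def test_single_qualifying_edge(self):
        tom = pd.DataFrame(
            [[1.0, 0.5, 0.01], [0.5, 1.0, 0.02], [0.01, 0.02, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        labels = ModuleAssignment(pd.Series([1, 1, 2], index=tom.index))
        edges = net.edge_export(tom, labels, 0.1)
        assert len(edges) == 1
        assert tuple(edges.loc[0, ["source", "target"]]) == ("a", "b")

    def test_zero_threshold_gives_complete_graph(self):
        n = 6
        rng = np.random.default_rng(10)
        a = rng.uniform(0.01, 0.99, size=(n, n))
        tom = pd.DataFrame((a + a.T) / 2)
        np.fill_diagonal(tom.to_numpy(), 1.0)
        labels = ModuleAssignment(pd.Series(1, index=tom.index))
        assert len(net.edge_export(tom, labels, 0.0)) == n * (n - 1) / 2

    def test_circular_alignment_statistic(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 2 * np.pi, 500)
        assert net.circular_correlation(a, a + 0.7) == pytest.approx(1.0)
        assert net.circular_correlation(a, -a + 0.2) == pytest.approx(1.0)
        assert net.circular_correlation(a, rng.uniform(0, 2 * np.pi, 500)) < 0.2
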