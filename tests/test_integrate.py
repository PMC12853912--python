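"""ChIP consensus sets, module enrichment, masks, heatmap layout."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirnet.containers import PeakSet
from mirnet.integrate import (
    chip_target_set,
    module_set_enrichment,
    module_coefficient_summary,
    order_genes_for_heatmap,
    targetscan_mask,
)
from mirnet.network import ModuleAssignment
from mirnet.synthetic import (
    SimulationScheme,
    make_design,
    simulate_chip,
    simulate_counts,
    true_bound_set,
)


def _peaks(source, entries):
    return PeakSet(source, pd.Series(entries))


class TestChipTargetSet:
    def test_two_of_three_votes(self):
        sets = [
            _peaks("A", {"g1": 5.0, "g2": 1.0}),
            _peaks("B", {"g1": 3.0, "g3": 2.0}),
            _peaks("C", {"g3": 4.0, "g4": 1.0}),
        ]
        assert chip_target_set(sets, "two_of_three") == {"g1", "g3"}

    def test_two_of_three_needs_three_sources(self):
        with pytest.raises(ValueError):
            chip_target_set([_peaks("A", {"g": 1.0})] * 2, "two_of_three")

    def test_focal_gene_needs_top_half_support(self):
        sets = [
            _peaks("focal", {"weak": 1.0, "good": 2.0}),
            _peaks("B", {"weak": 1.0, "good": 9.0, "x": 5.0, "y": 8.0}),
            _peaks("C", {"z": 1.0, "w": 2.0}),
        ]
        # median of B is (5+8)/2=6.5... ranks: weak=1 below, good=9 above
        out = chip_target_set(sets, "focal_plus_top50", focal="focal")
        assert out == {"good"}

    def test_focal_source_required_and_known(self):
        sets = [_peaks(s, {"g": 1.0}) for s in ("A", "B", "C")]
        with pytest.raises(ValueError):
            chip_target_set(sets, "focal_plus_top50")
        with pytest.raises(ValueError):
            chip_target_set(sets, "focal_plus_top50", focal="missing")

    def test_noiseless_sources_recover_the_bound_set(self, design12):
        scheme = SimulationScheme(n_genes=400, dispersion=0.0, seed=41)
        _, _, truth = simulate_counts(scheme, design12)
        sources = simulate_chip(truth, 3, 1.0, 0.0, seed=1)
        bound = true_bound_set(truth)
        assert chip_target_set(sources, "two_of_three") == bound
        focal = chip_target_set(sources, "focal_plus_top50", focal="chip1")
        assert focal <= bound
        assert len(focal) >= len(bound) // 2


class TestModuleEnrichment:
    def test_balanced_table_is_null(self):
        labels = pd.Series(
            [1] * 10 + [2] * 10, index=[f"g{i}" for i in range(20)]
        )
        gene_set = set(labels.index[:5]) | set(labels.index[10:15])
        out = module_set_enrichment(ModuleAssignment(labels), gene_set)
        assert np.allclose(out["odds_ratio"], 1.0)
        assert np.allclose(out["p"], 1.0)

    def test_empty_overlap_with_tiny_set_is_not_significant(self):
        labels = pd.Series([1] * 5 + [2] * 45, index=[f"g{i}" for i in range(50)])
        gene_set = {"g49"}
        out = module_set_enrichment(ModuleAssignment(labels), gene_set)
        assert out.loc[1, "p"] == pytest.approx(1.0)

    def test_disjoint_set_rejected(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        with pytest.raises(ValueError):
            module_set_enrichment(ModuleAssignment(labels), {"zzz"})

    def test_unassigned_genes_stay_in_the_universe(self):
        labels = pd.Series([1, 1, 0, 0], index=list("abcd"))
        out = module_set_enrichment(ModuleAssignment(labels), {"c", "d"})
        row = out.loc[1]
        assert row["a"] + row["b"] + row["c"] + row["d"] == 4

    def test_enrichment_detects_a_planted_module(self):
        rng = np.random.default_rng(42)
        labels = pd.Series(
            [1] * 50 + [2] * 150, index=[f"g{i}" for i in range(200)]
        )
        gene_set = set(labels.index[:40]) | set(
            rng.choice(labels.index[50:], 15, replace=False)
        )
        out = module_set_enrichment(ModuleAssignment(labels), gene_set)
        assert out.loc[1, "p"] < 1e-10
        assert out.loc[1, "odds_ratio"] > 1

    def test_permuted_labels_give_uniformish_p(self):
        """Fisher p under label permutation is stochastically >= uniform."""
        rng = np.random.default_rng(43)
        genes = [f"g{i}" for i in range(300)]
        gene_set = set(rng.choice(genes, 60, replace=False))
        pvals = []
        base = np.array([1] * 100 + [2] * 100 + [3] * 100)
        for _ in range(200):
            labels = pd.Series(rng.permutation(base), index=genes)
            out = module_set_enrichment(ModuleAssignment(labels), gene_set)
            pvals.append(out["p"].iloc[0])
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestTargetscanMask:
    def test_threshold_behaviour(self):
        pairs = pd.DataFrame(
            {
                "mirna": ["m"] * 3,
                "gene": ["kept", "masked", "dupe"],
                "score": [-0.35, -0.1, -0.25],
                "is_tf": False,
            }
        )
        mask = targetscan_mask(pairs, cutoff=-0.2)
        assert set(mask.index) == {"kept", "dupe"}
        assert mask["kept"] == -0.35

    def test_best_score_per_gene(self):
        pairs = pd.DataFrame(
            {
                "mirna": ["m1", "m2"],
                "gene": ["g", "g"],
                "score": [-0.3, -0.6],
                "is_tf": False,
            }
        )
        assert targetscan_mask(pairs)["g"] == -0.6

    def test_empty_table_masks_everything(self):
        out = targetscan_mask(pd.DataFrame(columns=["mirna", "gene", "score"]))
        assert out.empty


def _layout_inputs():
    labels = pd.Series(
        {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 3, "g": 3},
    )
    kme = pd.DataFrame(
        {
            1: [0.9, 0.8, 0.7, 0.2, 0.1, 0.3, 0.2],
            2: [0.1, 0.3, 0.2, 0.9, 0.8, 0.1, 0.4],
            3: [0.3, 0.1, 0.25, 0.1, 0.3, 0.9, 0.8],
        },
        index=labels.index,
    )
    return ModuleAssignment(labels), kme


class TestHeatmapLayout:
    def test_left_leaning_genes_rise_toward_the_centre(self):
        assign, kme = _layout_inputs()
        # module 1 between ring neighbours 3 (prev) and 2 (next):
        # a leans prev (0.3>0.1), b leans next, c leans prev
        layout = order_genes_for_heatmap(assign, kme, module_ring_order=[1, 2, 3])
        block = layout[layout["module"] == 1]
        left = block[block["side"] == "L"]
        assert list(left.index) == ["c", "a"]  # ascending kME toward centre
        assert (np.diff(left["kme_own"]) >= 0).all()

    def test_single_module_is_a_pure_kme_sort(self):
        labels = pd.Series({"a": 1, "b": 1, "c": 1})
        kme = pd.DataFrame({1: [0.5, 0.9, 0.7]}, index=labels.index)
        layout = order_genes_for_heatmap(
            ModuleAssignment(labels), kme, module_ring_order=[1]
        )
        assert list(layout.index) == ["b", "c", "a"]

    def test_layout_is_a_stable_bijection(self):
        assign, kme = _layout_inputs()
        layout1 = order_genes_for_heatmap(assign, kme, module_ring_order=[1, 2, 3])
        perm = ["g", "a", "c", "e", "b", "f", "d"]
        assign2 = ModuleAssignment(assign.labels.loc[perm])
        layout2 = order_genes_for_heatmap(
            assign2, kme.loc[perm], module_ring_order=[1, 2, 3]
        )
        assert list(layout1.index) == list(layout2.index)
        assert sorted(layout1.index) == sorted(assign.labels.index)

    def test_incomplete_ring_order_rejected(self):
        assign, kme = _layout_inputs()
        with pytest.raises(ValueError):
            order_genes_for_heatmap(assign, kme, module_ring_order=[1, 2])


class TestCoefficientSummary:
    def test_constant_module_collapses_to_its_value(self):
        labels = pd.Series({"a": 1, "b": 1, "c": 1})
        table = pd.DataFrame({"logFC": [-0.8, -0.8, -0.8]}, index=labels.index)
        res = type("R", (), {"table": table})()
        out = module_coefficient_summary({"mir": res}, ModuleAssignment(labels))
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(-0.8)
        assert row["q75"] - row["q25"] == pytest.approx(0.0)

    def test_disjoint_gene_universe_rejected(self):
        labels = pd.Series({"a": 1, "b": 1})
        table = pd.DataFrame({"logFC": [1.0]}, index=["zzz"])
        res = type("R", (), {"table": table})()
        with pytest.raises(ValueError):
            module_coefficient_summary({"mir": res}, ModuleAssignment(labels))

    def test_planted_module_signatures(self, design12):
        """Direct-target genes average their planted repression in every
        background; TF-repressed genes de-repress only in parental."""
        from mirnet.models import (
            build_design,
            contrast_test,
            fit_gene_models,
            moderate_variances,
            named_contrast,
        )
        from mirnet.prep import cpm_matrix, tmm_factors

        # regulated classes kept to ~25% of genes so that TMM's
        # majority-null assumption holds and coefficients are unbiased
        props = {
            "direct_miR_PT": 0.05,
            "ZEB_repressed": 0.05,
            "ZEB_activated": 0.025,
            "coherent_FFL": 0.025,
            "incoherent_FFL": 0.025,
            "indirect": 0.075,
            "null": 0.75,
        }
        scheme = SimulationScheme(
            n_genes=3000, class_proportions=props, dispersion=0.05, seed=44
        )
        exonic, _, truth = simulate_counts(scheme, design12)
        nf = tmm_factors(exonic)
        y = cpm_matrix(exonic, nf, log=True)
        x = build_design(design12, "combined")
        fit = moderate_variances(fit_gene_models(y, x))
        contrasts = {
            name: contrast_test(fit, named_contrast(x, name))
            for name in ("mir_in_parental", "mir_in_endogZEB", "mir_in_oexZEB")
        }
        labels = truth.gene_class.map(
            {"direct_miR_PT": 1, "ZEB_repressed": 2}
        ).fillna(0).astype(int)
        out = module_coefficient_summary(contrasts, ModuleAssignment(labels))
        direct = out[(out["module"] == 1)].set_index("contrast")["mean"]
        assert np.allclose(direct, -1.0, atol=0.15)
        zr = out[(out["module"] == 2)].set_index("contrast")["mean"]
        assert zr["mir_in_parental"] == pytest.approx(2.0, abs=0.15)
        assert zr["mir_in_oexZEB"] == pytest.approx(0.0, abs=0.15)
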