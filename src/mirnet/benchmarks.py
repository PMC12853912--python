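"""Recovery benchmarks on planted synthetic data.

Each function runs one self-contained check of the pipeline against
ground truth or against an independent brute-force oracle and returns a
flat dict of metrics. They power the end-to-end report and the
reproduction script; the test suite asserts on the same numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.metrics import adjusted_rand_score

from . import eisa as eisa_mod
from . import network as net
from . import screen as screen_mod
from .containers import CountTable
from .models import (
    bh_adjust,
    build_design,
    contrast_test,
    fit_gene_models,
    moderate_variances,
    named_contrast,
    voom_weights,
)
from .prep import cpm_matrix, filter_expressed, tmm_factors
from .synthetic import (
    SimulationScheme,
    make_design,
    simulate_counts,
    simulate_panel,
    simulate_ring,
)


def _seed(seed: int, tag: int) -> list:
    return [int(seed) % (2**31), tag]


# ---------------------------------------------------------------------------
# oracle equivalence checks


def tom_oracle_check(seed: int = 1, n_matrices: int = 200, n_genes: int = 12) -> dict:
    """Max deviation of the vectorised TOM from a double-loop oracle."""
    rng = np.random.default_rng(_seed(seed, 11))
    worst = 0.0
    for _ in range(n_matrices):
        a = rng.uniform(0, 1, size=(n_genes, n_genes))
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
        adf = pd.DataFrame(a)
        tom = net.tom_similarity(adf).to_numpy()
        # brute force, straight from the definition
        oracle = np.ones_like(a)
        k = a.sum(axis=1) - 1.0
        for i in range(n_genes):
            for j in range(n_genes):
                if i == j:
                    continue
                num = (
                    sum(a[i, u] * a[u, j] for u in range(n_genes) if u not in (i, j))
                    + a[i, j]
                )
                oracle[i, j] = num / (min(k[i], k[j]) + 1.0 - a[i, j])
        worst = max(worst, float(np.max(np.abs(tom - oracle))))
    return {"tom_oracle_max_abs_dev": worst, "n": n_matrices}


def wls_oracle_check(seed: int = 1, n_problems: int = 20) -> dict:
    """Max coefficient deviation of the batched WLS vs per-gene lstsq."""
    rng = np.random.default_rng(_seed(seed, 12))
    worst = 0.0
    for _ in range(n_problems):
        n, p, g = 12, 4, 20
        x = rng.normal(size=(n, p))
        y = pd.DataFrame(rng.normal(size=(g, n)))
        w = rng.uniform(0.2, 3.0, size=(g, n))
        from .models import DesignMatrix

        design = DesignMatrix(
            pd.DataFrame(x, index=y.columns, columns=[f"c{i}" for i in range(p)]),
            model_tag="combined",
        )
        fit = fit_gene_models(y, design, weights=w)
        for gi in range(g):
            sw = np.sqrt(w[gi])
            b, *_ = np.linalg.lstsq(x * sw[:, None], y.to_numpy()[gi] * sw, rcond=None)
            worst = max(worst, float(np.max(np.abs(fit.coef.to_numpy()[gi] - b))))
    return {"wls_oracle_max_abs_dev": worst, "n": n_problems}


def bh_oracle_check(seed: int = 1, n_vectors: int = 10, size: int = 40) -> dict:
    """Exact agreement of bh_adjust with a brute-force step-up oracle."""
    rng = np.random.default_rng(_seed(seed, 13))
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=size)
        q = bh_adjust(p)
        order = np.argsort(p)
        oracle = np.empty(size)
        for rank_pos, idx in enumerate(order, start=1):
            candidates = [
                p[order[k - 1]] * size / k for k in range(rank_pos, size + 1)
            ]
            oracle[idx] = min(1.0, min(candidates))
        worst = max(worst, float(np.max(np.abs(q - oracle))))
    return {"bh_oracle_max_abs_dev": worst, "n": n_vectors}


def _fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of the margin-fixed
    tables (hypergeometric pmf summed over tables as or less likely)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    xs = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(row1 + 1)
        - gammaln(xs + 1)
        - gammaln(row1 - xs + 1)
        + gammaln(n - row1 + 1)
        - gammaln(col1 - xs + 1)
        - gammaln(n - row1 - col1 + xs + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    pmf = np.exp(logpmf)
    pmf = pmf / pmf.sum()
    cutoff = pmf[xs == a][0]
    return float(pmf[pmf <= cutoff * (1 + 1e-9)].sum())


def fisher_oracle_check(max_total: int = 40) -> dict:
    """scipy Fisher exact (the pipeline's test) vs enumeration, all
    2x2 tables with total <= max_total.

    The two-sided p is invariant under row swap, column swap and
    transpose, so each symmetry orbit is evaluated once.
    """
    worst = 0.0
    n_tables = 0
    seen: dict = {}
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    n_tables += 1
                    key = min(
                        (a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
                        (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
                    )
                    if key in seen:
                        dev = seen[key]
                    else:
                        p_impl = stats.fisher_exact([[key[0], key[1]], [key[2], key[3]]])[1]
                        p_oracle = _fisher_p_enumeration(*key)
                        dev = abs(p_impl - p_oracle)
                        seen[key] = dev
                    worst = max(worst, dev)
    return {"fisher_oracle_max_abs_dev": float(worst), "n": n_tables}


def design_equivalence_check(seed: int = 1) -> dict:
    """Combined vs interaction parameterization on simulated counts:
    identical fitted values and identical miR-in-parental logFC."""
    design = make_design(n_reps=2, include_no_dox=False)
    scheme = SimulationScheme(n_genes=400, dispersion=0.05, seed=seed)
    exonic, _, _ = simulate_counts(scheme, design)
    nf = tmm_factors(exonic)
    y = cpm_matrix(exonic, nf, log=True)
    xc = build_design(design, "combined")
    xi = build_design(design, "interaction")
    fit_c = fit_gene_models(y, xc)
    fit_i = fit_gene_models(y, xi)
    fitted_c = fit_c.coef.to_numpy() @ xc.matrix.to_numpy().T
    fitted_i = fit_i.coef.to_numpy() @ xi.matrix.to_numpy().T
    dev_fitted = float(np.max(np.abs(fitted_c - fitted_i)))
    lfc_c = contrast_test(moderate_variances(fit_c), named_contrast(xc, "mir_in_parental")).table["logFC"]
    lfc_i = contrast_test(moderate_variances(fit_i), named_contrast(xi, "mir")).table["logFC"]
    dev_lfc = float(np.max(np.abs(lfc_c.to_numpy() - lfc_i.to_numpy())))
    return {
        "design_fitted_max_abs_dev": dev_fitted,
        "design_logfc_max_abs_dev": dev_lfc,
        "n": len(design),
    }


def tmm_checks(seed: int = 1, n_genes: int = 1000) -> dict:
    """Equal libraries give factors exactly 1; a 5% composition shift is
    corrected to within 2% of the known-unperturbed-subset oracle."""
    rng = np.random.default_rng(_seed(seed, 14))
    base = rng.integers(50, 2000, size=n_genes)
    equal = pd.DataFrame({"s1": base, "s2": base, "s3": base})
    f_equal = tmm_factors(CountTable(equal)).factors.to_numpy()
    dev_equal = float(np.max(np.abs(f_equal - 1.0)))

    shifted = base.copy().astype(np.int64)
    n_up = n_genes // 20
    up = rng.choice(n_genes, size=n_up, replace=False)
    shifted[up] *= 4
    two = pd.DataFrame({"A": base, "B": shifted})
    table = CountTable(two)
    f = tmm_factors(table).factors
    lib = two.sum(axis=0)
    unpert = np.setdiff1d(np.arange(n_genes), up)
    m = np.log2(
        (two["B"].to_numpy()[unpert] / lib["B"]) / (two["A"].to_numpy()[unpert] / lib["A"])
    )
    raw = np.array([1.0, 2.0 ** np.mean(m)])
    oracle = raw / np.exp(np.mean(np.log(raw)))
    rel_err = float(np.max(np.abs(f.to_numpy() / oracle - 1.0)))
    return {
        "tmm_equal_max_abs_dev": dev_equal,
        "tmm_composition_rel_err": rel_err,
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# recovery benchmarks on planted data


def eisa_recovery(seed: int = 1, n_per_class: int = 300, dispersion: float = 0.05) -> dict:
    """Separate planted transcriptional from post-transcriptional genes.

    300 TF-repressed (transcriptional de-repression, dI=+2 in
    parental+miR) vs 300 direct miRNA targets (dPT=-1) at the stated
    dispersion; a gene is called transcriptional when |dI| > |dPT| on
    the miR-in-parental contrast. Also reports the noise-free planted
    effect recovery error (dispersion 0, group-mean mode).
    """
    design = make_design(n_reps=2, include_no_dox=False)
    n_genes = n_per_class * 20  # planted classes ~10% of the transcriptome
    frac = n_per_class / n_genes
    props = {
        "direct_miR_PT": frac,
        "ZEB_repressed": frac,
        "ZEB_activated": 0.0,
        "coherent_FFL": 0.0,
        "incoherent_FFL": 0.0,
        "indirect": 0.0,
        "null": 1.0 - 2 * frac,
    }

    # noise-free exactness
    scheme0 = SimulationScheme(
        n_genes=n_genes,
        class_proportions=props,
        dispersion=0.0,
        batch_log2_shift=0.0,
        seed=seed,
    )
    ex0, in0, truth0 = simulate_counts(scheme0, design)
    prep0 = eisa_mod.eisa_prepare(ex0, in0)
    res0 = eisa_mod.eisa_group_means(
        prep0, design, "parental:mir200c", "parental:ctrl"
    )
    g = res0.table.index
    planted_di = truth0.delta_i.loc[g, "parental:mir200c"]
    planted_pt = truth0.delta_pt.loc[g, "parental:mir200c"]
    err = np.maximum(
        (res0.table["dI"] - planted_di).abs(), (res0.table["dPT"] - planted_pt).abs()
    )
    noise_free_err = float(err.max())

    # noisy separation
    scheme = SimulationScheme(
        n_genes=n_genes,
        class_proportions=props,
        dispersion=dispersion,
        seed=seed,
    )
    ex, iv, truth = simulate_counts(scheme, design)
    prep = eisa_mod.eisa_prepare(ex, iv)
    x = build_design(design, "combined")
    res = eisa_mod.eisa_contrast(prep, x, named_contrast(x, "mir_in_parental"))
    tab = res.table
    cls = truth.gene_class.reindex(tab.index)
    pred_transcriptional = tab["dI"].abs() > tab["dPT"].abs()
    is_tr = cls == "ZEB_repressed"
    is_pt = cls == "direct_miR_PT"
    sens_tr = float(pred_transcriptional[is_tr].mean())
    sens_pt = float((~pred_transcriptional[is_pt]).mean())
    bal_acc = 0.5 * (sens_tr + sens_pt)
    mean_pt = float(tab.loc[is_pt, "dPT"].mean())
    return {
        "eisa_noise_free_max_abs_err": noise_free_err,
        "eisa_balanced_accuracy": bal_acc,
        "eisa_mean_dpt_direct": mean_pt,
        "n": int(is_tr.sum() + is_pt.sum()),
    }


def de_recovery(
    seed: int = 1, n_genes: int = 5000, n_planted: int = 200, dispersion: float = 0.05
) -> dict:
    """Sensitivity, empirical FDR and logFC RMSE for planted |log2FC|=2.

    200 direct miRNA targets with dPT = -2 among 5000 genes, the full
    12-sample design, voom precision weights, moderated t and BH; the
    contrast is the average miR effect across backgrounds (where the
    planted effect lives in every background).
    """
    design = make_design(n_reps=2, include_no_dox=False)
    frac = n_planted / n_genes
    props = {
        "direct_miR_PT": frac,
        "ZEB_repressed": 0.0,
        "ZEB_activated": 0.0,
        "coherent_FFL": 0.0,
        "incoherent_FFL": 0.0,
        "indirect": 0.0,
        "null": 1.0 - frac,
    }
    effects = {k: (0.0, 0.0) for k in props}
    effects["direct_miR_PT"] = (0.0, -2.0)
    scheme = SimulationScheme(
        n_genes=n_genes,
        class_proportions=props,
        effect_sizes=effects,
        dispersion=dispersion,
        seed=seed,
    )
    exonic, _, truth = simulate_counts(scheme, design)
    filtered = filter_expressed(exonic, 1.0, 2)
    nf = tmm_factors(filtered)
    x = build_design(design, "combined")
    w = voom_weights(filtered, nf, x)
    y = cpm_matrix(filtered, nf, log=True)
    fit = moderate_variances(fit_gene_models(y, x, weights=w))
    c = np.zeros(len(x.columns))
    for g in x.columns:
        if g.endswith(":mir200c"):
            c[x.columns.get_loc(g)] = 1.0 / 3.0
        elif g.endswith(":ctrl"):
            c[x.columns.get_loc(g)] = -1.0 / 3.0
    res = contrast_test(fit, c).table
    planted = truth.gene_class.reindex(res.index) == "direct_miR_PT"
    called = res["q"] <= 0.05
    tp = int((called & planted).sum())
    fp = int((called & ~planted).sum())
    sens = tp / int(planted.sum())
    fdr = fp / max(tp + fp, 1)
    rmse = float(
        np.sqrt(np.mean((res.loc[planted, "logFC"] - (-2.0)) ** 2))
    )
    return {
        "de_sensitivity": float(sens),
        "de_empirical_fdr": float(fdr),
        "de_logfc_rmse": rmse,
        "n": n_genes,
    }


def null_de_check(seed: int = 1, n_genes: int = 5000) -> dict:
    """Fraction of q<=0.05 calls under a pure null simulation."""
    design = make_design(n_reps=2, include_no_dox=False)
    props = {k: 0.0 for k in ("direct_miR_PT", "ZEB_repressed", "ZEB_activated",
                              "coherent_FFL", "incoherent_FFL", "indirect")}
    props["null"] = 1.0
    scheme = SimulationScheme(
        n_genes=n_genes, class_proportions=props, dispersion=0.05, seed=seed
    )
    exonic, _, _ = simulate_counts(scheme, design)
    filtered = filter_expressed(exonic, 1.0, 2)
    nf = tmm_factors(filtered)
    x = build_design(design, "combined")
    w = voom_weights(filtered, nf, x)
    y = cpm_matrix(filtered, nf, log=True)
    fit = moderate_variances(fit_gene_models(y, x, weights=w))
    res = contrast_test(fit, named_contrast(x, "mir_in_parental")).table
    return {"null_q05_fraction": float((res["q"] <= 0.05).mean()), "n": n_genes}


def screen_recovery(seed: int = 1) -> dict:
    """Recall/precision of the top-1% x top-1% screen on planted pairs,
    plus the TF-enrichment p when TFs are planted at 50% vs 12%."""
    panel, pairs, truth = simulate_panel(
        n_samples=500,
        n_genes=10_000,
        n_pairs=10_000,
        n_planted=50,
        planted_tf_fraction=0.5,
        background_tf_fraction=0.12,
        anticorrelation_strength=0.9,
        seed=seed,
    )
    withrec = screen_mod.pair_expression_correlation(panel, pairs)
    strong = screen_mod.strong_pair_intersect(withrec, 0.01, 0.01)
    sel = set(zip(strong["mirna"], strong["gene"]))
    planted = set(truth.index[truth])
    tp = len(sel & planted)
    recall = tp / len(planted)
    precision = tp / max(len(sel), 1)
    prop, odds, pval = screen_mod.tf_proportion_enrichment(strong, 0.12)
    return {
        "screen_recall": float(recall),
        "screen_precision": float(precision),
        "screen_tf_proportion": float(prop),
        "screen_tf_enrichment_p": float(pval),
        "n": len(pairs),
    }


def screen_null_uniformity(
    seed: int = 1, n_reps: int = 200, n_pairs: int = 4000, n_samples: int = 60
) -> dict:
    """KS distance of null TF-enrichment p-values from uniform.

    200 panels with no planted anti-correlation and TF flags drawn at
    the background rate; moderate selection quantiles keep the selected
    sets large enough for the binomial support to be dense.
    """
    pvals = []
    for r in range(n_reps):
        panel, pairs, _ = simulate_panel(
            n_samples=n_samples,
            n_genes=n_pairs,
            n_pairs=n_pairs,
            n_planted=0,
            planted_tf_fraction=0.12,
            background_tf_fraction=0.12,
            anticorrelation_strength=0.0,
            n_mirnas=20,
            seed=int(seed) + 7919 * r,
        )
        withrec = screen_mod.pair_expression_correlation(panel, pairs)
        strong = screen_mod.strong_pair_intersect(withrec, 0.25, 0.25)
        _, _, p = screen_mod.tf_proportion_enrichment(strong, 0.12)
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    return {
        "screen_null_ks_stat": float(ks.statistic),
        "screen_null_ks_p": float(ks.pvalue),
        "n": n_reps,
    }


def module_recovery_ring(seed: int = 1, n_genes: int = 3000, n_modules: int = 8) -> dict:
    """Ring-of-modules recovery: ARI, circular angle correlation and the
    PC1+PC2 variance share at beta=1 vs beta=16."""
    design = make_design(n_reps=2, include_no_dox=False)
    counts, truth = simulate_ring(
        design, n_genes=n_genes, n_modules=n_modules, seed=seed
    )
    nf = tmm_factors(counts)
    y = cpm_matrix(counts, nf, log=True).values
    a16 = net.signed_adjacency(y, beta=16.0)
    diss = 1.0 - net.tom_similarity(a16)
    tree = net.average_linkage_tree(diss)
    assign = net.dynamic_cut(tree, diss, min_size=10, expr=y)
    assign = net.merge_close_modules(y, assign, diss_threshold=0.25)
    ari = adjusted_rand_score(
        truth["module"].to_numpy(), assign.labels.reindex(truth.index).to_numpy()
    )
    _, ratio16 = net.network_pca(a16)
    coords, _ = net.profile_pca(y.loc[truth.index])
    ang = net.gene_angles(coords)
    circ = net.circular_correlation(ang.to_numpy(), truth["theta"].to_numpy())
    a1 = net.signed_adjacency(y, beta=1.0)
    _, ratio1 = net.network_pca(a1)
    return {
        "module_ari": float(ari),
        "module_count": int(assign.labels[assign.labels != 0].nunique()),
        "circular_correlation": float(circ),
        "pc12_share_beta16": float(ratio16[:2].sum()),
        "pc12_share_beta1": float(ratio1[:2].sum()),
        "n": n_genes,
    }


RECOVERY_BENCHMARKS = {
    "eisa": eisa_recovery,
    "de": de_recovery,
    "screen": screen_recovery,
    "screen_null": screen_null_uniformity,
    "ring": module_recovery_ring,
}


def run_recovery_benchmarks(seed: int = 1) -> dict:
    out = {}
    for name, fn in RECOVERY_BENCHMARKS.items():
        out[name] = fn(seed=seed)
    return out
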