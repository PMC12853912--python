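"""End-to-end orchestration: simulate -> prep -> fit -> eisa -> screen ->
network -> integrate -> report.

Every stage reads its inputs from, and writes its outputs to, a shared
output directory, together with a manifest (input hashes, parameters,
seed, package version) sufficient to reproduce the stage in isolation.
Per-stage seeds are derived deterministically from the master seed and
the stage name, so toggling one stage never shifts another's random
stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import benchmarks, eisa as eisa_mod, io, network as net, screen as screen_mod
from . import integrate as integrate_mod
from .containers import CountTable, design_groups
from .models import (
    build_design,
    contrast_test,
    fit_gene_models,
    moderate_variances,
    named_contrast,
    voom_weights,
)
from .prep import cpm_matrix, filter_expressed, remove_batch_effect, tmm_factors
from .synthetic import (
    SimulationScheme,
    make_design,
    simulate_chip,
    simulate_counts,
    simulate_panel,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "prep", "fit", "eisa", "screen", "network", "integrate", "report"]

# stage -> files it must find in the output directory before running
STAGE_REQUIRES = {
    "simulate": [],
    "prep": ["simulate/exonic.tsv", "simulate/design.tsv"],
    "fit": ["prep/logcpm.tsv", "simulate/design.tsv", "prep/filtered_exonic.tsv"],
    "eisa": ["simulate/exonic.tsv", "simulate/intronic.tsv", "simulate/design.tsv"],
    "screen": ["simulate/pairs.tsv", "simulate/panel_mirna.tsv", "simulate/panel_genes.tsv"],
    "network": ["prep/logcpm_batchadj.tsv", "simulate/design.tsv"],
    "integrate": [
        "network/labels.tsv",
        "network/kme.tsv",
        "fit/contrast_mir_in_parental.tsv",
        "simulate/chip1.tsv",
    ],
    "report": [],
}

DEFAULT_CONFIG = {
    "seed": 1,
    "stages": {name: True for name in STAGE_ORDER},
    "simulate": {
        "n_genes": 6000,
        "n_reps": 2,
        "include_no_dox": True,
        "dispersion": 0.05,
        "panel": {
            "n_samples": 500,
            "n_genes": 10_000,
            "n_pairs": 10_000,
            "n_planted": 50,
            "planted_tf_fraction": 0.5,
            "background_tf_fraction": 0.12,
            "anticorrelation_strength": 0.9,
        },
        "chip": {"n_sources": 3, "sensitivity": 0.8, "false_positive_rate": 0.05},
    },
    "prep": {"min_cpm": 1.0, "min_samples": 2, "prior_count": 0.5},
    "fit": {
        "contrasts": ["mir_in_parental", "mir_in_endogZEB", "mir_in_oexZEB"],
        "interaction_terms": ["mir", "endogZEB:mir", "oexZEB:mir"],
    },
    "eisa": {
        "min_count": 5,
        "min_samples": 2,
        "fc_threshold": 0.585,
        "dominance_ratio": 2.0,
        "contrasts": ["mir_in_parental", "mir_in_endogZEB", "mir_in_oexZEB"],
    },
    "screen": {
        "method": "spearman",
        "score_quantile": 0.01,
        "rec_quantile": 0.01,
        "background_tf_proportion": 0.12,
    },
    "network": {
        "min_cpm": 4.0,
        "min_samples": 2,
        "top_n": 3000,
        "beta": 16.0,
        "min_module_size": 10,
        "merge_threshold": 0.25,
        "discard_below": 50,
        "edge_threshold": 0.1,
    },
    "integrate": {"score_cutoff": -0.2},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, seed: int | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        cfg = _deep_merge(cfg, io.read_config(path))
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, params: dict, seed: int, inputs: list) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "version": __version__,
        "inputs": {str(p): _hash_file(Path(p)) for p in inputs},
        "outputs": sorted(
            str(p.relative_to(out)) for p in (out / stage).glob("*") if p.is_file()
        ),
    }
    (out / stage / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _check_requirements(out: Path, stage: str) -> list:
    missing = [rel for rel in STAGE_REQUIRES[stage] if not (out / rel).exists()]
    if missing:
        upstream = sorted({rel.split("/", 1)[0] for rel in missing})
        raise FileNotFoundError(
            f"stage {stage!r} needs outputs from {upstream}: run those stages first "
            f"(missing {missing})"
        )
    return [out / rel for rel in STAGE_REQUIRES[stage]]


def _stage_simulate(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["simulate"]
    d = out / "simulate"
    design = make_design(n_reps=p["n_reps"], include_no_dox=p["include_no_dox"])
    scheme = SimulationScheme(
        n_genes=p["n_genes"], dispersion=p["dispersion"], seed=seed
    )
    exonic, intronic, truth = simulate_counts(scheme, design)
    io.write_design(design, d / "design.tsv")
    io.write_count_table(exonic, d / "exonic.tsv")
    io.write_count_table(intronic, d / "intronic.tsv")
    truth.frame().to_csv(d / "truth.tsv", sep="\t", index_label="gene")
    panel, pairs, planted = simulate_panel(seed=seed, **p["panel"])
    io.write_matrix(panel.mirna, d / "panel_mirna.tsv", index_label="mirna")
    io.write_matrix(panel.genes, d / "panel_genes.tsv", index_label="gene")
    io.write_pair_scores(pairs, d / "pairs.tsv")
    planted.reset_index().to_csv(d / "planted_pairs.tsv", sep="\t", index=False)
    for peaks in simulate_chip(truth, seed=seed, **p["chip"]):
        io.write_peak_set(peaks, d / f"{peaks.source}.tsv")


def _stage_prep(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["prep"]
    d = out / "prep"
    design = io.read_design(out / "simulate/design.tsv")
    exonic = io.read_count_table(out / "simulate/exonic.tsv")
    filtered = filter_expressed(exonic, p["min_cpm"], p["min_samples"])
    logger.info("prep: %d of %d genes pass the expression filter",
                filtered.counts.shape[0], exonic.counts.shape[0])
    nf = tmm_factors(filtered)
    logcpm = cpm_matrix(filtered, nf, log=True, prior_count=p["prior_count"])
    groups = pd.get_dummies(design_groups(design)).astype(float)
    adjusted = remove_batch_effect(logcpm, design["batch"], groups)
    io.write_count_table(filtered, d / "filtered_exonic.tsv")
    nf.factors.to_csv(d / "tmm_factors.tsv", sep="\t", index_label="sample_id")
    io.write_matrix(logcpm.values, d / "logcpm.tsv")
    io.write_matrix(adjusted.values, d / "logcpm_batchadj.tsv")


def _stage_fit(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["fit"]
    d = out / "fit"
    design = io.read_design(out / "simulate/design.tsv")
    filtered = io.read_count_table(out / "prep/filtered_exonic.tsv")
    nf = tmm_factors(filtered)
    y = cpm_matrix(filtered, nf, log=True)
    report = {}
    for model in ("combined", "interaction"):
        x = build_design(design, model)
        w = voom_weights(filtered, nf, x)
        fit = moderate_variances(fit_gene_models(y, x, weights=w))
        report[model] = {
            "columns": list(x.columns),
            "df_prior": fit.df_prior,
            "s2_prior": fit.s2_prior,
        }
        names = p["contrasts"] if model == "combined" else p["interaction_terms"]
        for name in names:
            res = contrast_test(fit, named_contrast(x, name))
            safe = name.replace(":", "_")
            prefix = "contrast" if model == "combined" else "interaction"
            res.table.to_csv(d / f"{prefix}_{safe}.tsv", sep="\t", index_label="gene")
    (d / "model_report.json").write_text(json.dumps(report, indent=2))


def _stage_eisa(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["eisa"]
    d = out / "eisa"
    design = io.read_design(out / "simulate/design.tsv")
    exonic = io.read_count_table(out / "simulate/exonic.tsv")
    intronic = io.read_count_table(out / "simulate/intronic.tsv", layer="intronic")
    prepared = eisa_mod.eisa_prepare(exonic, intronic, p["min_count"], p["min_samples"])
    logger.info("eisa: %d genes dropped by the two-layer filter", prepared.n_dropped)
    x = build_design(design, "combined")
    for name in p["contrasts"]:
        res = eisa_mod.eisa_contrast(prepared, x, named_contrast(x, name), name=name)
        res = eisa_mod.classify_regulation(res, p["fc_threshold"], p["dominance_ratio"])
        res.table.to_csv(d / f"eisa_{name}.tsv", sep="\t", index_label="gene")


def _stage_screen(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["screen"]
    d = out / "screen"
    from .containers import PanelExpression

    panel = PanelExpression(
        mirna=io.read_matrix(out / "simulate/panel_mirna.tsv"),
        genes=io.read_matrix(out / "simulate/panel_genes.tsv"),
    )
    pairs = io.read_pair_scores(out / "simulate/pairs.tsv")
    withrec = screen_mod.pair_expression_correlation(panel, pairs, p["method"])
    strong = screen_mod.strong_pair_intersect(
        withrec, p["score_quantile"], p["rec_quantile"]
    )
    io.write_pair_scores(strong, d / "strong_pairs.tsv")
    prop, odds, pval = screen_mod.tf_proportion_enrichment(
        strong, p["background_tf_proportion"]
    )
    grid = screen_mod.prediction_correlation_bins(withrec)
    grid.counts.to_csv(d / "bin_counts.tsv", sep="\t")
    grid.tf_proportion.to_csv(d / "bin_tf_proportion.tsv", sep="\t")
    (d / "enrichment.json").write_text(
        json.dumps(
            {
                "n_strong_pairs": int(len(strong)),
                "tf_proportion": prop,
                "odds_ratio": odds,
                "p": pval,
                "background": p["background_tf_proportion"],
            },
            indent=2,
        )
    )


def _stage_network(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["network"]
    d = out / "network"
    design = io.read_design(out / "simulate/design.tsv")
    y = io.read_matrix(out / "prep/logcpm_batchadj.tsv")
    # the network uses the dox-induced samples only (6 groups, 12 samples)
    induced = design.index[design["dox"] == 1] if "dox" in design else design.index
    y = y[list(induced)]
    genes = net.select_network_genes(
        y, p["min_cpm"], p["min_samples"], p["top_n"]
    )
    expr = y.loc[genes]
    adj = net.signed_adjacency(expr, beta=p["beta"])
    tom = net.tom_similarity(adj)
    diss = 1.0 - tom
    tree = net.average_linkage_tree(diss)
    assign = net.dynamic_cut(tree, diss, min_size=p["min_module_size"], expr=expr)
    assign = net.merge_close_modules(expr, assign, p["merge_threshold"])
    assign = net.discard_small_modules(assign, p["discard_below"])
    me = net.eigengenes(expr, assign.labels)
    kme = net.kme_matrix(expr, me)
    sub_design = design.loc[induced]
    gs_zeb = net.gene_significance(expr, net.zeb_trait(sub_design))
    gs_mir = net.gene_significance(expr, net.mir_trait(sub_design))
    edges = net.edge_export(tom, assign, threshold=p["edge_threshold"])
    assign.labels.to_csv(d / "labels.tsv", sep="\t", index_label="gene")
    io.write_matrix(me.me, d / "eigengenes.tsv", index_label="module")
    io.write_matrix(kme, d / "kme.tsv")
    pd.DataFrame({"GS_ZEB": gs_zeb, "GS_miR": gs_mir}).to_csv(
        d / "gene_significance.tsv", sep="\t", index_label="gene"
    )
    io.write_edge_list(edges, d / "edges.tsv")
    _, ratio_soft = net.network_pca(adj)
    _, ratio_raw = net.network_pca(net.signed_adjacency(expr, beta=1.0))
    (d / "network_report.json").write_text(
        json.dumps(
            {
                "n_genes": len(genes),
                "n_modules": int(assign.labels[assign.labels != 0].nunique()),
                "module_sizes": {
                    str(k): int(v) for k, v in assign.sizes().items()
                },
                "pc12_share_soft_power": float(ratio_soft[:2].sum()),
                "pc12_share_beta1": float(ratio_raw[:2].sum()),
            },
            indent=2,
        )
    )


def _stage_integrate(cfg: dict, out: Path, seed: int) -> None:
    p = cfg["integrate"]
    d = out / "integrate"
    labels = pd.read_csv(out / "network/labels.tsv", sep="\t", index_col=0)["module"]
    assign = net.ModuleAssignment(labels=labels)
    kme = io.read_matrix(out / "network/kme.tsv")
    kme.columns = kme.columns.astype(int)
    peak_sets = [
        io.read_peak_set(path) for path in sorted((out / "simulate").glob("chip*.tsv"))
    ]
    two_of_three = integrate_mod.chip_target_set(peak_sets, "two_of_three")
    focal = integrate_mod.chip_target_set(
        peak_sets, "focal_plus_top50", focal=peak_sets[0].source
    )
    pairs = io.read_pair_scores(out / "simulate/pairs.tsv")
    mask = integrate_mod.targetscan_mask(pairs, p["score_cutoff"])
    enr = []
    for name, gene_set in [
        ("chip_two_of_three", two_of_three),
        ("chip_focal_top50", focal),
        ("predicted_targets", set(mask.index)),
    ]:
        try:
            tab = integrate_mod.module_set_enrichment(assign, gene_set)
        except ValueError:
            continue
        tab = tab.assign(set_name=name)
        enr.append(tab)
    if enr:
        pd.concat(enr).to_csv(d / "enrichment.tsv", sep="\t", index_label="module")
    me = net.EigengeneSet(
        me=io.read_matrix(out / "network/eigengenes.tsv"),
        variance_explained=pd.Series(dtype=float),
        orientation=pd.Series(dtype=float),
    )
    me.me.index = me.me.index.astype(int)
    layout = integrate_mod.order_genes_for_heatmap(assign, kme, me_set=me)
    contrasts = {}
    for path in sorted((out / "fit").glob("contrast_*.tsv")):
        name = path.stem.replace("contrast_", "")
        table = pd.read_csv(path, sep="\t", index_col=0)
        contrasts[name] = type("R", (), {"table": table})()
    eisa_tables = {}
    for path in sorted((out / "eisa").glob("eisa_*.tsv")):
        name = path.stem.replace("eisa_", "")
        table = pd.read_csv(path, sep="\t", index_col=0)
        eisa_tables[name] = type("R", (), {"table": table})()
    layout = integrate_mod.attach_annotations(
        layout,
        chip_sets={"two_of_three": two_of_three, "focal_top50": focal},
        score_mask=mask,
        contrasts=contrasts,
        eisa_tables=eisa_tables,
    )
    layout.to_csv(d / "heatmap_layout.tsv", sep="\t", index_label="gene")
    summary = integrate_mod.module_coefficient_summary(contrasts, assign, eisa_tables)
    summary.to_csv(d / "module_summary.tsv", sep="\t", index=False)


def _stage_report(cfg: dict, out: Path, seed: int) -> None:
    d = out / "report"
    report = {"seed": cfg["seed"], "stages": {}}
    for stage in STAGE_ORDER[:-1]:
        manifest = out / stage / "manifest.json"
        report["stages"][stage] = (
            json.loads(manifest.read_text()) if manifest.exists() else "skipped"
        )
    report["benchmarks"] = benchmarks.run_recovery_benchmarks(seed=cfg["seed"])
    netrep = out / "network/network_report.json"
    if netrep.exists():
        report["network"] = json.loads(netrep.read_text())
    (d / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "fit": _stage_fit,
    "eisa": _stage_eisa,
    "screen": _stage_screen,
    "network": _stage_network,
    "integrate": _stage_integrate,
    "report": _stage_report,
}


def run_stage(cfg: dict, stage: str, out_dir) -> Path:
    """Run one stage, writing outputs + a manifest under out_dir/<stage>/."""
    if stage not in STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}")
    out = Path(out_dir)
    inputs = _check_requirements(out, stage)
    (out / stage).mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg["seed"], stage)
    t0 = time.time()
    STAGE_FUNCS[stage](cfg, out, seed)
    logger.info("stage %s finished in %.1fs", stage, time.time() - t0)
    _write_manifest(out, stage, cfg.get(stage, {}), seed, inputs)
    return out / stage


def run_all(cfg: dict, out_dir) -> dict:
    """Run every enabled stage in order; returns the final report."""
    out = Path(out_dir)
    for stage in STAGE_ORDER:
        if not cfg.get("stages", {}).get(stage, True):
            logger.info("stage %s skipped by config", stage)
            continue
        run_stage(cfg, stage, out)
    report_path = out / "report/report.json"
    if report_path.exists():
        report = json.loads(report_path.read_text())
    else:
        report = {"seed": cfg["seed"], "stages": "report stage disabled"}
    for stage in STAGE_ORDER:
        if not cfg.get("stages", {}).get(stage, True):
            report.setdefault("skipped", []).append(stage)
    return report
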