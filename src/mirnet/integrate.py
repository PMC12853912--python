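"""Cross-referencing modules with ChIP target sets, predicted miRNA
targets, linear-model coefficients and EISA components.

ChIP target sets come in the two flavours used throughout: genes bound
in at least 2 of 3 sources, or genes bound in a focal source that also
carry a peak score in the top half of at least one other source.
Module enrichment uses two-sided Fisher's exact tests with BH
adjustment across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PeakSet
from .models import bh_adjust
from .network import EigengeneSet, ModuleAssignment, kme_matrix


def chip_target_set(
    peak_sets: list[PeakSet],
    mode: str = "two_of_three",
    focal: str | None = None,
) -> set:
    """Consensus TF-bound gene set from several ChIP sources."""
    if mode == "two_of_three":
        if len(peak_sets) != 3:
            raise ValueError("two_of_three requires exactly 3 peak sets")
        tally = pd.Series(0, index=pd.Index(sorted(set().union(*[p.genes for p in peak_sets]))))
        for p in peak_sets:
            tally[tally.index.isin(p.genes)] += 1
        return set(tally.index[tally >= 2])
    if mode == "focal_plus_top50":
        if focal is None:
            raise ValueError("focal_plus_top50 requires a focal source name")
        by_name = {p.source: p for p in peak_sets}
        if focal not in by_name:
            raise ValueError(f"focal source {focal!r} not among peak sets")
        focal_genes = by_name[focal].genes
        others = [p for p in peak_sets if p.source != focal]
        supported: set = set()
        for p in others:
            med = p.scores.median()
            supported |= set(p.scores.index[p.scores >= med])
        return focal_genes & supported
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # module x (a, b, c, d, odds_ratio, p, q)


def module_set_enrichment(
    assignment: ModuleAssignment, gene_set: set, universe=None
) -> pd.DataFrame:
    """Fisher's exact enrichment of a gene set in each module.

    The 2x2 table per module is [[in-module & in-set, in-module & out],
    [out-module & in-set, out-module & out]] over the universe (default:
    all genes carrying a label, with unassigned genes counted outside
    every module). Two-sided p, BH q across modules.
    """
    labels = assignment.labels
    if universe is None:
        universe = pd.Index(labels.index)
    else:
        universe = pd.Index(sorted(universe))
        labels = labels.reindex(universe, fill_value=0)
    in_set = universe.isin(gene_set)
    if not in_set.any():
        raise ValueError("gene set is disjoint from the universe")
    rows = []
    modules = sorted(set(labels[labels != 0]))
    for mod in modules:
        in_mod = (labels == mod).to_numpy()
        a = int((in_mod & in_set).sum())
        b = int((in_mod & ~in_set).sum())
        c = int((~in_mod & in_set).sum())
        d = int((~in_mod & ~in_set).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"module": mod, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows).set_index("module")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def targetscan_mask(pairs: pd.DataFrame, cutoff: float = -0.2) -> pd.Series:
    """Per-gene best (most negative) score, kept only when < cutoff."""
    if pairs.empty:
        return pd.Series(dtype=float, name="score")
    best = pairs.groupby("gene")["score"].min()
    return best[best < cutoff].rename("score")


def ring_order_from_eigengenes(me_set: EigengeneSet) -> list:
    """Module ring order = angular order of eigengenes in their PC1/PC2 plane."""
    me = me_set.me.to_numpy(dtype=float)
    mec = me - me.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(mec, full_matrices=False)
    coords = mec @ vt[:2].T
    ang = np.mod(np.arctan2(coords[:, 1], coords[:, 0]), 2 * np.pi)
    order = np.argsort(ang, kind="mergesort")
    return [me_set.me.index[i] for i in order]


def order_genes_for_heatmap(
    assignment: ModuleAssignment,
    kme: pd.DataFrame,
    module_ring_order: list | None = None,
    me_set: EigengeneSet | None = None,
) -> pd.DataFrame:
    """Order genes module-by-module around the regulatory ring.

    Within a module, each gene leans toward whichever adjacent ring
    module it has the larger kME with; genes are sorted by own-module
    kME increasing toward the centre (left side ascending, centre =
    maximum, right side descending). Ties break by gene id, so the
    layout is a deterministic bijection on the labelled genes.
    """
    labels = assignment.labels
    modules = sorted(set(labels[labels != 0]))
    if module_ring_order is None:
        if me_set is None:
            raise ValueError("need module_ring_order or me_set")
        module_ring_order = ring_order_from_eigengenes(me_set)
    if set(module_ring_order) != set(modules):
        raise ValueError("ring order must cover exactly the retained modules")
    n_mod = len(module_ring_order)
    ordered = []
    for pos, mod in enumerate(module_ring_order):
        prev_mod = module_ring_order[(pos - 1) % n_mod]
        next_mod = module_ring_order[(pos + 1) % n_mod]
        genes = labels.index[labels == mod]
        sub = kme.loc[genes]
        own = sub[mod]
        if n_mod > 1 and prev_mod != next_mod:
            lean_left = sub[prev_mod] >= sub[next_mod]
        elif n_mod > 1:
            lean_left = sub[prev_mod] >= own  # degenerate 2-module ring
        else:
            lean_left = pd.Series(False, index=genes)
        # tie-break on gene id so the layout is reproducible
        def _sorted(series, ascending):
            frame = pd.DataFrame(
                {"kme_own": series.to_numpy(), "gid": series.index.to_numpy()}
            )
            frame = frame.sort_values(
                ["kme_own", "gid"], ascending=[ascending, True], kind="mergesort"
            )
            return zip(frame["gid"], frame["kme_own"])

        ordered.extend(
            {"gene": g, "module": mod, "side": "L", "kme_own": v}
            for g, v in _sorted(own[lean_left], True)
        )
        ordered.extend(
            {"gene": g, "module": mod, "side": "R", "kme_own": v}
            for g, v in _sorted(own[~lean_left], False)
        )
    layout = pd.DataFrame(ordered).set_index("gene")
    layout["position"] = np.arange(len(layout))
    return layout


def attach_annotations(
    layout: pd.DataFrame,
    gs_zeb: pd.Series | None = None,
    gs_mir: pd.Series | None = None,
    chip_sets: dict | None = None,
    score_mask: pd.Series | None = None,
    contrasts: dict | None = None,
    eisa_tables: dict | None = None,
) -> pd.DataFrame:
    """Join per-gene annotation rows onto a heatmap layout."""
    out = layout.copy()
    if gs_zeb is not None:
        out["GS_ZEB"] = gs_zeb.reindex(out.index)
    if gs_mir is not None:
        out["GS_miR"] = gs_mir.reindex(out.index)
    for name, genes in (chip_sets or {}).items():
        out[f"chip[{name}]"] = out.index.isin(genes)
    if score_mask is not None:
        out["targetscan_score"] = score_mask.reindex(out.index)
    for name, res in (contrasts or {}).items():
        out[f"logFC[{name}]"] = res.table["logFC"].reindex(out.index)
    for name, eisa_res in (eisa_tables or {}).items():
        out[f"dI[{name}]"] = eisa_res.table["dI"].reindex(out.index)
        out[f"dPT[{name}]"] = eisa_res.table["dPT"].reindex(out.index)
    return out


def module_coefficient_summary(
    contrasts: dict,
    assignment: ModuleAssignment,
    eisa_tables: dict | None = None,
) -> pd.DataFrame:
    """Per module x contrast distribution summaries of effect sizes.

    Quantifies, for every module, the location and spread of the
    contrast logFCs (and, when provided, the EISA dI / dPT components) —
    the numbers behind per-module violin plots.
    """
    labels = assignment.labels
    rows = []

    def summarize(series: pd.Series, what: str, contrast: str) -> None:
        for mod in sorted(set(labels[labels != 0])):
            genes = labels.index[labels == mod]
            vals = series.reindex(genes).dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "module": mod,
                    "contrast": contrast,
                    "component": what,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "median": float(vals.median()),
                    "q25": float(vals.quantile(0.25)),
                    "q75": float(vals.quantile(0.75)),
                }
            )

    for name, res in contrasts.items():
        missing = labels.index[labels != 0].difference(res.table.index)
        if len(missing) == len(labels.index[labels != 0]):
            raise ValueError(f"contrast {name!r} shares no genes with the modules")
        summarize(res.table["logFC"], "logFC", name)
    for name, eisa_res in (eisa_tables or {}).items():
        summarize(eisa_res.table["dI"], "dI", name)
        summarize(eisa_res.table["dPT"], "dPT", name)
    return pd.DataFrame(rows)
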