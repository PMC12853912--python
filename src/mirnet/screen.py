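"""The "strong target" screen.

A miRNA-target pair is called strong when it sits simultaneously in the
most-negative tail of the prediction scores (TargetScan-style context++
values) and the most-negative tail of miRNA:gene expression correlation
across a large cell panel (the REC score). TF enrichment among strong
targets is then quantified against the genomic background proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PanelExpression

logger = logging.getLogger(__name__)


@dataclass
class BinGrid:
    """Score-bin x correlation-bin grid of pair counts and TF shares."""

    counts: pd.DataFrame
    tf_counts: pd.DataFrame
    tf_proportion: pd.DataFrame
    background_tf_proportion: float


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    out = np.full(a.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def pair_expression_correlation(
    panel: PanelExpression, pairs: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Attach the panel expression correlation (REC score) to each pair.

    Spearman by default (ranks are robust to the panel's scale); pairs
    referencing absent genes or miRNAs are skipped with a warning and
    constant vectors yield a missing REC.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if panel.genes.shape[1] < 10:
        raise ValueError("need at least 10 panel samples")
    present = pairs["gene"].isin(panel.genes.index) & pairs["mirna"].isin(
        panel.mirna.index
    )
    if not present.any():
        raise ValueError("no pair references genes/miRNAs present in the panel")
    n_skip = int((~present).sum())
    if n_skip:
        logger.warning("skipping %d pairs absent from the panel", n_skip)
    sub = pairs.loc[present].copy()
    g = panel.genes.loc[sub["gene"]].to_numpy(dtype=float)
    m = panel.mirna.loc[sub["mirna"]].to_numpy(dtype=float)
    if method == "spearman":
        g = stats.rankdata(g, axis=1)
        m = stats.rankdata(m, axis=1)
    rec = _rowwise_corr(m, g)
    n_const = int(np.isnan(rec).sum())
    if n_const:
        logger.warning("%d pairs with constant expression get missing REC", n_const)
    sub["rec"] = rec
    return sub


def strong_pair_intersect(
    pairs: pd.DataFrame, score_quantile: float = 0.01, rec_quantile: float = 0.01
) -> pd.DataFrame:
    """Pairs in the most-negative score AND correlation tails.

    Percentiles are computed over all pairs with a defined REC; ties at
    either threshold are included, so the set can slightly exceed the
    nominal quantile.
    """
    for q in (score_quantile, rec_quantile):
        if not 0 < q <= 1:
            raise ValueError("quantiles must lie in (0, 1]")
    valid = pairs.dropna(subset=["rec"]).copy()
    score_thr = valid["score"].quantile(score_quantile)
    rec_thr = valid["rec"].quantile(rec_quantile)
    sel = valid[(valid["score"] <= score_thr) & (valid["rec"] <= rec_thr)].copy()
    sel["score_percentile"] = valid["score"].rank(pct=True).loc[sel.index]
    sel["rec_percentile"] = valid["rec"].rank(pct=True).loc[sel.index]
    return sel


def tf_proportion_enrichment(
    selected: pd.DataFrame, background_tf_proportion: float = 0.12
) -> tuple[float, float, float]:
    """TF share among the selected genes vs the genomic background.

    Genes are deduplicated before counting (a gene targeted by several
    miRNAs is one gene). Returns (proportion, odds ratio, one-sided
    exact binomial p for enrichment).
    """
    if selected.empty:
        raise ValueError("empty strong-pair set")
    genes = selected.groupby("gene")["is_tf"].any()
    n = int(genes.size)
    k = int(genes.sum())
    prop = k / n
    p0 = background_tf_proportion
    odds = (k / max(n - k, 1)) / (p0 / (1 - p0))
    pval = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    return prop, float(odds), pval


def prediction_correlation_bins(
    pairs: pd.DataFrame,
    score_cuts=(-0.1, -0.2, -0.3, -0.4, -0.5, -0.6, -0.7, -0.8, -0.9),
    rec_cuts=(-1.0, -0.5, -0.25, 0.0, 0.25, 0.5, 1.0),
) -> BinGrid:
    """Cumulative score thresholds crossed with correlation bins.

    Score cuts are nested: row "<c" contains every pair with
    score < c, so counts are monotone non-increasing down the rows.
    REC bins are half-open intervals over ``rec_cuts``.
    """
    cuts = list(score_cuts)
    if any(b >= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("score_cuts must be strictly descending")
    edges = list(rec_cuts)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("rec_cuts must be strictly ascending")
    valid = pairs.dropna(subset=["rec"])
    rec_bin = pd.cut(valid["rec"], bins=edges, include_lowest=True)
    cats = rec_bin.cat.categories
    rows = [f"<{c:g}" for c in cuts]
    counts = pd.DataFrame(0, index=rows, columns=cats.astype(str))
    tf_counts = counts.copy()
    for c, row in zip(cuts, rows):
        in_cut = valid["score"] < c
        tab = rec_bin[in_cut].value_counts().reindex(cats, fill_value=0)
        tft = (
            rec_bin[in_cut & valid["is_tf"]].value_counts().reindex(cats, fill_value=0)
        )
        counts.loc[row] = tab.to_numpy()
        tf_counts.loc[row] = tft.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = tf_counts / counts
    background = float(valid["is_tf"].mean())
    return BinGrid(
        counts=counts,
        tf_counts=tf_counts,
        tf_proportion=prop,
        background_tf_proportion=background,
    )
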