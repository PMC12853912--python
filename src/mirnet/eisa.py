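"""Exon-intron split analysis (EISA).

Intronic reads come from nascent pre-mRNA, so a change in intronic
coverage (dI) reflects transcriptional regulation, while the exonic
change (dE) is the sum of transcriptional and post-transcriptional
regulation. The post-transcriptional component is therefore dE - dI.
The two layers are normalised independently (their library compositions
differ) and the same linear-model contrast is applied to each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable, LogExpression, design_groups
from .models import DesignMatrix, contrast_test, fit_gene_models, moderate_variances
from .prep import cpm_matrix, tmm_factors


@dataclass
class EisaPrepared:
    exonic: LogExpression
    intronic: LogExpression
    n_dropped: int


@dataclass
class EisaResult:
    """Per-gene dE, dI and dPT = dE - dI (log2) for one contrast."""

    table: pd.DataFrame  # columns: dE, dI, dPT [, class]
    contrast_name: str = ""


def eisa_prepare(
    exonic: CountTable,
    intronic: CountTable,
    min_count: int = 5,
    min_samples: int = 2,
    normalize: bool = True,
) -> EisaPrepared:
    """Intersect layers and keep genes detected in both.

    A gene is retained only if it has >= min_count reads in
    >= min_samples samples in BOTH layers (intronless or silent genes
    drop out here). Each layer then gets its own TMM factors and
    log2-CPM; the dropped-gene count is recorded.
    """
    if not exonic.sample_ids.equals(intronic.sample_ids):
        common = exonic.sample_ids.intersection(intronic.sample_ids)
        if len(common) == 0:
            raise ValueError("exonic and intronic tables share no samples")
        exonic = CountTable(exonic.counts[common], layer="exonic")
        intronic = CountTable(intronic.counts[common], layer="intronic")
    shared = exonic.gene_ids.intersection(intronic.gene_ids)
    n_universe = len(exonic.gene_ids.union(intronic.gene_ids))
    ex = exonic.counts.loc[shared]
    iv = intronic.counts.loc[shared]
    ok = ((ex >= min_count).sum(axis=1) >= min_samples) & (
        (iv >= min_count).sum(axis=1) >= min_samples
    )
    ex, iv = ex.loc[ok], iv.loc[ok]
    exonic_t = CountTable(ex, layer="exonic")
    intronic_t = CountTable(iv, layer="intronic")
    nf_e = tmm_factors(exonic_t) if normalize else None
    nf_i = tmm_factors(intronic_t) if normalize else None
    return EisaPrepared(
        exonic=cpm_matrix(exonic_t, nf_e, log=True),
        intronic=cpm_matrix(intronic_t, nf_i, log=True),
        n_dropped=n_universe - int(ok.sum()),
    )


def _group_mean_delta(
    logexpr: LogExpression, design: pd.DataFrame, group_a: str, group_b: str
) -> pd.Series:
    groups = design_groups(design)
    in_a = logexpr.sample_ids[groups.reindex(logexpr.sample_ids) == group_a]
    in_b = logexpr.sample_ids[groups.reindex(logexpr.sample_ids) == group_b]
    return logexpr.values[in_a].mean(axis=1) - logexpr.values[in_b].mean(axis=1)


def eisa_contrast(
    prepared: EisaPrepared,
    design: DesignMatrix,
    contrast: np.ndarray,
    name: str = "",
) -> EisaResult:
    """dE and dI as the contrast logFCs of the two layers; dPT = dE - dI."""
    fit_e = moderate_variances(fit_gene_models(prepared.exonic, design))
    fit_i = moderate_variances(fit_gene_models(prepared.intronic, design))
    de = contrast_test(fit_e, contrast).table["logFC"]
    di = contrast_test(fit_i, contrast).table["logFC"]
    table = pd.DataFrame({"dE": de, "dI": di})
    table["dPT"] = table["dE"] - table["dI"]
    return EisaResult(table=table, contrast_name=name)


def eisa_group_means(
    prepared: EisaPrepared,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    name: str = "",
) -> EisaResult:
    """Group-mean variant of the contrast (exact on noise-free data)."""
    de = _group_mean_delta(prepared.exonic, design, group_a, group_b)
    di = _group_mean_delta(prepared.intronic, design, group_a, group_b)
    table = pd.DataFrame({"dE": de, "dI": di})
    table["dPT"] = table["dE"] - table["dI"]
    return EisaResult(table=table, contrast_name=name or f"{group_a}-{group_b}")


def classify_regulation(
    result: EisaResult, fc_threshold: float = 0.585, dominance_ratio: float = 2.0
) -> EisaResult:
    """Label genes transcriptional / post_transcriptional / mixed / none.

    ``transcriptional``: |dI| >= fc_threshold and |dI| >= ratio * |dPT|;
    ``post_transcriptional`` symmetric; ``mixed`` when both components
    clear the threshold without dominance; ``none`` otherwise. This is a
    display convenience — the underlying magnitudes are the result.
    """
    t = result.table
    ai, apt = t["dI"].abs(), t["dPT"].abs()
    big_i, big_pt = ai >= fc_threshold, apt >= fc_threshold
    cls = pd.Series("none", index=t.index, name="class")
    cls[big_i & (ai >= dominance_ratio * apt)] = "transcriptional"
    cls[big_pt & (apt >= dominance_ratio * ai)] = "post_transcriptional"
    both = big_i & big_pt & (ai < dominance_ratio * apt) & (apt < dominance_ratio * ai)
    cls[both] = "mixed"
    out = t.copy()
    out["class"] = cls
    return EisaResult(table=out, contrast_name=result.contrast_name)
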