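"""Gene-wise linear models with precision weights and empirical-Bayes
variance moderation.

The experiment is a 3 (ZEB background) x 2 (miR treatment) factorial
with a replicate batch. Two equivalent parameterizations are offered:

* ``combined`` — one indicator per (background, mir) group (cell-means
  coding) plus batch, plus a no-dox offset when no-dox controls exist;
* ``interaction`` — intercept, miR main effect, background dummies and
  background:miR interaction terms, plus the same nuisance columns.

Both span the same column space; the interaction terms measure how much
the miR response differs when the TF is restored.

Moderation follows the scaled-inverse-chi-square empirical-Bayes recipe:
the prior (d0, s0^2) is estimated by moment-matching of log s^2 using
digamma/trigamma inversion, and each gene's variance is shrunk to
``(d0 s0^2 + d s^2) / (d0 + d)``; moderated t statistics gain d0 degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import (
    BACKGROUNDS,
    CountTable,
    LogExpression,
    MIR_LEVELS,
    NormFactors,
    design_groups,
    group_label,
)


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame  # sample x p
    model_tag: str

    def __post_init__(self) -> None:
        x = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def columns(self) -> pd.Index:
        return self.matrix.columns


@dataclass
class GeneFit:
    """Per-gene weighted least-squares fits (+ optional moderation)."""

    coef: pd.DataFrame  # gene x p
    cov_unscaled: np.ndarray  # gene x p x p (or 1 x p x p when shared)
    sigma2: pd.Series
    df_resid: float
    design: DesignMatrix
    weights: np.ndarray | None = None
    sigma2_post: pd.Series | None = None
    df_prior: float | None = None
    s2_prior: float | None = None


@dataclass
class ContrastResult:
    table: pd.DataFrame  # gene x (logFC, t, p, q)
    contrast: np.ndarray
    df_total: float


def build_design(design: pd.DataFrame, model: str = "combined") -> DesignMatrix:
    """Build the combined (cell-means) or interaction design matrix."""
    groups = design_groups(design)
    dox = design["dox"].astype(int) if "dox" in design else pd.Series(1, design.index)
    core = design.loc[dox == 1]
    for background in BACKGROUNDS:
        for mir in MIR_LEVELS:
            n = int(((core["background"] == background) & (core["mir"] == mir)).sum())
            if n == 0:
                raise ValueError(
                    f"design has no samples for group {group_label(background, mir)}"
                )
    cols = {}
    if model == "combined":
        for background in BACKGROUNDS:
            for mir in MIR_LEVELS:
                g = group_label(background, mir)
                cols[g] = (
                    (design["background"] == background) & (design["mir"] == mir)
                ).astype(float)
    elif model == "interaction":
        mir = (design["mir"] == "mir200c").astype(float)
        endog = (design["background"] == "endogZEB").astype(float)
        oex = (design["background"] == "oexZEB").astype(float)
        cols["intercept"] = pd.Series(1.0, index=design.index)
        cols["mir"] = mir
        cols["endogZEB"] = endog
        cols["oexZEB"] = oex
        cols["endogZEB:mir"] = endog * mir
        cols["oexZEB:mir"] = oex * mir
    else:
        raise ValueError(f"unknown model {model!r}")
    if design["batch"].nunique() > 1:
        cols["batch2"] = (design["batch"].astype(int) == 2).astype(float)
    if (dox == 0).any():
        cols["nodox"] = (dox == 0).astype(float)
    mat = pd.DataFrame(cols, index=design.index)
    return DesignMatrix(mat, model_tag=model)


def voom_weights(
    counts: CountTable,
    norm_factors: NormFactors | None,
    design: DesignMatrix,
    span: float = 0.5,
) -> np.ndarray:
    """Precision weights from the mean-variance trend of log-CPM counts.

    Fits each gene by OLS on log2-CPM, smooths sqrt(residual sd) against
    average log2 count with lowess, evaluates the trend at each fitted
    log2 count, and returns trend^-4 as observation weights. The trend
    is clamped at its boundary values outside the fitted range.
    """
    x = design.matrix.to_numpy(dtype=float)
    n, p = x.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    mat = counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    f = (
        norm_factors.factors.reindex(counts.sample_ids).to_numpy(dtype=float)
        if norm_factors is not None
        else np.ones_like(lib)
    )
    eff = lib * f
    y = np.log2((mat + 0.5) / (eff + 1.0)[None, :] * 1e6)

    pinv = np.linalg.pinv(x)
    coef = y @ pinv.T
    fitted = coef @ x.T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    amean = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sigma)

    ok = sigma > 0
    trend = lowess(sqrt_sd[ok], amean[ok], frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    fitted_logcount = fitted + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty, left=ty[0], right=ty[-1])
    w = pred**-4.0
    if not np.isfinite(w).all() or (w <= 0).any():
        raise ValueError("non-finite precision weights")
    return w


def fit_gene_models(
    y: LogExpression | pd.DataFrame,
    design: DesignMatrix,
    weights: np.ndarray | None = None,
) -> GeneFit:
    """Weighted least squares per gene.

    ``weights`` is a gene x sample matrix of observation weights (from
    :func:`voom_weights`) or None for ordinary least squares.
    """
    values = y.values if isinstance(y, LogExpression) else y
    ymat = values.to_numpy(dtype=float)
    x = design.matrix.to_numpy(dtype=float)
    n, p = x.shape
    if ymat.shape[1] != n:
        raise ValueError("expression and design sample counts differ")
    df_resid = n - p
    if weights is None:
        xtx_inv = np.linalg.inv(x.T @ x)
        coef = ymat @ (xtx_inv @ x.T).T
        resid = ymat - coef @ x.T
        sigma2 = (resid**2).sum(axis=1) / df_resid
        cov = xtx_inv[None, :, :]
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != ymat.shape:
            raise ValueError("weights must be gene x sample")
        xtwx = np.einsum("ni,gn,nj->gij", x, w, x)
        xtwy = np.einsum("ni,gn->gi", x, w * ymat)
        cov = np.linalg.inv(xtwx)
        coef = np.einsum("gij,gj->gi", cov, xtwy)
        resid = ymat - coef @ x.T
        sigma2 = np.einsum("gn,gn->g", w, resid**2) / df_resid
    return GeneFit(
        coef=pd.DataFrame(coef, index=values.index, columns=design.columns),
        cov_unscaled=cov,
        sigma2=pd.Series(sigma2, index=values.index, name="sigma2"),
        df_resid=float(df_resid),
        design=design,
        weights=weights,
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(fit: GeneFit) -> GeneFit:
    """Empirical-Bayes shrinkage of the residual variances.

    Moment-matches log s^2 to a scaled F distribution: with
    e_g = log(s_g^2) - digamma(d/2) + log(d/2), the prior df solves
    trigamma(d0/2) = var(e) - trigamma(d/2) and
    s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2)). Under-dispersed
    log-variances give d0 = +inf and every gene shrinks fully to s0^2.
    """
    s2 = fit.sigma2.to_numpy(dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 genes to estimate the prior")
    d = fit.df_resid
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean, evar = float(np.mean(e)), float(np.var(e, ddof=1))
    target = evar - special.polygamma(1, d / 2.0)
    if target > 0:
        df_prior = 2.0 * trigamma_inverse(target)
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
        s2_post = (df_prior * s2_prior + d * s2) / (df_prior + d)
    else:
        # under-dispersed log-variances: infinite prior df, fully pooled
        df_prior = np.inf
        s2_prior = float(np.mean(s2[ok]))
        s2_post = np.full_like(s2, s2_prior)
    fit.sigma2_post = pd.Series(s2_post, index=fit.sigma2.index, name="sigma2_post")
    fit.df_prior = float(df_prior)
    fit.s2_prior = s2_prior
    return fit


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def contrast_test(fit: GeneFit, contrast: np.ndarray) -> ContrastResult:
    """Moderated t-test of c'b = 0 with BH-adjusted q-values."""
    c = np.asarray(contrast, dtype=float)
    p_cols = fit.coef.shape[1]
    if c.shape != (p_cols,):
        raise ValueError(f"contrast must have length {p_cols}")
    if fit.sigma2_post is None:
        fit = moderate_variances(fit)
    logfc = fit.coef.to_numpy() @ c
    cvc = np.einsum("i,gij,j->g", c, fit.cov_unscaled, c)
    if fit.cov_unscaled.shape[0] == 1:
        cvc = np.repeat(cvc, len(logfc))
    s2 = fit.sigma2_post.to_numpy()
    se = np.sqrt(s2 * cvc)
    t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
    df_total = fit.df_resid + (fit.df_prior or 0.0)
    if np.isinf(df_total):
        pval = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pval = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    q = bh_adjust(pval)
    table = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": pval, "q": q}, index=fit.coef.index
    )
    return ContrastResult(table=table, contrast=c, df_total=float(df_total))


def group_contrast(design: DesignMatrix, group_a: str, group_b: str) -> np.ndarray:
    """Contrast vector for group_a - group_b under the combined model."""
    if design.model_tag != "combined":
        raise ValueError("group contrasts require the combined parameterization")
    c = np.zeros(len(design.columns))
    c[design.columns.get_loc(group_a)] = 1.0
    c[design.columns.get_loc(group_b)] = -1.0
    return c


def named_contrast(design: DesignMatrix, name: str) -> np.ndarray:
    """Standard contrasts by name.

    combined model: ``mir_in_parental``, ``mir_in_endogZEB``,
    ``mir_in_oexZEB``, ``endogZEB_vs_parental``, ``oexZEB_vs_parental``
    (the last two within ctrl-treated samples).
    interaction model: any single column name (e.g. ``mir``,
    ``endogZEB:mir``).
    """
    if design.model_tag == "interaction":
        c = np.zeros(len(design.columns))
        c[design.columns.get_loc(name)] = 1.0
        return c
    table = {
        "mir_in_parental": ("parental:mir200c", "parental:ctrl"),
        "mir_in_endogZEB": ("endogZEB:mir200c", "endogZEB:ctrl"),
        "mir_in_oexZEB": ("oexZEB:mir200c", "oexZEB:ctrl"),
        "endogZEB_vs_parental": ("endogZEB:ctrl", "parental:ctrl"),
        "oexZEB_vs_parental": ("oexZEB:ctrl", "parental:ctrl"),
    }
    if name not in table:
        raise ValueError(f"unknown contrast {name!r}")
    return group_contrast(design, *table[name])
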