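"""Normalisation, filtering and batch-adjustment primitives.

TMM (trimmed mean of M-values) composition-robust scale factors, linear
and log2 CPM, expression filters, linear-model batch removal and the
midpoint centring used for heatmaps. The sample (n-1) standard
deviation convention is used throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountTable, LogExpression, NormFactors

logger = logging.getLogger(__name__)


def _pick_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    """Sample whose upper-quartile CPM is closest to the mean upper quartile."""
    uq = np.percentile(counts / lib[None, :] * 1e6, 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one library against the reference.

    M values are doubly trimmed (trim_m of M, trim_a of A) and averaged
    with inverse delta-method binomial variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M on the log2 scale
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: CountTable,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1."""
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = counts.sample_ids[np.flatnonzero(lib == 0)[0]]
        raise ValueError(f"sample {bad!r} has zero total count")
    if ref_sample is None:
        ref_idx = _pick_reference(mat, lib)
    else:
        ref_idx = counts.sample_ids.get_loc(ref_sample)
    f = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(pd.Series(f, index=counts.sample_ids, name="tmm"))


def cpm_matrix(
    counts: CountTable,
    norm_factors: NormFactors | None = None,
    log: bool = False,
    prior_count: float = 0.5,
):
    """Counts per million, linear or log2.

    Linear: ``counts / (libsize * f) * 1e6`` (columns of an f=1 matrix
    sum to 1e6). Log: the library-size-scaled prior convention — with
    effective library L_s = libsize_s * f_s and per-sample prior
    pc_s = prior_count * L_s / mean(L),

        log2cpm = log2((y + pc_s) / (L_s + 2 * pc_s) * 1e6).
    """
    mat = counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if norm_factors is not None:
        f = norm_factors.factors.reindex(counts.sample_ids).to_numpy(dtype=float)
        if (f <= 0).any() or np.isnan(f).any():
            raise ValueError("non-positive or missing normalisation factor")
    else:
        f = np.ones_like(lib)
    eff = lib * f
    if not log:
        vals = mat / eff[None, :] * 1e6
        return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    pc = prior_count * eff / eff.mean()
    vals = np.log2((mat + pc[None, :]) / (eff + 2 * pc)[None, :] * 1e6)
    return LogExpression(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        prior_count=prior_count,
        norm_factors=norm_factors,
    )


def filter_expressed(
    counts: CountTable, min_cpm: float = 1.0, min_samples: int = 2
) -> CountTable:
    """Keep genes with CPM >= min_cpm (raw library sizes) in >= min_samples."""
    if min_samples > counts.counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    cpm = cpm_matrix(counts, None, log=False)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return CountTable(counts.counts.loc[keep], layer=counts.layer)


def _batch_columns(batch: pd.Series) -> np.ndarray:
    """Sum-to-zero coding of the batch factor (mean-preserving removal)."""
    levels = pd.unique(batch)
    if len(levels) < 2:
        return np.zeros((len(batch), 0))
    cols = []
    for lev in levels[:-1]:
        col = (batch == lev).astype(float) - (batch == levels[-1]).astype(float)
        cols.append(col.to_numpy())
    return np.column_stack(cols)


def remove_batch_effect(
    logexpr: LogExpression, batch: pd.Series, design: pd.DataFrame | None = None
) -> LogExpression:
    """Subtract the fitted batch component, keeping the design effects.

    Fits, per gene, a linear model with the retained design columns plus
    sum-coded batch indicators and subtracts only the batch part.
    Idempotent; a single batch level is the identity transform.
    """
    y = logexpr.values.to_numpy()
    batch = batch.reindex(logexpr.sample_ids)
    b = _batch_columns(batch)
    if b.shape[1] == 0:
        return LogExpression(
            logexpr.values.copy(), logexpr.prior_count, logexpr.norm_factors
        )
    if design is not None:
        x = np.asarray(design.loc[logexpr.sample_ids], dtype=float)
    else:
        x = np.ones((y.shape[1], 1))
    full = np.hstack([x, b])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("batch is confounded with the retained design")
    coef, *_ = np.linalg.lstsq(full, y.T, rcond=None)
    gamma = coef[x.shape[1] :, :]
    adjusted = y - (b @ gamma).T
    return LogExpression(
        pd.DataFrame(adjusted, index=logexpr.gene_ids, columns=logexpr.sample_ids),
        logexpr.prior_count,
        logexpr.norm_factors,
    )


def midpoint_scale(logexpr) -> pd.DataFrame:
    """Centre each gene by (max+min)/2, scale by its sample sd.

    Constant rows become zeros (with a warning); every output row
    satisfies max + min = 0.
    """
    values = logexpr.values if isinstance(logexpr, LogExpression) else logexpr
    y = values.to_numpy(dtype=float)
    mid = (y.max(axis=1) + y.min(axis=1)) / 2.0
    sd = y.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance genes set to zero rows", int(zero.sum()))
    sd_safe = np.where(zero, 1.0, sd)
    out = (y - mid[:, None]) / sd_safe[:, None]
    out[zero] = 0.0
    return pd.DataFrame(out, index=values.index, columns=values.columns)
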