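"""Signed weighted co-expression network construction and module detection.

The pipeline follows the weighted-correlation-network recipe: a signed
adjacency ``a_ij = ((1 + cor)/2)^beta`` with soft power beta = 16, the
topological overlap measure (TOM) as a smoothed similarity, average
linkage on 1 - TOM, a static adaptive cut of the dendrogram with
kME-based rescue of small branches (a simplified form of hybrid dynamic
branch cutting with deep split 0), eigengene-based module merging, and
Cytoscape-style edge export above a TOM threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDE_PREFIXES = ("SNOR", "SCARN", "RNU", "MIR")


@dataclass
class EigengeneSet:
    """Module x sample eigengene matrix plus variance explained."""

    me: pd.DataFrame  # module x sample, unit-norm rows
    variance_explained: pd.Series
    orientation: pd.Series  # +1/-1 sign applied to the raw PC


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module label, 0 = unassigned
    merge_history: list = field(default_factory=list)

    def sizes(self) -> pd.Series:
        lab = self.labels[self.labels != 0]
        return lab.value_counts()


def select_network_genes(
    logexpr,
    min_cpm: float = 4.0,
    min_samples: int = 2,
    top_n: int = 3000,
    name_exclude_prefixes=DEFAULT_EXCLUDE_PREFIXES,
) -> list:
    """Gene selection for the network.

    Excludes noisy noncoding classes by name prefix, requires
    log2-CPM >= log2(min_cpm) in >= min_samples samples, then ranks by
    the robust range (second-highest minus second-lowest expression) and
    keeps the top_n most variable genes.
    """
    df = logexpr if isinstance(logexpr, pd.DataFrame) else logexpr.values
    keep = ~df.index.str.upper().str.startswith(tuple(name_exclude_prefixes))
    df = df.loc[keep]
    expressed = (df >= np.log2(min_cpm)).sum(axis=1) >= min_samples
    df = df.loc[expressed]
    y = np.sort(df.to_numpy(), axis=1)
    robust_range = y[:, -2] - y[:, 1]
    if top_n >= len(df):
        if top_n > len(df):
            logger.warning("top_n=%d exceeds %d available genes", top_n, len(df))
        return list(df.index)
    order = np.argsort(-robust_range, kind="mergesort")[:top_n]
    return list(df.index[np.sort(order)])


def signed_adjacency(expr: pd.DataFrame, beta: float = 16.0) -> pd.DataFrame:
    """a_ij = ((1 + cor(x_i, x_j)) / 2)^beta with unit diagonal."""
    y = expr.to_numpy(dtype=float)
    sd = y.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance gene {bad!r}")
    c = np.corrcoef(y)
    a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    s = a @ a
    # remove the u=i and u=j terms (diagonal of a is 1)
    d = np.diag(a)
    num = s - d[:, None] * a - a * d[None, :] + a
    k = a.sum(axis=1) - d
    denom = np.minimum(k[:, None], k[None, :]) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def tom_dissimilarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    return 1.0 - tom_similarity(adjacency)


def average_linkage_tree(diss: pd.DataFrame) -> np.ndarray:
    d = diss.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def eigengenes(expr: pd.DataFrame, labels: pd.Series) -> EigengeneSet:
    """First principal component per module, oriented along the module mean.

    Gene profiles are z-scored across samples first; the eigengene is
    the unit-norm leading right singular vector, sign-flipped so that it
    correlates positively with the module's mean expression profile.
    """
    labels = labels.reindex(expr.index)
    me_rows, varexp, orient = {}, {}, {}
    for mod in sorted(set(labels[labels != 0])):
        sub = expr.loc[labels == mod].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        v1 = vt[0]
        mean_profile = z.mean(axis=0)
        sign = 1.0 if np.dot(v1, mean_profile) >= 0 else -1.0
        me_rows[mod] = sign * v1
        varexp[mod] = float(s[0] ** 2 / (s**2).sum())
        orient[mod] = sign
    me = pd.DataFrame(me_rows, index=expr.columns).T
    me.index.name = "module"
    return EigengeneSet(
        me=me,
        variance_explained=pd.Series(varexp, name="variance_explained"),
        orientation=pd.Series(orient, name="orientation"),
    )


def kme_matrix(expr: pd.DataFrame, me: EigengeneSet | pd.DataFrame) -> pd.DataFrame:
    """Module membership: cor(gene expression, module eigengene)."""
    me_df = me.me if isinstance(me, EigengeneSet) else me
    y = expr.to_numpy(dtype=float)
    yc = y - y.mean(axis=1, keepdims=True)
    ys = np.sqrt((yc**2).sum(axis=1))
    m = me_df.to_numpy(dtype=float)
    mc = m - m.mean(axis=1, keepdims=True)
    ms = np.sqrt((mc**2).sum(axis=1))
    num = yc @ mc.T
    den = np.outer(ys, ms)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(k, index=expr.index, columns=me_df.index)


def gene_significance(expr: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """Correlation of each gene with a sample trait (ZEB level, miR flag)."""
    t = trait.reindex(expr.columns).to_numpy(dtype=float)
    if np.std(t) == 0:
        raise ValueError("trait is constant")
    y = expr.to_numpy(dtype=float)
    yc = y - y.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    den = np.sqrt((yc**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        gs = np.where(den > 0, yc @ tc / den, np.nan)
    return pd.Series(gs, index=expr.index, name="GS")


def zeb_trait(design: pd.DataFrame) -> pd.Series:
    level = design["background"].map({"parental": 0, "endogZEB": 1, "oexZEB": 2})
    return level.astype(float).rename("zeb_level")


def mir_trait(design: pd.DataFrame) -> pd.Series:
    return (design["mir"] == "mir200c").astype(float).rename("mir_level")


def dynamic_cut(
    tree: np.ndarray,
    diss: pd.DataFrame,
    min_size: int = 10,
    deep_split: int = 0,
    expr: pd.DataFrame | None = None,
    kme_floor: float = 0.3,
    cut_height: float | None = None,
    cut_quantile: float = 0.99,
) -> ModuleAssignment:
    """Static adaptive cut with kME rescue of sub-minimum branches.

    The dendrogram is cut at the ``cut_quantile`` quantile of merge
    heights (or at an explicit ``cut_height``). Cutting inside the top
    tail of merge heights deliberately over-fragments; fragments are
    then consolidated by :func:`merge_close_modules`, which approximates
    the adaptive behaviour of hybrid dynamic branch cutting.
    Branches below the cut with >= min_size members become modules
    (labelled 1.. in decreasing size); smaller branches are dissolved
    and their genes reassigned to the module of highest kME when that
    kME >= kme_floor (requires ``expr``), otherwise left unassigned (0).
    Only deep_split = 0 semantics are implemented.
    """
    if deep_split != 0:
        raise NotImplementedError("only deep_split=0 is implemented")
    if np.isnan(diss.to_numpy()).any():
        raise ValueError("dissimilarity contains NaN")
    heights = tree[:, 2]
    if cut_height is None:
        cut_height = float(np.quantile(heights, cut_quantile))
    raw = fcluster(tree, t=cut_height, criterion="distance")
    raw = pd.Series(raw, index=diss.index)
    sizes = raw.value_counts()
    big = sizes[sizes >= min_size].index
    order = sizes.loc[big].sort_values(ascending=False).index
    relabel = {old: i + 1 for i, old in enumerate(order)}
    labels = raw.map(lambda c: relabel.get(c, 0)).astype(int)
    dissolved = labels.index[labels == 0]
    if len(dissolved) and len(order) and expr is not None:
        me = eigengenes(expr, labels)
        kme = kme_matrix(expr.loc[dissolved], me)
        best = kme.idxmax(axis=1)
        best_val = kme.max(axis=1)
        ok = best_val >= kme_floor
        labels.loc[dissolved[ok.to_numpy()]] = best[ok].astype(int)
    return ModuleAssignment(labels=labels.rename("module"))


def merge_close_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    diss_threshold: float = 0.25,
    manual_map: dict | None = None,
) -> ModuleAssignment:
    """Merge modules whose eigengenes are closer than ``diss_threshold``.

    Iteratively merges the closest pair with 1 - cor(ME_a, ME_b) below
    the threshold (the smaller module takes the larger one's label),
    recomputing eigengenes after each merge; then applies any explicit
    ``manual_map`` relabelings verbatim.
    """
    labels = assignment.labels.copy()
    history = list(assignment.merge_history)
    while True:
        mods = sorted(set(labels[labels != 0]))
        if len(mods) < 2:
            break
        me = eigengenes(expr, labels).me
        c = np.corrcoef(me.to_numpy())
        d = 1.0 - c
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= diss_threshold:
            break
        a, b = me.index[i], me.index[j]
        sizes = labels.value_counts()
        keep, drop = (a, b) if sizes[a] >= sizes[b] else (b, a)
        labels[labels == drop] = keep
        history.append((drop, keep, float(d[i, j])))
    if manual_map:
        known = set(labels.unique())
        for old in manual_map:
            if old not in known:
                raise ValueError(f"manual_map references unknown label {old!r}")
        labels = labels.map(lambda m: manual_map.get(m, m))
        history.extend((k, v, None) for k, v in manual_map.items())
    return ModuleAssignment(labels=labels, merge_history=history)


def discard_small_modules(
    assignment: ModuleAssignment, min_size: int = 50
) -> ModuleAssignment:
    """Drop modules below min_size (their genes become unassigned)."""
    labels = assignment.labels.copy()
    sizes = labels[labels != 0].value_counts()
    small = sizes[sizes < min_size].index
    labels[labels.isin(small)] = 0
    return ModuleAssignment(labels=labels, merge_history=list(assignment.merge_history))


def edge_export(
    tom: pd.DataFrame, assignment: ModuleAssignment, threshold: float = 0.1
) -> pd.DataFrame:
    """Undirected edges with TOM > threshold, each once, with module labels."""
    t = tom.to_numpy()
    iu, ju = np.triu_indices(t.shape[0], k=1)
    keep = t[iu, ju] > threshold
    genes = tom.index.to_numpy()
    src, tgt = genes[iu[keep]], genes[ju[keep]]
    swap = src > tgt
    src2 = np.where(swap, tgt, src)
    tgt2 = np.where(swap, src, tgt)
    lab = assignment.labels
    return pd.DataFrame(
        {
            "source": src2,
            "target": tgt2,
            "weight": t[iu[keep], ju[keep]],
            "source_module": lab.reindex(src2).to_numpy(),
            "target_module": lab.reindex(tgt2).to_numpy(),
        }
    ).sort_values(["source", "target"], ignore_index=True)


def network_pca(adjacency: pd.DataFrame, n_components: int = 2):
    """PCA of the (soft-powered) network matrix, genes as observations.

    Returns (coords gene x PC DataFrame, explained variance ratios).
    Used for the circular-structure check: gene angles are
    atan2(PC2, PC1) and the PC1+PC2 variance share measures how much of
    the network is a single two-dimensional continuum.
    """
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(adjacency.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=adjacency.index, columns=cols),
        np.asarray(pca.explained_variance_ratio_),
    )


def profile_pca(expr: pd.DataFrame, n_components: int = 2):
    """PCA of z-scored gene profiles (genes as observations).

    Each gene is standardized across samples first, so the leading
    components span the dominant shared response profiles; a gene's
    atan2(PC2, PC1) angle locates it on the regulatory continuum.
    """
    y = expr.to_numpy(dtype=float)
    mu = y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (y - mu) / sd
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(z)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=expr.index, columns=cols),
        np.asarray(pca.explained_variance_ratio_),
    )


def gene_angles(coords: pd.DataFrame) -> pd.Series:
    return pd.Series(
        np.mod(np.arctan2(coords["PC2"], coords["PC1"]), 2 * np.pi),
        index=coords.index,
        name="angle",
    )


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Rotation- and reflection-invariant circular alignment of two
    angle vectors: the mean resultant length of the pairwise angle
    differences, maximised over orientation,

        max(|mean exp(i(a - b))|, |mean exp(i(a + b))|).

    Equals 1 when a = +/-b + const and is ~n^-1/2 under independence.
    (Moment-based circular correlations that subtract circular means are
    undefined for ring-uniform marginals, the case of interest here.)
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    direct = np.abs(np.exp(1j * (a - b)).mean())
    reflected = np.abs(np.exp(1j * (a + b)).mean())
    return float(max(direct, reflected))
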