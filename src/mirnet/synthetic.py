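"""Ground-truth simulators for the miR-200/ZEB feedback analysis.

The generators plant the regulatory structure the downstream stages are
designed to detect: a miRNA that represses a transcription factor (TF)
post-transcriptionally, a TF that represses (or activates) downstream
programs transcriptionally, feed-forward combinations of the two, and
backgrounds in which the TF is restored at endogenous or elevated levels
so that its transcriptional arm escapes the miRNA.

Sample-level regulator activities
---------------------------------
Each sample carries a ZEB activity Z and a miR activity M:

* parental + ctrl       Z=1, M=0   (baseline mesenchymal state)
* parental + mir200c    Z=0, M=1   (miRNA knocks the TF down)
* endogZEB + any miR    Z=1        (transgene restores endogenous level)
* oexZEB + any miR      Z=2        (transgene over-expresses)

Gene classes map onto (Z, M) responses; intronic reads follow only the
transcriptional component, which is the identifying assumption of
exon-intron split analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BACKGROUNDS,
    GENE_CLASSES,
    MIR_LEVELS,
    CountTable,
    GroundTruth,
    PanelExpression,
    PeakSet,
    design_groups,
    group_label,
)

DEFAULT_CLASS_PROPORTIONS = {
    "direct_miR_PT": 0.10,
    "ZEB_repressed": 0.10,
    "ZEB_activated": 0.05,
    "coherent_FFL": 0.05,
    "incoherent_FFL": 0.05,
    "indirect": 0.15,
    "null": 0.50,
}

# (transcriptional log2 effect per unit of ZEB-activity change,
#  post-transcriptional log2 effect per unit of miR activity)
DEFAULT_EFFECT_SIZES = {
    "direct_miR_PT": (0.0, -1.0),
    "ZEB_repressed": (2.0, 0.0),
    "ZEB_activated": (1.5, 0.0),
    "coherent_FFL": (1.0, -1.0),
    "incoherent_FFL": (1.0, -1.0),
    "indirect": (1.0, 0.0),
    "null": (0.0, 0.0),
}

DEFAULT_TF_FRACTIONS = {c: 0.12 for c in GENE_CLASSES}
DEFAULT_TF_FRACTIONS["ZEB_repressed"] = 0.25
DEFAULT_TF_FRACTIONS["ZEB_activated"] = 0.25


@dataclass
class SimulationScheme:
    """Parameters of the count simulator (defaults are the study design)."""

    n_genes: int = 6000
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    dispersion: float = 0.05
    lib_size_range: tuple = (15_000_000, 25_000_000)
    batch_log2_shift: float = 0.3
    batch_gene_fraction: float = 0.3
    intron_fraction: float = 0.3
    tf_fraction_by_class: dict = field(
        default_factory=lambda: dict(DEFAULT_TF_FRACTIONS)
    )
    base_log2_range: tuple = (6.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.intron_fraction < 1:
            raise ValueError("intron_fraction must lie in (0, 1)")


def zeb_activity(background: str, mir: str, dox: int = 1) -> float:
    if dox == 0 or background == "parental":
        return 0.0 if mir == "mir200c" else 1.0
    return 1.0 if background == "endogZEB" else 2.0


def mir_activity(mir: str) -> float:
    return 1.0 if mir == "mir200c" else 0.0


def make_design(n_reps: int = 2, include_no_dox: bool = False) -> pd.DataFrame:
    """Factorial sample sheet: 3 ZEB backgrounds x 2 miR treatments.

    Returns ``6 * n_reps`` dox-induced samples (replicates alternate
    batch labels) plus, when requested, parental no-dox controls (one
    per miR treatment) that let the models estimate a dox term.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for background in BACKGROUNDS:
        for mir in MIR_LEVELS:
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{background}_{mir}_dox_r{rep}",
                        "background": background,
                        "mir": mir,
                        "dox": 1,
                        "batch": 1 + (rep - 1) % 2,
                    }
                )
    if include_no_dox:
        for i, mir in enumerate(MIR_LEVELS):
            rows.append(
                {
                    "sample_id": f"parental_{mir}_nodox",
                    "background": "parental",
                    "mir": mir,
                    "dox": 0,
                    "batch": 1 + i % 2,
                }
            )
    design = pd.DataFrame(rows).set_index("sample_id")
    return design


def _assign_classes(scheme: SimulationScheme, rng: np.random.Generator) -> pd.Series:
    classes = []
    counts = {
        c: int(round(scheme.class_proportions.get(c, 0.0) * scheme.n_genes))
        for c in GENE_CLASSES
    }
    # absorb rounding drift into the null class
    counts["null"] += scheme.n_genes - sum(counts.values())
    for c in GENE_CLASSES:
        classes.extend([c] * counts[c])
    genes = [f"G{i:05d}" for i in range(scheme.n_genes)]
    labels = pd.Series(classes, index=genes, name="gene_class")
    return labels


def planted_effects(
    scheme: SimulationScheme, design: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-group planted log2 effects relative to parental ctrl.

    Returns (class labels, delta_i, delta_pt) with one column per design
    group.
    """
    labels = _assign_classes(scheme, rng)
    groups = design_groups(design).unique()
    z0 = zeb_activity("parental", "ctrl")
    n = len(labels)
    indirect_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    di = pd.DataFrame(0.0, index=labels.index, columns=groups)
    dpt = pd.DataFrame(0.0, index=labels.index, columns=groups)
    sample_of_group = design.groupby(design_groups(design)).head(1)
    meta = dict(
        zip(
            design_groups(design).loc[sample_of_group.index],
            sample_of_group[["background", "mir", "dox"]].itertuples(index=False),
        )
    )
    for g in groups:
        background, mir, dox = meta[g]
        dz = zeb_activity(background, mir, dox) - z0
        m = mir_activity(mir)
        for cls, (tr, pt) in scheme.effect_sizes.items():
            mask = (labels == cls).to_numpy()
            if not mask.any():
                continue
            if cls == "ZEB_repressed":
                di.loc[mask, g] = -tr * dz
            elif cls == "ZEB_activated":
                di.loc[mask, g] = tr * dz
            elif cls == "coherent_FFL":
                di.loc[mask, g] = tr * dz
                dpt.loc[mask, g] = pt * m
            elif cls == "incoherent_FFL":
                di.loc[mask, g] = -tr * dz
                dpt.loc[mask, g] = pt * m
            elif cls == "indirect":
                di.loc[mask, g] = indirect_sign[mask] * 0.5 * tr * dz
            elif cls == "direct_miR_PT":
                dpt.loc[mask, g] = pt * m
    return labels, di, dpt


def _driver_basis(design: pd.DataFrame) -> np.ndarray:
    """Orthonormal (ZEB, miR) activity basis over the samples."""
    z = np.array(
        [
            zeb_activity(r.background, r.mir, int(r.dox))
            for r in design.itertuples(index=False)
        ],
        dtype=float,
    )
    m = np.array([mir_activity(r.mir) for r in design.itertuples(index=False)])
    basis = np.column_stack([z - z.mean(), m - m.mean()])
    q, _ = np.linalg.qr(basis)
    return q


def _theta_from_effects(
    design: pd.DataFrame, delta_e: pd.DataFrame, labels: pd.Series
) -> pd.Series:
    groups = design_groups(design)
    per_sample = delta_e[groups.to_numpy()].to_numpy()
    q = _driver_basis(design)
    proj = per_sample @ q  # genes x 2 (ZEB axis, miR axis)
    theta = np.mod(np.arctan2(proj[:, 1], proj[:, 0]), 2 * np.pi)
    theta = pd.Series(theta, index=delta_e.index, name="theta")
    theta[labels == "null"] = np.nan
    return theta


def _nb_draw(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB(mean mu, variance mu + dispersion*mu^2); dispersion 0 is the
    rounded deterministic mean, keeping noise-free oracles exact."""
    if dispersion == 0:
        return np.round(mu).astype(np.int64)
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p).astype(np.int64)


def simulate_counts(
    scheme: SimulationScheme, design: pd.DataFrame
) -> tuple[CountTable, CountTable, GroundTruth]:
    """Exonic + intronic NB count tables with planted regulation.

    Mean model per gene g, sample s (log2 scale):

        mu_E = base_g * 2^(dI + dPT + batch) * L_s / B
        mu_I = intron_fraction * base_g * 2^(dI + batch) * L_s / B

    where B is the total baseline abundance (fixed across samples so the
    planted log2 fold changes survive in the count means exactly) and
    batch is an additive log2 shift on a random subset of genes in
    batch 2. Post-transcriptional effects never touch the intronic layer.
    """
    if "dox" in design and int((design["dox"] == 1).sum()) == 0:
        raise ValueError("design has no dox-induced samples")
    rng = np.random.default_rng([int(scheme.seed) % (2**31), 101])
    labels, di, dpt = planted_effects(scheme, design, rng)
    groups = design_groups(design)
    base = 2.0 ** rng.uniform(*scheme.base_log2_range, size=scheme.n_genes)
    btot = base.sum()
    lib = rng.integers(
        scheme.lib_size_range[0], scheme.lib_size_range[1] + 1, size=len(design)
    ).astype(float)
    batch_mask = rng.random(scheme.n_genes) < scheme.batch_gene_fraction
    in_batch2 = (design["batch"].astype(int) == 2).to_numpy()

    di_s = di[groups.to_numpy()].to_numpy()
    dpt_s = dpt[groups.to_numpy()].to_numpy()
    batch_term = (
        scheme.batch_log2_shift * np.outer(batch_mask, in_batch2.astype(float))
    )
    mu_e = base[:, None] * 2.0 ** (di_s + dpt_s + batch_term) * (lib[None, :] / btot)
    mu_i = (
        scheme.intron_fraction
        * base[:, None]
        * 2.0 ** (di_s + batch_term)
        * (lib[None, :] / btot)
    )
    exonic = _nb_draw(mu_e, scheme.dispersion, rng)
    intronic = _nb_draw(mu_i, scheme.dispersion, rng)
    idx = labels.index
    cols = design.index
    tf_p = labels.map(lambda c: scheme.tf_fraction_by_class.get(c, 0.12)).to_numpy()
    is_tf = pd.Series(rng.random(scheme.n_genes) < tf_p, index=idx, name="is_tf")
    truth = GroundTruth(
        gene_class=labels,
        is_tf=is_tf,
        theta=_theta_from_effects(design, di + dpt, labels),
        delta_i=di,
        delta_pt=dpt,
    )
    return (
        CountTable(pd.DataFrame(exonic, index=idx, columns=cols), layer="exonic"),
        CountTable(pd.DataFrame(intronic, index=idx, columns=cols), layer="intronic"),
        truth,
    )


def simulate_panel(
    n_samples: int = 500,
    n_genes: int = 10_000,
    n_pairs: int = 10_000,
    n_planted: int = 50,
    planted_tf_fraction: float = 0.5,
    background_tf_fraction: float = 0.12,
    anticorrelation_strength: float = 0.9,
    n_mirnas: int = 50,
    seed: int = 0,
) -> tuple[PanelExpression, pd.DataFrame, pd.Series]:
    """CCLE-like panel with planted anti-correlated strong miRNA-target pairs.

    Planted pairs get prediction scores from the extreme negative tail
    and target expression ``-s * mirna + (1 - s) * noise`` where s is the
    anti-correlation strength; background pairs get weak scores and
    independent expression. Returns (panel, pair score table, truth).
    """
    if n_planted > n_pairs:
        raise ValueError("n_planted exceeds n_pairs")
    if n_pairs > n_genes:
        raise ValueError("need n_pairs <= n_genes for unique target genes")
    if not 0 <= anticorrelation_strength <= 1:
        raise ValueError("anticorrelation_strength must lie in [0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 202])
    samples = [f"CL{j:04d}" for j in range(n_samples)]
    mirnas = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    mexpr = rng.normal(size=(n_mirnas, n_samples))
    mirna_df = pd.DataFrame(mexpr, index=mirnas, columns=samples)

    genes = [f"T{i:05d}" for i in range(n_genes)]
    gexpr = rng.normal(size=(n_genes, n_samples))
    pair_mirna = np.array(mirnas)[rng.integers(0, n_mirnas, size=n_pairs)]
    pair_gene = np.array(genes[:n_pairs])
    planted = np.zeros(n_pairs, dtype=bool)
    planted[:n_planted] = True
    s = anticorrelation_strength
    for k in np.flatnonzero(planted):
        mi = mirnas.index(pair_mirna[k])
        gexpr[k] = -s * mexpr[mi] + (1.0 - s) * rng.normal(size=n_samples)
    genes_df = pd.DataFrame(gexpr, index=genes, columns=samples)

    score = -np.clip(rng.exponential(0.08, size=n_pairs), 0.0, 0.55)
    score[planted] = rng.uniform(-1.2, -0.6, size=n_planted)
    tf_p = np.where(planted, planted_tf_fraction, background_tf_fraction)
    is_tf = rng.random(n_pairs) < tf_p
    pairs = pd.DataFrame(
        {"mirna": pair_mirna, "gene": pair_gene, "score": score, "is_tf": is_tf}
    )
    truth = pd.Series(planted, index=pd.MultiIndex.from_arrays(
        [pair_mirna, pair_gene], names=["mirna", "gene"]
    ), name="planted")
    return PanelExpression(mirna=mirna_df, genes=genes_df), pairs, truth


def true_bound_set(truth: GroundTruth) -> set:
    """Genes transcriptionally bound by the TF in the planted model."""
    mask = truth.gene_class.isin(["ZEB_repressed", "ZEB_activated"])
    return set(truth.gene_class.index[mask])


def simulate_chip(
    truth: GroundTruth,
    n_sources: int = 3,
    sensitivity: float = 0.8,
    false_positive_rate: float = 0.05,
    seed: int = 0,
) -> list[PeakSet]:
    """Noisy ChIP peak sets around the true TF-bound genes.

    Each source includes true targets with probability ``sensitivity``
    and any other gene with probability ``false_positive_rate``; true
    targets carry higher peak scores on average.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= false_positive_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    bound = true_bound_set(truth)
    genes = truth.gene_class.index
    is_bound = genes.isin(bound)
    out = []
    for k in range(n_sources):
        rng = np.random.default_rng([int(seed) % (2**31), 303, k])
        p = np.where(is_bound, sensitivity, false_positive_rate)
        included = rng.random(len(genes)) < p
        scores = np.where(
            is_bound,
            rng.gamma(4.0, 2.0, size=len(genes)),
            rng.gamma(2.0, 1.5, size=len(genes)),
        )
        sel = pd.Series(scores[included], index=genes[included])
        sel = sel.clip(lower=1e-3)
        out.append(PeakSet(source=f"chip{k + 1}", scores=sel))
    return out


def simulate_ring(
    design: pd.DataFrame,
    n_genes: int = 3000,
    n_modules: int = 8,
    amplitude: float = 2.0,
    angle_sd: float = 0.1,
    dispersion: float = 0.05,
    base_log2_range: tuple = (6.0, 10.0),
    lib_size: float = 20_000_000,
    seed: int = 0,
) -> tuple[CountTable, pd.DataFrame]:
    """Genes on a ring of mixed miR/ZEB responses, grouped into modules.

    Each module sits at an angle on the circle spanned by the two
    orthonormalised regulator activity profiles; a gene's log2 response
    is ``amplitude * (cos(theta) u_Z + sin(theta) u_M)`` with a small
    per-gene angular jitter. This is the planted version of the circular
    regulatory continuum the network stage is expected to reveal.

    Returns the exonic count table and a truth frame (module, theta).
    """
    rng = np.random.default_rng([int(seed) % (2**31), 404])
    q = _driver_basis(design) * np.sqrt(len(design))
    centers = 2 * np.pi * (np.arange(n_modules) + 0.5) / n_modules
    module = rng.integers(0, n_modules, size=n_genes)
    theta = np.mod(centers[module] + rng.normal(0.0, angle_sd, size=n_genes), 2 * np.pi)
    profile = amplitude * (
        np.cos(theta)[:, None] * q[:, 0][None, :]
        + np.sin(theta)[:, None] * q[:, 1][None, :]
    )
    base = 2.0 ** rng.uniform(*base_log2_range, size=n_genes)
    mu = base[:, None] * 2.0**profile * (lib_size / base.sum())
    counts = _nb_draw(mu, dispersion, rng)
    genes = [f"R{i:05d}" for i in range(n_genes)]
    table = CountTable(
        pd.DataFrame(counts, index=genes, columns=design.index), layer="exonic"
    )
    truth = pd.DataFrame({"module": module + 1, "theta": theta}, index=genes)
    return table, truth
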