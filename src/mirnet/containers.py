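"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas objects: count tables and expression
matrices are gene x sample DataFrames, designs are one row per sample.
The thin dataclass wrappers below exist to carry the metadata the
analysis needs (layer identity, normalisation factors, prior counts) and
to validate invariants once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BACKGROUNDS = ("parental", "endogZEB", "oexZEB")
MIR_LEVELS = ("ctrl", "mir200c")

GENE_CLASSES = (
    "direct_miR_PT",
    "ZEB_repressed",
    "ZEB_activated",
    "coherent_FFL",
    "incoherent_FFL",
    "indirect",
    "null",
)


class FormatError(ValueError):
    """Raised when an external file violates its documented format."""


@dataclass
class CountTable:
    """Gene x sample matrix of non-negative integer read counts.

    ``layer`` distinguishes exonic from intronic quantification; both
    layers share gene/sample naming conventions but are normalised
    independently downstream.
    """

    counts: pd.DataFrame
    layer: str = "exonic"

    def __post_init__(self) -> None:
        if self.layer not in ("exonic", "intronic"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise FormatError("negative counts")
        if not np.issubdtype(vals.dtype, np.integer):
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise FormatError("non-integer counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormFactors:
    """Per-sample TMM scale factors, geometric mean constrained to 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if (f <= 0).any():
            raise ValueError("normalisation factors must be positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-8:
            self.factors = self.factors / gm


@dataclass
class LogExpression:
    """log2-CPM matrix plus the normalisation provenance that produced it."""

    values: pd.DataFrame
    prior_count: float = 0.5
    norm_factors: NormFactors | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("log expression must be finite")
        if self.prior_count <= 0:
            raise ValueError("prior_count must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class PanelExpression:
    """Expression bundle across a large cell panel (CCLE-like).

    ``mirna``: miRNA x sample matrix; ``genes``: gene x sample matrix.
    Values are on a log-like continuous scale; the screen only consumes
    ranks by default.
    """

    mirna: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mirna.columns.equals(self.genes.columns):
            raise ValueError("miRNA and gene matrices must share samples")


@dataclass
class PeakSet:
    """One ChIP-seq source: gene -> positive peak score."""

    source: str
    scores: pd.Series

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise FormatError(f"duplicate genes in peak set {self.source!r}")
        if self.scores.size and (self.scores.to_numpy(dtype=float) <= 0).any():
            raise ValueError("peak scores must be positive")

    @property
    def genes(self) -> set:
        return set(self.scores.index)


@dataclass
class GroundTruth:
    """Planted regulatory structure of a simulated experiment.

    ``delta_i`` / ``delta_pt`` are gene x group log2 effects relative to
    the parental control group; ``delta_e = delta_i + delta_pt`` by
    construction. ``theta`` is the gene's angle on the miR/ZEB response
    continuum (NaN for null genes).
    """

    gene_class: pd.Series
    is_tf: pd.Series
    theta: pd.Series
    delta_i: pd.DataFrame
    delta_pt: pd.DataFrame

    @property
    def delta_e(self) -> pd.DataFrame:
        return self.delta_i + self.delta_pt

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"gene_class": self.gene_class, "is_tf": self.is_tf, "theta": self.theta}
        )
        for g in self.delta_i.columns:
            out[f"dI[{g}]"] = self.delta_i[g]
            out[f"dPT[{g}]"] = self.delta_pt[g]
        return out


def group_label(background: str, mir: str) -> str:
    return f"{background}:{mir}"


def design_groups(design: pd.DataFrame) -> pd.Series:
    """(background, mir) group label per sample; no-dox samples get a
    ':nodox' suffix so they never merge with induced groups."""
    lab = design["background"].astype(str) + ":" + design["mir"].astype(str)
    if "dox" in design:
        lab = lab.where(design["dox"].astype(int) == 1, lab + ":nodox")
    return lab.rename("group")
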