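"""Readers and writers for every external table the pipeline touches.

Everything is plain UTF-8 TSV with no quoting. Gene identifiers are
opaque strings; no symbol/Ensembl mapping happens here. Readers reject
malformed input rather than coercing it, and every writer round-trips
through its paired reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CountTable, FormatError, PeakSet

logger = logging.getLogger(__name__)

# TargetScan v7.2 column names (tab-delimited flat files).
TS_SUMMARY_COLUMNS = {
    "gene": "Gene Symbol",
    "mirna": "Representative miRNA",
    "score": "Total context++ score",
    "species": "Species ID",
}
TS_FAMILY_COLUMNS = {
    "mirna": "MiRBase ID",
    "species": "Species ID",
}


def read_count_table(path, layer: str = "exonic") -> CountTable:
    """Read a gene x sample TSV (header = sample ids, first col = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dup)[-1]) + 2  # +1 header, +1 1-based
        raise FormatError(f"{path}: duplicate gene id {dup!r} at line {line}")
    mat = df.to_numpy()
    if not np.issubdtype(mat.dtype, np.number):
        raise FormatError(f"{path}: non-numeric count cell")
    if np.any(mat != np.floor(mat)):
        g, s = np.argwhere(mat != np.floor(mat))[0]
        raise FormatError(
            f"{path}: non-integer count {mat[g, s]!r} for gene {df.index[g]!r}"
        )
    if (mat < 0).any():
        raise FormatError(f"{path}: negative count")
    return CountTable(df.astype(np.int64), layer=layer)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="gene")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for col in ("dox", "batch"):
        if col in design:
            design[col] = design[col].astype(int)
    if design.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_targetscan_summary(
    summary_path,
    family_path=None,
    mirna_filter=None,
    species: str | None = "9606",
) -> pd.DataFrame:
    """Collapse TargetScan v7.2 predictions to one row per (miRNA, gene).

    Keeps the most negative "Total context++ score" across transcripts of
    a gene (the collapse rule is a package decision; TargetScan itself
    reports per-transcript scores). Rows with a non-numeric score (e.g.
    "NULL") are dropped with a logged count. ``family_path`` restricts to
    miRNAs annotated for ``species`` in miR_family_Info.txt;
    ``mirna_filter`` (iterable of MiRBase IDs) restricts further — an
    empty filter retains everything.
    """
    df = pd.read_csv(summary_path, sep="\t", dtype=str)
    for key in ("gene", "mirna", "score"):
        col = TS_SUMMARY_COLUMNS[key]
        if col not in df.columns:
            raise FormatError(f"{summary_path}: missing required column {col!r}")
    if species is not None and TS_SUMMARY_COLUMNS["species"] in df.columns:
        df = df[df[TS_SUMMARY_COLUMNS["species"]].astype(str) == str(species)]
    score = pd.to_numeric(df[TS_SUMMARY_COLUMNS["score"]], errors="coerce")
    n_bad = int(score.isna().sum())
    if n_bad:
        logger.warning("dropping %d TargetScan rows with non-numeric scores", n_bad)
    df = df.assign(score=score).dropna(subset=["score"])

    allowed = None
    if family_path is not None:
        fam = pd.read_csv(family_path, sep="\t", dtype=str)
        col = TS_FAMILY_COLUMNS["mirna"]
        if col not in fam.columns:
            raise FormatError(f"{family_path}: missing required column {col!r}")
        if species is not None and TS_FAMILY_COLUMNS["species"] in fam.columns:
            fam = fam[fam[TS_FAMILY_COLUMNS["species"]].astype(str) == str(species)]
        allowed = set(fam[col])
    if mirna_filter:
        wanted = set(mirna_filter)
        allowed = wanted if allowed is None else allowed & wanted
    if allowed is not None:
        df = df[df[TS_SUMMARY_COLUMNS["mirna"]].isin(allowed)]

    out = (
        df.groupby(
            [TS_SUMMARY_COLUMNS["mirna"], TS_SUMMARY_COLUMNS["gene"]], sort=True
        )["score"]
        .min()
        .reset_index()
    )
    out.columns = ["mirna", "gene", "score"]
    out["is_tf"] = False
    return out


def read_pair_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    required = {"mirna", "gene", "score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(["mirna", "gene"]).any():
        raise FormatError(f"{path}: duplicate (mirna, gene) pair")
    if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite score")
    if "is_tf" not in df.columns:
        df["is_tf"] = False
    df["is_tf"] = df["is_tf"].astype(bool)
    return df


def write_pair_scores(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> set:
    """One gene id per line; blank lines ignored; empty file -> empty set."""
    text = Path(path).read_text(encoding="utf-8")
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_gene_set(genes, path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8"
    )


def read_peak_set(path, source: str | None = None) -> PeakSet:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected (gene, score) columns")
    genes, scores = df.iloc[:, 0], pd.to_numeric(df.iloc[:, 1])
    return PeakSet(
        source=source or Path(path).stem,
        scores=pd.Series(scores.to_numpy(), index=pd.Index(genes, name="gene")),
    )


def write_peak_set(peaks: PeakSet, path) -> None:
    peaks.scores.rename("peak_score").to_csv(path, sep="\t", index_label="gene")


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["source", "target", "weight"]:
        raise FormatError(f"{path}: expected columns source, target, weight")
    return df


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Cytoscape-style TSV; each undirected edge once, source < target."""
    out = edges.copy()
    swap = out["source"] > out["target"]
    out.loc[swap, ["source", "target"]] = out.loc[swap, ["target", "source"]].to_numpy()
    out = out.drop_duplicates(["source", "target"]).sort_values(["source", "target"])
    out.to_csv(path, sep="\t", index=False)


def write_matrix(values: pd.DataFrame, path, index_label: str = "gene") -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
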