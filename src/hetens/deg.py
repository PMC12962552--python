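"""Differential-expression table input and the entry-gene filter.

Reads per-cluster DE result tables in the DESeq2 results dialect
(``gene``, ``cluster``, ``log2FoldChange``, ``padj``; names remappable) and
selects *entry genes*: significantly upregulated genes (adjusted p strictly
below 0.05 and log2 fold change strictly above 0 by default) that seed the
path search, one weight per (cluster, gene).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path as FsPath
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: canonical field -> default input column name (DESeq2 results naming)
DEFAULT_DEG_COLUMNS: dict[str, str] = {
    "gene": "gene",
    "cluster": "cluster",
    "log2fc": "log2FoldChange",
    "padj": "padj",
}

DEG_FIELDS = ("gene", "cluster", "log2fc", "padj")


def load_deg_table(
    path: str | FsPath, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a DE result TSV into the canonical ``gene/cluster/log2fc/padj`` frame.

    ``columns`` remaps canonical field names to input column names.  Rows with
    an unparseable or non-finite ``log2fc``, or a ``padj`` outside [0, 1], are
    dropped with a logged count; a missing/"NA" ``padj`` is kept as missing
    (it fails the strict significance test later).
    """
    colmap = dict(DEFAULT_DEG_COLUMNS)
    if columns:
        unknown = set(columns) - set(DEG_FIELDS)
        if unknown:
            raise FormatError(f"unknown DEG field(s) in column mapping: {sorted(unknown)}")
        colmap.update(columns)

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if colmap["gene"] not in df.columns:
        raise FormatError(f"{path}: no gene column {colmap['gene']!r} in header")
    if colmap["log2fc"] not in df.columns:
        raise FormatError(f"{path}: no log2 fold change column {colmap['log2fc']!r} in header")

    if colmap["cluster"] in df.columns:
        cluster = df[colmap["cluster"]].astype(str)
    else:
        logger.warning("%s: no cluster column %r; using single cluster 'all'", path, colmap["cluster"])
        cluster = pd.Series(["all"] * len(df), dtype=str)
    if colmap["padj"] in df.columns:
        padj = pd.to_numeric(df[colmap["padj"]].replace("", None), errors="coerce")
    else:
        logger.warning("%s: no padj column %r; all padj treated as missing", path, colmap["padj"])
        padj = pd.Series([np.nan] * len(df), dtype=float)

    out = pd.DataFrame(
        {
            "gene": df[colmap["gene"]].astype(str),
            "cluster": cluster,
            "log2fc": pd.to_numeric(df[colmap["log2fc"]].replace("", None), errors="coerce"),
            "padj": padj,
        }
    )
    n_in = len(out)
    keep = np.isfinite(out["log2fc"]) & (
        out["padj"].isna() | ((out["padj"] >= 0.0) & (out["padj"] <= 1.0))
    )
    out = out.loc[keep].reset_index(drop=True)
    if len(out) < n_in:
        logger.warning("%s: dropped %d unparseable/invalid row(s)", path, n_in - len(out))
    if out.empty:
        logger.warning("%s: no usable DE rows", path)
    return out


def canonicalize(df: pd.DataFrame, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Rename an in-memory DE frame from the input dialect to the canonical
    ``gene/cluster/log2fc/padj`` columns (no-op if already canonical)."""
    if all(f in df.columns for f in DEG_FIELDS):
        return df
    colmap = dict(DEFAULT_DEG_COLUMNS)
    if columns:
        colmap.update(columns)
    renames = {v: k for k, v in colmap.items() if v in df.columns and k not in df.columns}
    out = df.rename(columns=renames)
    missing = [f for f in ("gene", "log2fc") if f not in out.columns]
    if missing:
        raise FormatError(f"DE frame lacks required column(s): {missing}")
    if "cluster" not in out.columns:
        out = out.assign(cluster="all")
    if "padj" not in out.columns:
        out = out.assign(padj=np.nan)
    return out


def select_entries(
    rows: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 0.0
) -> pd.DataFrame:
    """Apply the entry filter: ``padj < padj_max`` and ``log2fc > lfc_min``.

    Both comparisons are strict; missing padj never passes.  Duplicate
    (cluster, gene) rows collapse to the larger log2fc with a warning.
    Returns a frame with columns ``gene``, ``cluster``, ``log2fc`` sorted by
    (cluster, gene).
    """
    if not (math.isfinite(padj_max) and math.isfinite(lfc_min)):
        raise FormatError("entry-filter thresholds must be finite")
    mask = rows["padj"].notna() & (rows["padj"] < padj_max) & (rows["log2fc"] > lfc_min)
    out = rows.loc[mask, ["gene", "cluster", "log2fc"]]
    n_dup = out.duplicated(subset=["cluster", "gene"]).sum()
    if n_dup:
        logger.warning(
            "collapsed %d duplicate (cluster, gene) entries, keeping max log2fc", n_dup
        )
        out = (
            out.groupby(["cluster", "gene"], as_index=False, sort=False)["log2fc"].max()
        )[["gene", "cluster", "log2fc"]]
    return out.sort_values(["cluster", "gene"], kind="mergesort").reset_index(drop=True)
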