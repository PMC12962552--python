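"""End Node Scores: per-type top-fraction filtering and log2fc weighting.

The pair-score table is first thinned to the strongest connections — within
each end-node type (and, by default, each cluster) only the top 5% of pairs
by DWPCpair survive — then each surviving pair is weighted by the log2 fold
change of its entry gene and summed per end node:

    ENS(cluster, end) = sum over retained pairs (entry -> end)
                        of log2fc(entry) * DWPCpair(entry, end).

Filtering sees only the pair scores, never the weights, so permuting the
log2fc values can change ENS magnitudes but never which pairs survive.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

logger = logging.getLogger(__name__)

FILTER_SCOPES = ("per_cluster", "pooled")

ENS_COLUMNS = ("cluster", "end", "end_type", "ens")


def filter_top_fraction(
    pairs: pd.DataFrame, frac: float = 0.05, scope: str = "per_cluster"
) -> pd.DataFrame:
    """Retain the top ``ceil(frac * n)`` pairs by DWPCpair per end-node type.

    With ``scope='per_cluster'`` each cluster's table is filtered
    independently; ``'pooled'`` groups across clusters.  Ties at the cutoff
    break by lexicographic (entry, end) order, so any nonempty group retains
    at least one pair and the result is reproducible.
    """
    if not (0 < frac <= 1) or not math.isfinite(frac):
        raise ConfigurationError(f"frac must be in (0, 1], got {frac}")
    if scope not in FILTER_SCOPES:
        raise ConfigurationError(f"scope must be one of {FILTER_SCOPES}, got {scope!r}")
    if pairs.empty:
        return pairs.copy()
    group_cols = ["end_type"] + (["cluster"] if scope == "per_cluster" else [])
    s = pairs.sort_values(
        ["dwpc_pair", "entry", "end"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    grp = s.groupby(group_cols, sort=False)
    n = grp["dwpc_pair"].transform("size").to_numpy()
    keep_n = np.ceil(frac * n).astype(int)
    rank = grp.cumcount().to_numpy()
    out = s.loc[rank < keep_n]
    return out.sort_values(
        ["cluster", "entry", "end"], kind="mergesort"
    ).reset_index(drop=True)


def weight_and_aggregate(pairs: pd.DataFrame, entries: pd.DataFrame) -> pd.DataFrame:
    """Aggregate retained pairs to per-(cluster, end) End Node Scores.

    Every pair's (cluster, entry) must appear in ``entries``; a miss means the
    pipeline fed inconsistent tables and raises :class:`ConsistencyError`.
    """
    if pairs.empty:
        return pd.DataFrame(columns=ENS_COLUMNS)
    merged = pairs.merge(
        entries.rename(columns={"gene": "entry"})[["cluster", "entry", "log2fc"]],
        on=["cluster", "entry"],
        how="left",
        validate="many_to_one",
    )
    if merged["log2fc"].isna().any():
        missing = merged.loc[merged["log2fc"].isna(), ["cluster", "entry"]].drop_duplicates()
        raise ConsistencyError(
            f"pair table references entries absent from the entry table: "
            f"{missing.to_dict('records')[:5]}"
        )
    merged["ens"] = merged["log2fc"] * merged["dwpc_pair"]
    out = (
        merged.groupby(["cluster", "end", "end_type"], as_index=False, sort=True)["ens"]
        .sum()
    )
    return out[list(ENS_COLUMNS)].sort_values(["cluster", "end"], kind="mergesort").reset_index(
        drop=True
    )
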