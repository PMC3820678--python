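"""Map gene-expression summary rows onto promoters via shared identifiers.

Expression rows carry GenBank accession / gene symbol / UniGene identifiers;
any exact (case-insensitive) match with a promoter's gene identifiers assigns
the row to that promoter, and multiply-mapped rows are averaged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from combichip.occupancy_signals import INDUCED, REPRESSED, UNCHANGED
from combichip.promoter_catalog import PromoterRecord

logger = logging.getLogger(__name__)

ID_COLUMNS = ("genbank", "symbol", "unigene_cluster", "unigene_id")
VALUE_COLUMNS = (
    "expr_undiff",
    "expr_diff",
    "expr_acebp",
    "expr_afos",
    "expr_5aza",
    "expr_control",
)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with header row_id + identifier + expression columns."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("row_id",) + ID_COLUMNS})
    if "row_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'row_id'")
    present_ids = [c for c in ID_COLUMNS if c in df.columns]
    if not present_ids:
        raise ValueError(f"{path}: no identifier columns among {ID_COLUMNS}")
    return df


def map_expression(
    expr: pd.DataFrame, promoters: Sequence[PromoterRecord]
) -> pd.DataFrame:
    """Assign expression rows to promoters sharing any identifier.

    Returns a DataFrame indexed by promoter_id with the mean of every numeric
    expression column over contributing rows plus ``n_source_rows``.
    Promoters with no matching row are absent.  A row matching several
    promoters contributes to all of them (counted and logged).
    """
    id_cols = [c for c in ID_COLUMNS if c in expr.columns]
    value_cols = [c for c in expr.columns if c not in id_cols and c != "row_id"]
    ident_to_promoters: dict[str, list[str]] = {}
    for p in promoters:
        for g in p.gene_ids:
            ident_to_promoters.setdefault(str(g).lower(), []).append(p.promoter_id)

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    n_multi = 0
    values = expr[value_cols].to_numpy(dtype=float)
    for i, row in enumerate(expr.itertuples(index=False)):
        matched: set[str] = set()
        for c in id_cols:
            ident = getattr(row, c)
            if isinstance(ident, str) and ident:
                matched.update(ident_to_promoters.get(ident.lower(), ()))
        if not matched:
            continue
        if len(matched) > 1:
            n_multi += 1
        for pid in matched:
            if pid in sums:
                sums[pid] = sums[pid] + values[i]
                counts[pid] += 1
            else:
                sums[pid] = values[i].copy()
                counts[pid] = 1
    if n_multi:
        logger.info("%d expression rows matched more than one promoter", n_multi)

    pids = sorted(sums)
    data = {
        c: [sums[pid][j] / counts[pid] for pid in pids]
        for j, c in enumerate(value_cols)
    }
    out = pd.DataFrame(data, index=pd.Index(pids, name="promoter_id"))
    out["n_source_rows"] = [counts[pid] for pid in pids]
    if {"expr_undiff", "expr_diff"} <= set(value_cols):
        out["log2fc_diff_vs_undiff"] = out["expr_diff"] - out["expr_undiff"]
    for pert in ("acebp", "afos", "5aza"):
        col = f"expr_{pert}"
        if col in value_cols and "expr_control" in value_cols:
            out[f"log2fc_{pert}"] = out[col] - out["expr_control"]
    return out


def call_mrna_change(log2fc: float, threshold: float = 0.5) -> str:
    """Induced iff log2fc > threshold, repressed iff < -threshold, else unchanged."""
    if np.isnan(log2fc):
        raise ValueError("cannot call mRNA change on a missing value")
    if log2fc > threshold:
        return INDUCED
    if log2fc < -threshold:
        return REPRESSED
    return UNCHANGED


def call_mrna_changes(log2fc: pd.Series, threshold: float = 0.5) -> pd.Series:
    """Vectorised :func:`call_mrna_change`; missing values are dropped."""
    s = log2fc.dropna()
    out = pd.Series(UNCHANGED, index=s.index, dtype=object)
    out[s > threshold] = INDUCED
    out[s < -threshold] = REPRESSED
    return out
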