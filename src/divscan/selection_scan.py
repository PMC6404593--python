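"""Joint ECDF-percentile scan for candidate targets of positive selection.

Windows carrying pi and Tajima's D are intersected with gene models;
per-gene means are turned into empirical-CDF percentiles; the product of
the pi and D percentiles is re-percentiled; genes whose joint percentile
falls in the lowest tail (default 5%) are called candidates.  The scan is
purely rank-based, so it is invariant to any monotone transform applied
jointly to all pi (or all D) values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel

logger = logging.getLogger(__name__)


def intersect_genes_windows(
    genes: list[GeneModel], windows: pd.DataFrame
) -> dict[str, list[int]]:
    """Map gene id -> indices of windows overlapping it by >= 1 bp.

    Genes on scaffolds absent from the window table are excluded with a
    warning; genes with zero overlapping windows map to an empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for scaf, group in windows.groupby("scaffold"):
        tree = IntervalTree()
        for i, row in group.iterrows():
            if row["end"] > row["start"]:
                tree[row["start"] : row["end"]] = i
        trees[scaf] = tree
    out: dict[str, list[int]] = {}
    for g in genes:
        tree = trees.get(g.scaffold)
        if tree is None:
            logger.warning("gene %s on unknown scaffold %s; excluded", g.gene_id, g.scaffold)
            continue
        out[g.gene_id] = sorted(iv.data for iv in tree[g.start : g.end])
    return out


def aggregate_gene_stats(
    gene_windows: dict[str, list[int]],
    windows: pd.DataFrame,
    pi_col: str = "pi",
    d_col: str = "tajimas_d",
) -> pd.DataFrame:
    """Unweighted mean pi and mean D per gene over its overlapping windows.

    Windows with undefined (NaN) D are dropped from the D mean only; genes
    with no defined-D window (or no defined-pi window) are excluded from
    the scan and reported in the returned frame's complement.
    """
    rows = []
    for gene_id, idx in gene_windows.items():
        if not idx:
            continue
        sub = windows.loc[idx]
        pi_vals = sub[pi_col].dropna()
        d_vals = sub[d_col].dropna()
        rows.append(
            {
                "gene": gene_id,
                "n_windows": len(idx),
                "mean_pi": pi_vals.mean() if len(pi_vals) else np.nan,
                "mean_d": d_vals.mean() if len(d_vals) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_windows", "mean_pi", "mean_d"])


def ecdf_percentile(values, x) -> float:
    """Right-continuous empirical CDF: fraction of values <= x."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    return float(np.count_nonzero(values <= x) / values.size)


def _ecdf_column(values: np.ndarray) -> np.ndarray:
    """ECDF of each value within its own sample (vectorised weak ranks)."""
    order = np.sort(values)
    return np.searchsorted(order, values, side="right") / values.size


def joint_percentile_scan(
    gene_stats: pd.DataFrame, tail: float = 0.05, min_genes: int = 20
) -> pd.DataFrame:
    """Score genes by the product of their pi and D ECDF percentiles.

    Genes lacking a defined mean_pi or mean_d are dropped (counted in the
    log).  With fewer than ``min_genes`` usable genes the tail is empty and
    nothing is selected.  Ties in the joint product are all-in or all-out
    because selection thresholds the joint ECDF percentile.
    """
    usable = gene_stats.dropna(subset=["mean_pi", "mean_d"]).copy()
    n_dropped = len(gene_stats) - len(usable)
    if n_dropped:
        logger.info("%d genes without defined statistics excluded from scan", n_dropped)
    usable = usable.sort_values("gene", kind="stable").reset_index(drop=True)
    if usable.empty:
        return usable.assign(
            pct_pi=[], pct_d=[], joint=[], joint_pct=[], selected=[]
        )
    pct_pi = _ecdf_column(usable["mean_pi"].to_numpy())
    pct_d = _ecdf_column(usable["mean_d"].to_numpy())
    joint = pct_pi * pct_d
    joint_pct = _ecdf_column(joint)
    usable["pct_pi"] = pct_pi
    usable["pct_d"] = pct_d
    usable["joint"] = joint
    usable["joint_pct"] = joint_pct
    if len(usable) < min_genes:
        logger.warning(
            "only %d genes scored (< %d); empty selection", len(usable), min_genes
        )
        usable["selected"] = False
    else:
        usable["selected"] = joint_pct <= tail
    return usable


def run_selection_scan(
    genes: list[GeneModel],
    windows: pd.DataFrame,
    pi_col: str = "pi",
    tail: float = 0.05,
) -> pd.DataFrame:
    """Convenience composition: intersect, aggregate, scan."""
    gw = intersect_genes_windows(genes, windows)
    stats = aggregate_gene_stats(gw, windows, pi_col=pi_col)
    return joint_percentile_scan(stats, tail=tail)
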