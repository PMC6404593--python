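"""Motif-target enrichment of a query gene set.

One one-sided Fisher exact test (upper-tail hypergeometric) per motif
target set, Benjamini-Hochberg correction across the whole battery, and a
significance call at adjusted-P below the configured alpha (default 6e-4,
a threshold suited to a ~1,800-test battery).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .motif_scan import TargetSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 6e-4


def fisher_one_sided(k: int, q: int, t: int, U: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k | U, t, q).

    ``k`` genes overlap between a query of size ``q`` and a target set of
    size ``t`` drawn from a universe of ``U`` genes.
    """
    if not (0 <= k <= min(q, t) and q <= U and t <= U and min(q, t, U) >= 0):
        raise ValueError(f"inconsistent margins k={k} q={q} t={t} U={U}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, U, t, q))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def odds_ratio(k: int, q: int, t: int, U: int) -> float:
    """Sample odds ratio of the 2x2 table, Haldane 0.5 correction on zeros."""
    a = k
    b = t - k
    c = q - k
    d = U - t - q + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def run_enrichment(
    query: Iterable[str],
    target_sets: list[TargetSet],
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Fisher test of the query against every target set, BH across all.

    Genes outside the universe are dropped from both the query and the
    target sets (counted in the log).  Results are sorted by adjusted p.
    """
    universe_set = set(universe)
    U = len(universe_set)
    query_set = set(query) & universe_set
    dropped = len(set(query)) - len(query_set)
    if dropped:
        logger.info("%d query genes outside the universe dropped", dropped)
    if not query_set:
        logger.warning("empty query after universe restriction; all p = 1")
    rows = []
    for s in target_sets:
        tgt = set(s.genes) & universe_set
        k = len(query_set & tgt)
        q = len(query_set)
        t = len(tgt)
        p = 1.0 if q == 0 else fisher_one_sided(k, q, t, U)
        rows.append(
            {
                "set_id": s.set_id,
                "motif": s.motif,
                "normalization": s.normalization,
                "region": s.region,
                "size": s.size,
                "overlap": k,
                "query_size": q,
                "target_size": t,
                "universe_size": U,
                "odds_ratio": odds_ratio(k, q, t, U) if q else float("nan"),
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adjusted"] = []
        out["significant"] = []
        return out
    out["p_adjusted"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values(["p_adjusted", "p_raw", "set_id"], kind="stable").reset_index(
        drop=True
    )
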