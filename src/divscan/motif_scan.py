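"""PWM scoring of sliding genomic windows with a two-state partition-function
HMM, score normalization, regulatory-region definitions, and motif target
sets.

Window scoring
--------------
Each 500 bp window (250 bp step) is scored for a motif with the forward
recursion of a background/motif HMM: at every position the chain either
emits one background base (probability ``1 - t``) or enters the motif state
(probability ``t``, split evenly across strands) and emits a full ``w``-mer
from the PWM.  With ``f(0) = 1``::

    f(i) = f(i-1) (1-t) b(s_i) + sum_strand f(i-w) (t/2) P_pwm(s_{i-w+1..i})

and the window score is ``log f(L) - sum_i log b(s_i)``: the log partition
function of all ways to tile the window with motif sites, relative to the
background-only model.  The score tends to 0 as ``t`` tends to 0.  The
background is a mononucleotide distribution learned from long non-genic
regions.

Normalization
-------------
Raw scores are mapped per motif to [0, 1] by descending rank (0 = best).
The GC-binned variant sorts windows by GC content into 20 equal-count bins
and rank-normalizes within each bin, removing the tendency of GC-rich
motifs to score high in GC-rich windows.

Gene scores and target sets
---------------------------
For a gene g and motif m, ``Ngm`` is the best (minimum) normalized score
among the ``Wg`` windows overlapping the gene's regulatory region and
``Pgm = 1 - (1 - Ngm)**Wg`` (a Sidak-style correction of a minimum over
windows).  Target sets take the top 100 (conservative) or 800 (liberal)
genes by ascending Pgm for each motif x normalization x region
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .models import GeneModel

logger = logging.getLogger(__name__)

#: default HMM motif-entry probability
DEFAULT_TRANSITION = 0.0025
WINDOW = 500
STEP = 250

REGION_DEFINITIONS = ("5Kup2Kdown", "5Kup", "1Kup", "NearStartSite", "GeneTerr")


class PWM:
    """Position probability matrix over A,C,G,T with a small pseudocount."""

    def __init__(self, motif_id: str, matrix, pseudocount: float = 0.01,
                 renormalize: bool = False):
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError("PWM matrix must be (w, 4) with w >= 1")
        if renormalize or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            mat = mat + pseudocount
            mat = mat / mat.sum(axis=1, keepdims=True)
        self.motif_id = motif_id
        self.matrix = mat
        self.pseudocount = pseudocount

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> np.ndarray:
        return self.matrix[::-1, ::-1]

    def consensus_codes(self) -> np.ndarray:
        return self.matrix.argmax(axis=1)

    def information_content(self) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(
                np.where(self.matrix > 0, self.matrix * np.log2(self.matrix), 0.0),
                axis=1,
            )
        return float(np.sum(2.0 - h))


# ---------------------------------------------------------------------------
# Window partition


def apply_mask(genome: dict[str, np.ndarray], mask: pd.DataFrame | None) -> dict[str, np.ndarray]:
    """Return a genome copy with masked positions set to the N code (-1)."""
    if mask is None or len(mask) == 0:
        return genome
    out = {name: seq.copy() for name, seq in genome.items()}
    for row in mask.itertuples(index=False):
        if row.scaffold in out:
            out[row.scaffold][max(0, int(row.start)) : int(row.end)] = -1
    return out


def partition_windows(
    genome: dict[str, np.ndarray],
    window: int = WINDOW,
    step: int = STEP,
    mask: pd.DataFrame | None = None,
    max_masked_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Sliding windows over each scaffold; returns (table, masked genome).

    The table has scaffold/start/end plus ``gc`` (computed on unmasked
    bases), ``masked_fraction``, ``truncated`` and ``scored`` (False when
    more than half the window is masked).  A scaffold shorter than one
    window yields a single truncated window.
    """
    masked = apply_mask(genome, mask)
    rows = []
    for name, seq in masked.items():
        L = len(seq)
        if L == 0:
            continue
        starts = list(range(0, L - window + 1, step)) if L >= window else [0]
        for start in starts:
            end = min(start + window, L)
            chunk = seq[start:end]
            valid = chunk >= 0
            n_valid = int(valid.sum())
            gc = float(np.isin(chunk[valid], (1, 2)).mean()) if n_valid else np.nan
            mfrac = 1.0 - n_valid / (end - start)
            rows.append(
                {
                    "scaffold": name,
                    "start": start,
                    "end": end,
                    "gc": gc,
                    "masked_fraction": mfrac,
                    "truncated": end - start < window,
                    "scored": mfrac <= max_masked_fraction,
                }
            )
    return pd.DataFrame(rows), masked


# ---------------------------------------------------------------------------
# Background model


def estimate_background(
    genome: dict[str, np.ndarray],
    genes: list[GeneModel],
    min_region: int = 5_000,
    min_scaffold: int = 22_000,
    floor: float = 0.001,
) -> np.ndarray:
    """Mononucleotide frequencies over long non-genic regions.

    Regions are the gaps between gene spans (and scaffold edges) of length
    >= ``min_region`` on scaffolds >= ``min_scaffold``.  If no region
    qualifies, the whole genome is used with a warning.  Frequencies are
    floored at ``floor`` and renormalized.
    """
    counts = np.zeros(4)
    for name, seq in genome.items():
        if len(seq) < min_scaffold:
            continue
        spans = sorted(
            (g.start, g.end) for g in genes if g.scaffold == name
        )
        edges = [0]
        for s, e in spans:
            edges.append(s)
            edges.append(e)
        edges.append(len(seq))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo >= min_region:
                chunk = seq[lo:hi]
                chunk = chunk[chunk >= 0]
                counts += np.bincount(chunk, minlength=4)
    if counts.sum() == 0:
        logger.warning("no qualifying non-genic region; using whole-genome frequencies")
        for seq in genome.values():
            chunk = seq[seq >= 0]
            counts += np.bincount(chunk, minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freq = counts / counts.sum()
    low = freq < floor
    if low.any():
        freq[low] = floor
        freq[~low] *= (1.0 - floor * low.sum()) / freq[~low].sum()
    return freq


# ---------------------------------------------------------------------------
# HMM window scoring


def _sliding_bg_product(idx: np.ndarray, background: np.ndarray, w: int) -> np.ndarray:
    """prod of background emissions over every w-mer placement (N -> 1)."""
    n, L = idx.shape
    nw = L - w + 1
    bg = np.concatenate([background, [1.0]])
    out = np.ones((n, nw))
    for k in range(w):
        out *= bg[idx[:, k : k + nw]]
    return out


def _placement_odds(
    seqs: np.ndarray,
    pwm: PWM,
    background: np.ndarray,
    t: float,
    _idx: np.ndarray | None = None,
    _bg_prod: np.ndarray | None = None,
) -> np.ndarray:
    """(t/2)(P_fwd + P_rev)/prod(b) for every motif placement.

    ``seqs`` is (n_windows, L) int codes with -1 for N/masked; returns
    (n_windows, L - w + 1); placements covering an N get odds 0.
    """
    w = pwm.width
    n, L = seqs.shape
    if L < w:
        return np.empty((n, 0))
    idx = _idx if _idx is not None else np.where(seqs < 0, 4, seqs)
    nw = L - w + 1
    fwd = np.concatenate([pwm.matrix, np.zeros((w, 1))], axis=1)  # col 4 -> N
    rev = np.concatenate([pwm.reverse_complement(), np.zeros((w, 1))], axis=1)
    p_f = np.ones((n, nw))
    p_r = np.ones((n, nw))
    for k in range(w):
        col = idx[:, k : k + nw]
        p_f *= fwd[k][col]
        p_r *= rev[k][col]
    b_prod = _bg_prod if _bg_prod is not None else _sliding_bg_product(idx, background, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (t / 2.0) * (p_f + p_r) / b_prod
    odds[~np.isfinite(odds)] = 0.0
    return odds


def stubb_score_windows(
    seqs: np.ndarray,
    pwm: PWM,
    background: np.ndarray,
    t: float = DEFAULT_TRANSITION,
    _idx: np.ndarray | None = None,
    _bg_prod: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized forward-recursion scores for equal-length windows.

    Works in the background-normalised domain g(i) = f(i)/prod_{j<=i} b_j,
    so the recursion is g(i) = g(i-1)(1-t) + g(i-w) * odds(i) and the score
    is log g(L); occasional rescaling guards against overflow.
    """
    seqs = np.atleast_2d(seqs)
    n, L = seqs.shape
    w = pwm.width
    if t < 0 or t >= 1:
        raise ValueError("transition probability must be in [0, 1)")
    if L < w:
        return np.full(n, np.nan)
    odds = _placement_odds(seqs, pwm, background, t, _idx=_idx, _bg_prod=_bg_prod)
    g = np.empty((n, L + 1))
    g[:, 0] = 1.0
    logoff = np.zeros(n)
    for i in range(1, L + 1):
        g[:, i] = g[:, i - 1] * (1.0 - t)
        if i >= w:
            g[:, i] += g[:, i - w] * odds[:, i - w]
        big = g[:, i] > 1e200
        if big.any():
            scale = g[big, i]
            lo = max(0, i - w + 1)
            g[big, lo : i + 1] /= scale[:, None]
            logoff[big] += np.log(scale)
    score = np.log(g[:, L]) + logoff
    # windows whose unmasked length cannot hold the motif are undefined
    n_valid = (seqs >= 0).sum(axis=1)
    score[n_valid < w] = np.nan
    return score


def stubb_score_window(
    seq: np.ndarray, pwm: PWM, background: np.ndarray, t: float = DEFAULT_TRANSITION
) -> float:
    """Score a single window (codes array); NaN if shorter than the motif."""
    seq = np.asarray(seq, dtype=np.int8)
    if seq.size < pwm.width:
        return float("nan")
    return float(stubb_score_windows(seq[None, :], pwm, background, t)[0])


def score_windows(
    windows: pd.DataFrame,
    masked_genome: dict[str, np.ndarray],
    pwms: list[PWM],
    background: np.ndarray,
    t: float = DEFAULT_TRANSITION,
) -> pd.DataFrame:
    """Raw scores for every scored window x motif; NaN where unscored.

    Full-length windows are scored in one vectorized batch per motif;
    truncated windows fall back to the scalar path.
    """
    scores = np.full((len(windows), len(pwms)), np.nan)
    scored = windows["scored"].to_numpy()
    trunc = windows["truncated"].to_numpy()
    full_idx = np.nonzero(scored & ~trunc)[0]
    if full_idx.size:
        lengths = (windows["end"] - windows["start"]).to_numpy()
        L = int(lengths[full_idx[0]])
        seqs = np.empty((full_idx.size, L), dtype=np.int8)
        scafs = windows["scaffold"].to_numpy()
        starts = windows["start"].to_numpy()
        ends = windows["end"].to_numpy()
        for row, i in enumerate(full_idx):
            seqs[row] = masked_genome[scafs[i]][starts[i] : ends[i]]
        # placement-independent pieces are shared across motifs
        idx = np.where(seqs < 0, 4, seqs)
        bg_by_width: dict[int, np.ndarray] = {}
        for m, pwm in enumerate(pwms):
            w = pwm.width
            if w not in bg_by_width and L >= w:
                bg_by_width[w] = _sliding_bg_product(idx, background, w)
            scores[full_idx, m] = stubb_score_windows(
                seqs, pwm, background, t, _idx=idx, _bg_prod=bg_by_width.get(w)
            )
    for i in np.nonzero(scored & trunc)[0]:
        rec = windows.iloc[i]
        seq = masked_genome[rec["scaffold"]][rec["start"] : rec["end"]]
        for m, pwm in enumerate(pwms):
            scores[i, m] = stubb_score_window(seq, pwm, background, t)
    return pd.DataFrame(scores, columns=[p.motif_id for p in pwms], index=windows.index)


# ---------------------------------------------------------------------------
# Normalization


def rank_normalize(scores: np.ndarray, warn: bool = True) -> np.ndarray:
    """Map scores to [0, 1] by descending rank: 0 = best, 1 = worst.

    Ties get their mean rank; NaN scores stay NaN.  All-identical scores
    map to 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    out = np.full(scores.shape, np.nan)
    ok = np.isfinite(scores)
    n = int(ok.sum())
    if n == 0:
        return out
    if n == 1:
        out[ok] = 0.0
        return out
    vals = scores[ok]
    if np.all(vals == vals[0]):
        logger.log(
            logging.WARNING if warn else logging.DEBUG,
            "all scores identical; rank normalization degenerate",
        )
        out[ok] = 0.5
        return out
    ranks = rankdata(-vals, method="average")
    out[ok] = (ranks - 1.0) / (n - 1.0)
    return out


def gc_bin_assignment(gc: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Split windows into equal-count bins by GC (remainder to first bins)."""
    gc = np.asarray(gc, dtype=float)
    ok = np.isfinite(gc)
    n = int(ok.sum())
    bins = np.full(gc.shape, -1, dtype=int)
    if n == 0:
        return bins
    if n < 2 * n_bins:
        n_bins = max(1, n // 2)
        logger.warning("too few windows for requested GC bins; using %d", n_bins)
    base = n // n_bins
    rem = n - base * n_bins
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    order = np.argsort(gc[ok], kind="stable")
    labels = np.empty(n, dtype=int)
    pos = 0
    for b, size in enumerate(sizes):
        labels[order[pos : pos + size]] = b
        pos += size
    bins[ok] = labels
    return bins


def gc_rank_normalize(scores: np.ndarray, gc: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Rank-normalize within equal-count GC bins."""
    scores = np.asarray(scores, dtype=float)
    usable = np.isfinite(scores) & np.isfinite(np.asarray(gc, dtype=float))
    bins = np.full(scores.shape, -1, dtype=int)
    bins[usable] = gc_bin_assignment(np.asarray(gc, dtype=float)[usable], n_bins)
    out = np.full(scores.shape, np.nan)
    for b in np.unique(bins[bins >= 0]):
        sel = bins == b
        # a fully tied bin (e.g. no motif placement anywhere in it) is
        # routine for high-information motifs; not worth a warning per bin
        out[sel] = rank_normalize(scores[sel], warn=False)
    return out


def normalize_score_matrix(
    raw: pd.DataFrame, windows: pd.DataFrame, n_bins: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (rank-normalized, GC-normalized) copies of the raw matrix."""
    gc = windows["gc"].to_numpy()
    rank = raw.apply(lambda col: rank_normalize(col.to_numpy()), axis=0)
    gcn = raw.apply(lambda col: gc_rank_normalize(col.to_numpy(), gc, n_bins), axis=0)
    return rank, gcn


# ---------------------------------------------------------------------------
# Regulatory regions


@dataclass
class RegulatoryRegion:
    gene_id: str
    scaffold: str
    definition: str
    intervals: list[tuple[int, int]] = field(default_factory=list)
    #: NearStartSite assigns windows by midpoint rather than overlap
    midpoint_rule: bool = False


def define_regulatory_region(
    gene: GeneModel,
    definition: str,
    genes: list[GeneModel],
    scaffold_lengths: dict[str, int],
) -> RegulatoryRegion:
    """Resolve one of the five region definitions to concrete intervals.

    Intervals are strand-oriented (upstream flips for minus-strand genes)
    and clipped to scaffold bounds.
    """
    if definition not in REGION_DEFINITIONS:
        raise ValueError(f"unknown regulatory region definition {definition!r}")
    L = scaffold_lengths[gene.scaffold]
    tss = gene.tss
    plus = gene.strand == "+"

    def up_down(up: int, down: int) -> tuple[int, int]:
        if plus:
            return tss - up, tss + down
        return tss - down, tss + up

    midpoint_rule = False
    if definition == "5Kup2Kdown":
        lo, hi = up_down(5_000, 2_000)
    elif definition == "5Kup":
        lo, hi = up_down(5_000, 0)
    elif definition == "1Kup":
        lo, hi = up_down(1_000, 0)
    elif definition == "NearStartSite":
        midpoint_rule = True
        others = sorted(
            g.tss for g in genes if g.scaffold == gene.scaffold and g.gene_id != gene.gene_id
        )
        import bisect

        lo, hi = 0, L
        i = bisect.bisect_left(others, tss)
        if i > 0:
            lo = (others[i - 1] + tss) / 2.0
        if i < len(others):
            hi = (others[i] + tss) / 2.0
    else:  # GeneTerr
        same = [g for g in genes if g.scaffold == gene.scaffold and g.gene_id != gene.gene_id]
        up_ends = [g.end for g in same if g.end <= gene.start]
        down_starts = [g.start for g in same if g.start >= gene.end]
        lo = max(up_ends) if up_ends else 0
        hi = min(down_starts) if down_starts else L
        if plus:
            lo = min(lo, tss - 5_000)
        else:
            hi = max(hi, tss + 5_000)
    lo_c, hi_c = max(0, int(np.floor(lo))), min(L, int(np.ceil(hi)))
    if (lo_c, hi_c) != (int(np.floor(lo)), int(np.ceil(hi))):
        logger.debug("region %s for %s clipped to scaffold", definition, gene.gene_id)
    intervals = [(lo_c, hi_c)] if hi_c > lo_c else []
    return RegulatoryRegion(gene.gene_id, gene.scaffold, definition, intervals, midpoint_rule)


def region_window_indices(
    region: RegulatoryRegion, windows: pd.DataFrame, scored_only: bool = True
) -> list[int]:
    """Indices of windows belonging to a region.

    Interval regions use >= 1 bp overlap; NearStartSite uses the window
    midpoint (boundary midpoints belong to both neighbouring genes).
    """
    sel = windows["scaffold"].to_numpy() == region.scaffold
    if scored_only and "scored" in windows.columns:
        sel &= windows["scored"].to_numpy()
    idx = np.nonzero(sel)[0]
    if idx.size == 0 or not region.intervals:
        return []
    starts = windows["start"].to_numpy()[idx]
    ends = windows["end"].to_numpy()[idx]
    keep = np.zeros(idx.size, dtype=bool)
    for lo, hi in region.intervals:
        if region.midpoint_rule:
            mid = (starts + ends) / 2.0
            keep |= (mid >= lo) & (mid <= hi)
        else:
            keep |= (starts < hi) & (lo < ends)
    return [int(windows.index[i]) for i in idx[keep]]


# ---------------------------------------------------------------------------
# Gene-level scores


def gene_motif_scores(
    genes: list[GeneModel],
    windows: pd.DataFrame,
    norm_matrices: dict[str, pd.DataFrame],
    scaffold_lengths: dict[str, int],
    regions: tuple[str, ...] = ("1Kup", "GeneTerr"),
) -> pd.DataFrame:
    """Pgm for every gene x motif x region x normalization.

    ``norm_matrices`` maps normalization name ('rank', 'gc') to a
    windows x motifs matrix.  Genes whose region overlaps no scored window
    are unscored for that region (counted in the log).
    """
    any_norm = next(iter(norm_matrices.values()))
    motif_ids = list(any_norm.columns)
    frames = []
    n_unscored = 0
    for region_name in regions:
        for gene in genes:
            region = define_regulatory_region(
                gene, region_name, genes, scaffold_lengths
            )
            idx = region_window_indices(region, windows)
            if not idx:
                n_unscored += 1
                continue
            wg = len(idx)
            for norm_name, mat in norm_matrices.items():
                sub = mat.loc[idx]
                ngm = sub.min(axis=0, skipna=True).to_numpy()
                n_def = sub.notna().sum(axis=0).to_numpy()
                with np.errstate(invalid="ignore"):
                    pgm = 1.0 - (1.0 - ngm) ** n_def
                frames.append(
                    pd.DataFrame(
                        {
                            "gene": gene.gene_id,
                            "motif": motif_ids,
                            "region": region_name,
                            "normalization": norm_name,
                            "Wg": n_def,
                            "Ngm": ngm,
                            "Pgm": pgm,
                        }
                    )
                )
    if n_unscored:
        logger.info("%d gene x region combinations had no scored window", n_unscored)
    if not frames:
        return pd.DataFrame(
            columns=["gene", "motif", "region", "normalization", "Wg", "Ngm", "Pgm"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Target sets


@dataclass(frozen=True)
class TargetSet:
    motif: str
    normalization: str
    region: str
    size: int
    genes: tuple[str, ...]

    @property
    def set_id(self) -> str:
        return f"{self.motif}|{self.normalization}|{self.region}|{self.size}"


def build_target_sets(
    gene_scores: pd.DataFrame,
    sizes: tuple[int, ...] = (100, 800),
    normalizations: tuple[str, ...] = ("rank", "gc"),
    regions: tuple[str, ...] = ("1Kup", "GeneTerr"),
) -> list[TargetSet]:
    """Top-N gene sets per motif x normalization x region x size.

    Genes are ordered by ascending Pgm (best first), ties broken by gene
    id; a combination with fewer scored genes than the requested size
    yields the full list (flagged in the log).
    """
    sets: list[TargetSet] = []
    grouped = gene_scores.dropna(subset=["Pgm"]).groupby(
        ["motif", "normalization", "region"], sort=True
    )
    tables = {key: df for key, df in grouped}
    motifs = sorted(gene_scores["motif"].unique())
    for motif in motifs:
        for norm in normalizations:
            for region in regions:
                df = tables.get((motif, norm, region))
                if df is None or df.empty:
                    ordered: list[str] = []
                else:
                    ordered = (
                        df.sort_values(["Pgm", "gene"], kind="stable")["gene"].tolist()
                    )
                for size in sizes:
                    if len(ordered) < size:
                        logger.debug(
                            "target set %s|%s|%s|%d short: %d genes",
                            motif, norm, region, size, len(ordered),
                        )
                    sets.append(
                        TargetSet(motif, norm, region, size, tuple(ordered[:size]))
                    )
    return sets


def target_sets_manifest(sets: list[TargetSet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": s.set_id,
                "motif": s.motif,
                "normalization": s.normalization,
                "region": s.region,
                "size": s.size,
                "n_genes": len(s.genes),
            }
            for s in sets
        ]
    )


def write_target_sets(sets: list[TargetSet], outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target_sets_manifest(sets).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    for s in sets:
        fname = s.set_id.replace("|", "_") + ".txt"
        (outdir / fname).write_text("".join(f"{g}\n" for g in s.genes))


def read_target_sets(outdir) -> list[TargetSet]:
    from pathlib import Path

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    sets = []
    for row in manifest.itertuples(index=False):
        fname = str(row.set_id).replace("|", "_") + ".txt"
        genes = tuple((outdir / fname).read_text().split())
        sets.append(
            TargetSet(row.motif, row.normalization, row.region, int(row.size), genes)
        )
    return sets
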