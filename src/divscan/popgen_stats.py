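"""Windowed diversity statistics and per-sample/per-site population tests.

Implements nucleotide diversity per site and per window (with an optional
coverage-corrected denominator), Tajima's D with the standard constants,
per-individual heterozygosity and inbreeding F, the exact test of
Hardy-Weinberg proportions, and the moment-based Ajk relatedness matrix.

Missing-data conventions: the per-site sample size ``n`` is the number of
called alleles at that site; ``S`` counts sites segregating among called
alleles; the ``n`` used for the Tajima constants of a window is the median
per-site called-allele count (rounded), because the cohort filter allows a
few missing genotypes per site.  Undefined statistics are NaN, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .models import GenotypeMatrix


# ---------------------------------------------------------------------------
# Per-site diversity


def site_pi(n_called_alleles: int, alt_count: int) -> float:
    """Per-site heterozygosity 2j(n-j) / (n(n-1)).

    Returns NaN (undefined, distinct from 0) when fewer than two alleles
    were called; 0 for a monomorphic site.
    """
    n, j = int(n_called_alleles), int(alt_count)
    if j < 0 or j > n:
        raise ValueError(f"alt_count {j} outside [0, {n}]")
    if n < 2:
        return math.nan
    return 2.0 * j * (n - j) / (n * (n - 1))


def site_pi_array(n_called: np.ndarray, alt: np.ndarray) -> np.ndarray:
    n = n_called.astype(float)
    j = alt.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * j * (n - j) / (n * (n - 1))
    out[n < 2] = np.nan
    return out


# ---------------------------------------------------------------------------
# Tajima's D


def tajima_constants(n: int) -> dict[str, float]:
    """Standard Tajima constants a1..e2 for n sampled chromosomes."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_sums(pi_sum: float, S: int, n: int) -> float:
    """D from a window's pairwise-difference sum, S, and chromosome count.

    Undefined (NaN) when S = 0.
    """
    if S == 0:
        return math.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_sum - S / c["a1"]) / math.sqrt(var)


def window_tajimas_d(n_called: np.ndarray, alt: np.ndarray) -> float:
    """Tajima's D for one window given per-site called/alt allele counts.

    Sites monomorphic among called alleles contribute neither to S nor to
    the pairwise sum; n is the rounded median per-site called count over
    segregating sites.
    """
    n_called = np.asarray(n_called)
    alt = np.asarray(alt)
    seg = (alt > 0) & (alt < n_called) & (n_called >= 2)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    pi_sum = float(np.nansum(site_pi_array(n_called[seg], alt[seg])))
    n = int(round(float(np.median(n_called[seg]))))
    if n < 2:
        return math.nan
    return tajimas_d_from_sums(pi_sum, S, n)


# ---------------------------------------------------------------------------
# Windows


def tile_windows(scaffold_lengths: dict[str, int], window: int) -> pd.DataFrame:
    """Non-overlapping windows anchored at 0; trailing partials kept."""
    if window <= 0:
        raise ValueError("window length must be positive")
    rows = [
        (name, start, min(start + window, L))
        for name, L in scaffold_lengths.items()
        for start in range(0, L, window)
    ]
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def _coverage_per_window(
    windows: pd.DataFrame, coverage: pd.DataFrame
) -> np.ndarray:
    """Length-weighted mean of coverage-track fractions per stats window."""
    frac = np.full(len(windows), np.nan)
    for scaf, widx in windows.groupby("scaffold").groups.items():
        cov = coverage[coverage["scaffold"] == scaf]
        if cov.empty:
            continue
        cs = cov["start"].to_numpy()
        ce = cov["end"].to_numpy()
        cf = cov.iloc[:, 3].to_numpy(dtype=float)
        for i in widx:
            ws, we = windows.at[i, "start"], windows.at[i, "end"]
            lo = np.maximum(cs, ws)
            hi = np.minimum(ce, we)
            olap = np.maximum(hi - lo, 0)
            tot = olap.sum()
            if tot > 0:
                frac[i] = float((olap * cf).sum() / tot)
    return frac


def compute_window_stats(
    gm: GenotypeMatrix,
    scaffold_lengths: dict[str, int],
    window: int = 1_000,
    coverage: pd.DataFrame | None = None,
    genome: dict[str, np.ndarray] | None = None,
    min_depth: int = 5,
    corrected: bool = True,
) -> pd.DataFrame:
    """Per-window n_sites, S, pi (uncorrected), pi_corrected, Tajima's D.

    ``pi`` divides the pairwise-difference sum by the window length;
    ``pi_corrected`` divides by the *count* of well-covered sites
    (covered_fraction x window length), the denominator used when coverage
    is patchy.  Windows with zero well-covered sites get NaN corrected pi.
    """
    windows = tile_windows(scaffold_lengths, window)
    n_called, alt = gm.allele_counts()
    pos = gm.sites["pos"].to_numpy()
    scaf = gm.sites["scaffold"].to_numpy()

    n_sites = np.zeros(len(windows), dtype=int)
    S = np.zeros(len(windows), dtype=int)
    pi_sum = np.zeros(len(windows))
    tajd = np.full(len(windows), np.nan)

    widx_by_scaf = {s: g for s, g in windows.groupby("scaffold").groups.items()}
    for s in np.unique(scaf):
        if s not in widx_by_scaf:
            continue
        sel = scaf == s
        wpos = pos[sel] // window
        wstart = (windows.loc[widx_by_scaf[s], "start"] // window).to_numpy()
        base_idx = np.asarray(widx_by_scaf[s])
        lookup = {w: i for w, i in zip(wstart, base_idx)}
        nc = n_called[sel]
        al = alt[sel]
        for w in np.unique(wpos):
            i = lookup.get(w)
            if i is None:
                continue
            in_w = wpos == w
            nc_w, al_w = nc[in_w], al[in_w]
            n_sites[i] = int(in_w.sum())
            seg = (al_w > 0) & (al_w < nc_w) & (nc_w >= 2)
            S[i] = int(seg.sum())
            pi_sum[i] = float(np.nansum(site_pi_array(nc_w[seg], al_w[seg])))
            if S[i] > 0:
                tajd[i] = window_tajimas_d(nc_w, al_w)

    length = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    out = windows.copy()
    out["n_sites"] = n_sites
    out["S"] = S
    out["pi"] = pi_sum / length

    covered_fraction = np.full(len(windows), np.nan)
    pi_corr = np.full(len(windows), np.nan)
    if coverage is not None:
        covered_fraction = _coverage_per_window(windows, coverage)
        denom = covered_fraction * length
        with np.errstate(divide="ignore", invalid="ignore"):
            pi_corr = np.where(denom > 0, pi_sum / denom, np.nan)
    elif corrected:
        # with no coverage track every site counts as covered
        covered_fraction = np.ones(len(windows))
        pi_corr = pi_sum / length
    out["pi_corrected"] = pi_corr
    out["tajimas_d"] = tajd
    out["covered_fraction"] = covered_fraction

    gc = np.full(len(windows), np.nan)
    if genome is not None:
        for i, row in enumerate(windows.itertuples(index=False)):
            seq = genome.get(row.scaffold)
            if seq is None:
                continue
            chunk = seq[row.start : row.end]
            valid = chunk >= 0
            if valid.any():
                gc[i] = float(np.isin(chunk[valid], (1, 2)).mean())
    out["gc"] = gc
    return out


# ---------------------------------------------------------------------------
# Per-individual heterozygosity / inbreeding


@dataclass(frozen=True)
class SampleStat:
    sample: str
    observed_hom: int
    expected_hom: float
    n_sites: int
    F: float


def individual_heterozygosity(gm: GenotypeMatrix) -> list[SampleStat]:
    """Observed vs expected homozygosity and F = (O - E)/(N - E) per sample.

    Expected homozygosity at a site with alt frequency p and C called
    alleles is 1 - 2pq * C/(C-1) (the small-sample-corrected expectation);
    sites monomorphic among called alleles are excluded.  Computed over the
    diploid cohort with p estimated from it.
    """
    cols = gm.diploid_columns()
    if len(cols) < 2:
        raise ValueError("need at least two diploid samples")
    n_called, alt = gm.allele_counts(cols)
    usable = (n_called >= 2) & (alt > 0) & (alt < n_called)
    p = alt[usable] / n_called[usable]
    corr = n_called[usable] / (n_called[usable] - 1)
    e_hom_site = 1.0 - 2.0 * p * (1 - p) * corr

    out = []
    for c in cols:
        dos = gm.dosage[usable, c]
        called = dos >= 0
        n = int(called.sum())
        obs = int(((dos == 0) | (dos == 2))[called].sum())
        exp = float(e_hom_site[called].sum())
        f = (obs - exp) / (n - exp) if n > 0 and n != exp else math.nan
        out.append(SampleStat(gm.samples[c], obs, exp, n, f))
    return out


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value (sum of genotype-configuration
    probabilities, conditional on allele counts, that do not exceed the
    observed configuration's probability).

    Monomorphic sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het | allele counts) up to a shared constant
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * math.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_Aa
    p_obs = probs[hets == obs]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    # numerical slack so equal-probability configurations are included
    p = float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_tests(gm: GenotypeMatrix) -> pd.DataFrame:
    """Exact HWE p per site over the diploid cohort."""
    cols = gm.diploid_columns()
    dos = gm.dosage[:, cols]
    n_hom_ref = (dos == 0).sum(axis=1)
    n_het = (dos == 1).sum(axis=1)
    n_hom_alt = (dos == 2).sum(axis=1)
    pvals = [
        hwe_exact_test(int(a), int(h), int(b)) if (a + h + b) > 0 else math.nan
        for a, h, b in zip(n_hom_ref, n_het, n_hom_alt)
    ]
    out = gm.sites[["scaffold", "pos"]].copy()
    out["n_hom_ref"] = n_hom_ref
    out["n_het"] = n_het
    out["n_hom_alt"] = n_hom_alt
    out["p_hwe"] = pvals
    return out


# ---------------------------------------------------------------------------
# Relatedness (unadjusted Ajk)


def relatedness_ajk(gm: GenotypeMatrix) -> pd.DataFrame:
    """Moment-based pairwise relatedness from dosages and sample frequencies.

    Off-diagonal: Ajk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i q_i);
    diagonal:     Ajj = 1 + (1/m) sum_i (x_ij^2 - (1+2p_i) x_ij + 2p_i^2)
                                   / (2 p_i q_i),
    with p_i the alt frequency estimated from the diploid cohort itself and
    m the number of sites polymorphic in the cohort.  Sites with any
    missing genotype are excluded from m (complete-case), as are
    monomorphic sites.

    Because p is estimated from the same individuals, unrelated pairs have
    expectation about -1/N rather than exactly 0.
    """
    cols = gm.diploid_columns()
    N = len(cols)
    if N < 2:
        raise ValueError("need at least two diploid samples")
    dos = gm.dosage[:, cols].astype(float)
    complete = (dos >= 0).all(axis=1)
    dos = dos[complete]
    p = dos.sum(axis=1) / (2 * N)
    poly = (p > 0) & (p < 1)
    dos = dos[poly]
    p = p[poly]
    m = dos.shape[0]
    if m == 0:
        raise ValueError("no polymorphic complete-case sites available")
    denom = 2 * p * (1 - p)
    centred = (dos - 2 * p[:, None]) / np.sqrt(denom)[:, None]
    ajk = centred.T @ centred / m
    diag = 1.0 + (
        (dos**2 - (1 + 2 * p[:, None]) * dos + 2 * p[:, None] ** 2) / denom[:, None]
    ).sum(axis=0) / m
    np.fill_diagonal(ajk, diag)
    names = [gm.samples[c] for c in cols]
    return pd.DataFrame(ajk, index=names, columns=names)


def mean_offdiagonal(ajk: pd.DataFrame) -> float:
    a = ajk.to_numpy()
    mask = ~np.eye(a.shape[0], dtype=bool)
    return float(a[mask].mean())
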