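"""End-to-end pipeline compositions on synthetic studies.

These functions wire the generator through the analysis stages the way a
user would at the shell, and are what the validation suite and the
reproduction script run.  Each takes an explicit seed and returns plain
numbers, so results are reproducible and machine-checkable against the
generator's truth tables.
"""

from __future__ import annotations

import numpy as np

from . import enrichment as enr
from . import motif_scan as ms
from . import popgen_stats as pg
from . import selection_scan as ss
from .synthetic_data import SimConfig, simulate_study


def score_motif_study(sim, t: float = ms.DEFAULT_TRANSITION):
    """Window scores -> both normalizations -> Pgm -> target sets."""
    lengths = {k: len(v) for k, v in sim.genome.items()}
    windows, masked = ms.partition_windows(sim.genome)
    background = ms.estimate_background(sim.genome, sim.genes)
    raw = ms.score_windows(windows, masked, sim.pwms, background, t=t)
    rank, gcn = ms.normalize_score_matrix(raw, windows)
    scores = ms.gene_motif_scores(
        sim.genes, windows, {"rank": rank, "gc": gcn}, lengths
    )
    sets = ms.build_target_sets(scores)
    return windows, raw, scores, sets


def count_target_sets(seed: int, n_motifs: int = 223) -> int:
    """Full motif pipeline on a compact genome; returns the target-set count.

    A collection of ``n_motifs`` motifs scored with both normalizations,
    both regulatory regions (1Kup, GeneTerr) and both set sizes (100, 800)
    yields ``n_motifs * 8`` sets.
    """
    cfg = SimConfig(
        seed=seed,
        genome_length=200_000,
        n_scaffolds=2,
        n_genes=40,
        gene_length=1_000,
        min_gene_gap=400,
        n_motifs=n_motifs,
        planted_gene_fraction=0.1,
        sweep_gene_fraction=0.0,
    )
    sim = simulate_study(cfg)
    _, _, _, sets = score_motif_study(sim)
    return len(sets)


def neutral_calibration(seed: int) -> dict:
    """Windowed diversity and relatedness under the default study conditions.

    Returns mean Tajima's D and mean coverage-corrected pi over the windows
    free of planted sweeps, and the mean off-diagonal Ajk over all
    polymorphic complete-case sites.
    """
    cfg = SimConfig(seed=seed)
    sim = simulate_study(cfg)
    lengths = {k: len(v) for k, v in sim.genome.items()}
    stats = pg.compute_window_stats(
        sim.gm, lengths, window=1_000, coverage=sim.coverage, genome=sim.genome
    )
    # windows untouched by a sweep region
    regions, _ = _sweep_regions(sim)
    neutral = np.ones(len(stats), dtype=bool)
    for r in regions:
        hit = (
            (stats["scaffold"] == r.scaffold)
            & (stats["start"] < r.end)
            & (r.start < stats["end"])
        )
        neutral &= ~hit.to_numpy()
    d = stats.loc[neutral, "tajimas_d"].dropna()
    pi = stats.loc[neutral, "pi_corrected"].dropna()
    ajk = pg.relatedness_ajk(sim.gm)
    n_called, alt = sim.gm.allele_counts()
    n_poly = int(((alt > 0) & (alt < n_called)).sum())
    return {
        "mean_tajimas_d": float(d.mean()),
        "n_windows": int(d.size),
        "pi_per_bp": float(pi.mean()),
        "mean_offdiag_ajk": pg.mean_offdiagonal(ajk),
        "n_sites": n_poly,
    }


def _sweep_regions(sim):
    from .synthetic_data import derive_sweep_regions

    return derive_sweep_regions(sim.cfg, sim.genes, sim.genome)


def sweep_recovery(
    seed: int, sweep_gene_fraction: float = 0.2, n_seeds: int = 5, tail: float = 0.05
) -> dict:
    """Sensitivity/precision of the lowest-tail joint-percentile call for
    planted sweeps (reduction 0.2, SFS skew 2), averaged over seeds."""
    sens, prec = [], []
    for k in range(n_seeds):
        cfg = SimConfig(
            seed=seed + k,
            n_genes=200,
            sweep_gene_fraction=sweep_gene_fraction,
            n_motifs=0,
            planted_gene_fraction=0.0,
            bad_site_fraction=0.0,
            haploid_error_fraction=0.0,
        )
        sim = simulate_study(cfg)
        lengths = {k_: len(v) for k_, v in sim.genome.items()}
        stats = pg.compute_window_stats(sim.gm, lengths, window=1_000)
        scores = ss.run_selection_scan(sim.genes, stats, tail=tail)
        selected = set(scores.loc[scores["selected"], "gene"])
        truth = sim.truth.sweep_gene_ids
        tp = len(selected & truth)
        sens.append(tp / len(truth) if truth else float("nan"))
        prec.append(tp / len(selected) if selected else 0.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "precision": float(np.mean(prec)),
        "n_seeds": n_seeds,
    }


def motif_recovery(seed: int, n_seeds: int = 5, n_motifs: int = 20) -> dict:
    """Planted-promoter-site recovery and enrichment specificity.

    For each seed, 5% of 400 genes receive one site of a deterministic
    (2 bits/column) PWM in their 1 kb upstream region.  Reported: the
    fraction of planted genes captured by that motif's conservative
    (top-100) 1Kup target set, and the number of seeds in which an
    enrichment run with the planted genes as query flags the planted motif
    and no other.
    """
    captured, total = 0, 0
    planted_only = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            seed=seed + k,
            genome_length=600_000,
            n_scaffolds=3,
            n_genes=400,
            gene_length=1_000,
            min_gene_gap=400,
            n_motifs=n_motifs,
            motif_consensus_prob=1.0,
            planted_gene_fraction=0.05,
            sweep_gene_fraction=0.0,
        )
        sim = simulate_study(cfg)
        planted = set(sim.truth.planted_sites["gene_id"])
        _, _, _, sets = score_motif_study(sim)
        planted_motif = sim.pwms[0].motif_id
        cons = next(
            s
            for s in sets
            if s.motif == planted_motif
            and s.normalization == "rank"
            and s.region == "1Kup"
            and s.size == 100
        )
        captured += len(planted & set(cons.genes))
        total += len(planted)
        universe = [g.gene_id for g in sim.genes]
        res = enr.run_enrichment(planted, sets, universe)
        sig_motifs = set(res.loc[res["significant"], "motif"])
        if sig_motifs == {planted_motif}:
            planted_only += 1
    return {
        "capture_fraction": captured / total if total else float("nan"),
        "planted_only_seeds": planted_only,
        "n_seeds": n_seeds,
    }


def filter_fixture_survivors() -> dict:
    """Run the default cascade on the built-in hand-evaluated cohort."""
    from .variant_filter import FilterConfig, demo_cohort, filter_cascade

    gm = demo_cohort()
    out, report = filter_cascade(gm, FilterConfig())
    again, _ = filter_cascade(out, FilterConfig())
    return {
        "survivors": out.n_sites,
        "n_input": gm.n_sites,
        "idempotent": bool(again.n_sites == out.n_sites),
    }
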