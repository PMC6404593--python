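"""Synthetic study generator: genome, genes, cohort variants, coverage, motifs.

This module fabricates a complete desk-scale analogue of a low-coverage
population-resequencing study of a haplodiploid insect: a multi-scaffold
genome, non-overlapping gene models, a biallelic SNP cohort for 18 diploid
females plus one haploid male, a per-window coverage track, and a motif
collection with high-probability binding sites planted into promoters of a
chosen gene subset.  Every planted signal is recorded in a machine-readable
:class:`~divscan.models.TruthTable` so downstream stages can be validated
without any external data.

The variant model is deliberately not a sequencing emulator: sites are
placed by a Bernoulli process with per-bp density ``theta_per_bp * a1``
(``a1`` the harmonic number over 2N-1), the derived-allele count ``j`` at a
segregating site is drawn from the neutral infinite-sites spectrum
(P(j) proportional to 1/j), and the ``j`` derived alleles are assigned to
the 2N chromosomes uniformly at random (random union of gametes, i.e.
Hardy-Weinberg).  This makes the expected per-bp pairwise diversity equal
``theta_per_bp`` exactly and centres windowed Tajima's D on zero.  Inside a
sweep region the site density is thinned by ``reduction`` and the spectrum
is skewed toward rare variants (P(j) proportional to 1/j**skew), producing
the low-pi / negative-D signature a selection scan targets.

Site annotations (QD, FS, MQ, ReadPosRankSum) and genotype DP/GQ are drawn
from labelled passing/failing distributions rather than recomputed from
reads; the filter cascade tests predicates, not a caller.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as dio
from .models import BASES, GeneModel, GenotypeMatrix, TruthTable, decode_seq, revcomp_codes

logger = logging.getLogger(__name__)


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SweepRegion:
    scaffold: str
    start: int
    end: int
    reduction: float = 0.2
    skew: float = 2.0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise SimConfigError(f"bad sweep interval [{self.start}, {self.end})")
        if not 0 < self.reduction <= 1:
            raise SimConfigError("sweep reduction must be in (0, 1]")
        if self.skew < 1:
            raise SimConfigError("sweep sfs skew must be >= 1")


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated study design: 18 diploid females and one
    haploid male, genome-wide diversity around 0.0015/bp, and roughly 5% of
    genes inside sweep regions (the study called ~4.4% of its genes as
    selection candidates).  Coverage is low-pass (mean 20x) so the depth>=5
    correction and the DP/GQ genotype filters both have work to do.
    """

    seed: int = 0
    genome_length: int = 1_800_000
    n_scaffolds: int = 5
    gc_mean: float = 0.40
    n_genes: int = 200
    gene_length: int = 5_000
    min_gene_gap: int = 500
    n_diploid: int = 18
    n_haploid: int = 1
    theta_per_bp: float = 0.0015
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    sweep_gene_fraction: float = 0.05
    sweep_reduction: float = 0.2
    sweep_skew: float = 2.0
    sweep_margin: int = 1_000
    coverage_mean: float = 20.0
    coverage_dip_regions: list[tuple[str, int, int]] = field(default_factory=list)
    dip_mean: float = 2.0
    coverage_window: int = 100
    n_motifs: int = 10
    motif_length: int = 8
    motif_consensus_prob: float = 0.9
    planted_gene_fraction: float = 0.1
    bad_site_fraction: float = 0.05
    haploid_error_fraction: float = 0.01

    def validate(self) -> None:
        if self.genome_length < 10_000:
            raise SimConfigError("genome_length must be >= 10 kb")
        if self.n_scaffolds < 1:
            raise SimConfigError("need at least one scaffold")
        if self.genome_length // self.n_scaffolds < 1:
            raise SimConfigError("zero-length scaffold requested")
        for name, val in (
            ("gc_mean", self.gc_mean),
            ("sweep_gene_fraction", self.sweep_gene_fraction),
            ("planted_gene_fraction", self.planted_gene_fraction),
            ("bad_site_fraction", self.bad_site_fraction),
            ("haploid_error_fraction", self.haploid_error_fraction),
        ):
            if not 0 <= val <= 1:
                raise SimConfigError(f"{name} must be in [0, 1], got {val}")
        for name in ("n_genes", "n_diploid", "n_haploid", "n_motifs"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.theta_per_bp < 0 or self.coverage_mean < 0:
            raise SimConfigError("rates must be non-negative")
        if self.motif_length < 1:
            raise SimConfigError("motif_length must be >= 1")

    def scaffold_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_scaffolds
        rem = self.genome_length - base * self.n_scaffolds
        return {
            f"scaffold_{i + 1}": base + (1 if i < rem else 0)
            for i in range(self.n_scaffolds)
        }


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(cfg: SimConfig) -> dict[str, np.ndarray]:
    """i.i.d. genome with P(G or C) = gc_mean, split over n_scaffolds."""
    cfg.validate()
    rng = _rng(cfg, 0)
    half_gc = cfg.gc_mean / 2
    half_at = (1 - cfg.gc_mean) / 2
    probs = np.array([half_at, half_gc, half_gc, half_at])  # A C G T
    genome = {}
    for name, length in cfg.scaffold_lengths().items():
        genome[name] = rng.choice(4, size=length, p=probs).astype(np.int8)
    return genome


# ---------------------------------------------------------------------------
# Gene models


def simulate_gene_models(cfg: SimConfig, genome: dict[str, np.ndarray]) -> list[GeneModel]:
    """Place non-overlapping genes of fixed length with random gaps/strands."""
    cfg.validate()
    rng = _rng(cfg, 1)
    lengths = {name: len(seq) for name, seq in genome.items()}
    total = sum(lengths.values())
    need = cfg.n_genes * (cfg.gene_length + cfg.min_gene_gap)
    if need > total:
        raise SimConfigError(
            f"genome of {total} bp too short for {cfg.n_genes} genes of "
            f"{cfg.gene_length} bp with {cfg.min_gene_gap} bp gaps"
        )
    # apportion genes per scaffold by length
    names = list(lengths)
    quota = {n: int(round(cfg.n_genes * lengths[n] / total)) for n in names}
    while sum(quota.values()) != cfg.n_genes:
        adjust = 1 if sum(quota.values()) < cfg.n_genes else -1
        n = names[int(rng.integers(len(names)))]
        if quota[n] + adjust >= 0:
            quota[n] += adjust
    genes: list[GeneModel] = []
    idx = 1
    for name in names:
        k = quota[name]
        if k == 0:
            continue
        slot = lengths[name] // k
        if slot < cfg.gene_length + cfg.min_gene_gap:
            raise SimConfigError(f"scaffold {name} too short for {k} genes")
        for j in range(k):
            lo = j * slot + cfg.min_gene_gap // 2
            hi = (j + 1) * slot - cfg.gene_length - cfg.min_gene_gap // 2
            start = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"gene_{idx:04d}", name, start, start + cfg.gene_length, strand)
            )
            idx += 1
    return genes


# ---------------------------------------------------------------------------
# Sweep regions


def derive_sweep_regions(
    cfg: SimConfig, genes: list[GeneModel], genome: dict[str, np.ndarray]
) -> tuple[list[SweepRegion], set[str]]:
    """Resolve configured sweeps to concrete regions plus the truth gene set.

    Explicit ``cfg.sweep_regions`` win; otherwise ``sweep_gene_fraction`` of
    the genes are drawn at random and each gene span (plus ``sweep_margin``
    on both sides, clipped to the scaffold) becomes one region.
    """
    lengths = {name: len(seq) for name, seq in genome.items()}
    if cfg.sweep_regions:
        for r in cfg.sweep_regions:
            if r.scaffold not in lengths or r.end > lengths[r.scaffold]:
                raise SimConfigError(f"sweep region {r} outside the genome")
        truth = {
            g.gene_id
            for g in genes
            for r in cfg.sweep_regions
            if g.scaffold == r.scaffold and g.start < r.end and r.start < g.end
        }
        return list(cfg.sweep_regions), truth
    n_sweep = int(round(cfg.sweep_gene_fraction * len(genes)))
    if n_sweep == 0:
        return [], set()
    rng = _rng(cfg, 2)
    chosen = rng.choice(len(genes), size=n_sweep, replace=False)
    regions, truth = [], set()
    for i in sorted(chosen):
        g = genes[i]
        regions.append(
            SweepRegion(
                g.scaffold,
                max(0, g.start - cfg.sweep_margin),
                min(lengths[g.scaffold], g.end + cfg.sweep_margin),
                cfg.sweep_reduction,
                cfg.sweep_skew,
            )
        )
        truth.add(g.gene_id)
    return regions, truth


# ---------------------------------------------------------------------------
# Variants


def _sfs_weights(n_chrom: int, skew: float) -> np.ndarray:
    j = np.arange(1, n_chrom)
    w = 1.0 / j**skew
    return w / w.sum()


def simulate_variants(
    cfg: SimConfig,
    genome: dict[str, np.ndarray],
    genes: list[GeneModel] | None = None,
    sweep_regions: list[SweepRegion] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw the SNP cohort; returns (GenotypeMatrix, per-site truth table).

    See the module docstring for the generative model.  The haploid male is
    written as a diploid homozygote (dosage 0 or 2) except for
    ``haploid_error_fraction`` of sites, which are written heterozygous to
    exercise the haploid-consistency filter.
    """
    cfg.validate()
    if cfg.n_diploid < 2:
        raise SimConfigError("need at least two diploid samples")
    if sweep_regions is None:
        sweep_regions = []
    lengths = {name: len(seq) for name, seq in genome.items()}
    for r in sweep_regions:
        if r.scaffold not in lengths or r.end > lengths[r.scaffold]:
            raise SimConfigError(f"sweep region {r} outside the genome")

    rng = _rng(cfg, 3)
    n_chrom = 2 * cfg.n_diploid
    a1 = np.sum(1.0 / np.arange(1, n_chrom))
    base_rate = cfg.theta_per_bp * a1

    samples = [f"F{i + 1:02d}" for i in range(cfg.n_diploid)]
    haploid = None
    if cfg.n_haploid > 0:
        haploid = "MALE1"
        samples.append(haploid)

    neutral_w = _sfs_weights(n_chrom, 1.0)
    rows, dosages, truth_rows = [], [], []
    for name, codes in genome.items():
        L = lengths[name]
        rate = np.full(L, base_rate)
        skew_arr = np.ones(L)
        for r in sweep_regions:
            if r.scaffold == name:
                rate[r.start : r.end] *= r.reduction
                skew_arr[r.start : r.end] = r.skew
        hit = np.nonzero(rng.random(L) < rate)[0]
        for pos in hit:
            skew = skew_arr[pos]
            w = neutral_w if skew == 1.0 else _sfs_weights(n_chrom, skew)
            j = int(rng.choice(np.arange(1, n_chrom), p=w))
            alleles = np.zeros(n_chrom, dtype=np.int8)
            alleles[rng.permutation(n_chrom)[:j]] = 1
            dos = alleles.reshape(cfg.n_diploid, 2).sum(axis=1).astype(np.int8)
            if haploid is not None:
                p = j / n_chrom
                if rng.random() < cfg.haploid_error_fraction:
                    hap_dos = 1
                    hap_err = True
                else:
                    hap_dos = 2 if rng.random() < p else 0
                    hap_err = False
                dos = np.append(dos, np.int8(hap_dos))
            else:
                hap_err = False
            ref_code = int(codes[pos])
            ref = BASES[ref_code] if ref_code >= 0 else "A"
            alt = BASES[(ref_code + 1 + int(rng.integers(3))) % 4]
            rows.append((name, int(pos), ref, alt))
            dosages.append(dos)
            truth_rows.append((name, int(pos), j, j / n_chrom, skew != 1.0, hap_err))

    n_sites = len(rows)
    n_samples = len(samples)
    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])
    sites["n_alt"] = 1

    # site annotations: passing by default, bad_site_fraction fail one predicate
    qd = np.clip(rng.normal(25, 5, n_sites), 3.0, None)
    fs = np.clip(rng.exponential(5, n_sites), None, 30.0)
    mq = np.clip(rng.normal(55, 3, n_sites), 42.0, None)
    rprs = np.clip(rng.normal(0, 1.5, n_sites), -6.0, 6.0)
    bad = rng.random(n_sites) < cfg.bad_site_fraction
    which = rng.integers(0, 4, n_sites)
    qd = np.where(bad & (which == 0), rng.uniform(0.0, 1.9, n_sites), qd)
    fs = np.where(bad & (which == 1), rng.uniform(61.0, 120.0, n_sites), fs)
    mq = np.where(bad & (which == 2), rng.uniform(10.0, 39.9, n_sites), mq)
    rprs = np.where(bad & (which == 3), rng.uniform(-12.0, -8.1, n_sites), rprs)
    sites["QD"], sites["FS"], sites["MQ"], sites["ReadPosRankSum"] = qd, fs, mq, rprs

    # per-genotype depth and quality
    dip_mask = _coverage_mean_per_site(cfg, sites)
    dp = rng.poisson(dip_mask[:, None], size=(n_sites, n_samples)).astype(np.int32)
    gq = np.clip(np.round(rng.normal(60, 15, (n_sites, n_samples))), 0, 99).astype(np.int32)

    gm = GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosage=(
            np.array(dosages, dtype=np.int8)
            if n_sites
            else np.empty((0, n_samples), np.int8)
        ),
        dp=dp if n_sites else np.empty((0, n_samples), np.int32),
        gq=gq if n_sites else np.empty((0, n_samples), np.int32),
        haploid_sample=haploid,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["scaffold", "pos", "true_count", "true_freq", "in_sweep", "haploid_error"],
    )
    truth["bad_annotation"] = bad if n_sites else np.array([], dtype=bool)
    return gm, truth


def _coverage_mean_per_site(cfg: SimConfig, sites: pd.DataFrame) -> np.ndarray:
    mean = np.full(len(sites), float(cfg.coverage_mean))
    for scaf, start, end in cfg.coverage_dip_regions:
        sel = (sites["scaffold"] == scaf) & (sites["pos"] >= start) & (sites["pos"] < end)
        mean[sel.to_numpy()] = cfg.dip_mean
    return mean


# ---------------------------------------------------------------------------
# Coverage track


def simulate_coverage(cfg: SimConfig, genome: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-window fraction of sites with depth >= 5, as a BED4-shaped frame.

    Depth is Poisson(coverage_mean) per base (Poisson(dip_mean) inside dip
    regions); the per-window fraction is drawn binomially from the Poisson
    upper-tail probability instead of materialising per-base depths.
    """
    cfg.validate()
    if cfg.coverage_mean <= 0:
        raise SimConfigError("coverage_mean must be > 0")
    rng = _rng(cfg, 4)
    p_hi = float(stats.poisson.sf(4, cfg.coverage_mean))
    p_lo = float(stats.poisson.sf(4, cfg.dip_mean))
    rows = []
    for name, codes in genome.items():
        L = len(codes)
        for start in range(0, L, cfg.coverage_window):
            end = min(start + cfg.coverage_window, L)
            p = p_hi
            for scaf, dstart, dend in cfg.coverage_dip_regions:
                if scaf == name and start < dend and dstart < end:
                    p = p_lo
                    break
            frac = rng.binomial(end - start, p) / (end - start)
            rows.append((name, start, end, frac))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "frac_ge5"])


# ---------------------------------------------------------------------------
# PWMs and planted promoter sites


def simulate_pwms(cfg: SimConfig) -> list:
    """Random-consensus PWMs with ``motif_consensus_prob`` on the consensus base."""
    from .motif_scan import PWM

    cfg.validate()
    rng = _rng(cfg, 5)
    c = cfg.motif_consensus_prob
    off = (1 - c) / 3
    pwms = []
    for i in range(cfg.n_motifs):
        consensus = rng.integers(0, 4, cfg.motif_length)
        mat = np.full((cfg.motif_length, 4), off)
        mat[np.arange(cfg.motif_length), consensus] = c
        pwms.append(PWM(f"motif_{i + 1:03d}", mat))
    return pwms


def plant_motif_sites(
    cfg: SimConfig,
    genome: dict[str, np.ndarray],
    genes: list[GeneModel],
    pwms: list,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Write one sampled site of the first PWM into each planted gene's 1 kb
    upstream region; returns (modified genome copy, planted-site table).

    Sites that would fall off the scaffold edge are skipped with a warning.
    """
    rng = _rng(cfg, 6)
    n_plant = int(round(cfg.planted_gene_fraction * len(genes)))
    genome = {name: seq.copy() for name, seq in genome.items()}
    cols = ["motif_id", "scaffold", "pos", "strand", "gene_id"]
    if n_plant == 0 or not pwms:
        return genome, pd.DataFrame(columns=cols)
    pwm = pwms[0]
    w = pwm.width
    chosen = sorted(rng.choice(len(genes), size=n_plant, replace=False))
    rows = []
    for i in chosen:
        g = genes[i]
        L = len(genome[g.scaffold])
        if g.strand == "+":
            lo, hi = g.tss - 1000, g.tss - w
        else:
            lo, hi = g.tss, g.tss + 1000 - w
        lo = max(lo, 0)
        if hi < lo or hi + w > L:
            logger.warning("planted site for %s off scaffold edge; skipped", g.gene_id)
            continue
        pos = int(rng.integers(lo, hi + 1))
        sample = np.array(
            [rng.choice(4, p=pwm.matrix[k]) for k in range(w)], dtype=np.int8
        )
        strand = "+" if rng.random() < 0.5 else "-"
        genome[g.scaffold][pos : pos + w] = (
            sample if strand == "+" else revcomp_codes(sample)
        )
        rows.append((pwm.motif_id, g.scaffold, pos, strand, g.gene_id))
    return genome, pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class SimResult:
    cfg: SimConfig
    genome: dict[str, np.ndarray]
    genes: list[GeneModel]
    gm: GenotypeMatrix
    coverage: pd.DataFrame
    pwms: list
    truth: TruthTable


def simulate_study(cfg: SimConfig) -> SimResult:
    """Run the full generator pipeline under one config.

    Order matters: motif sites are planted into the genome before variants
    are drawn, so VCF REF alleles agree with the emitted FASTA.
    """
    cfg.validate()
    genome = simulate_genome(cfg)
    genes = simulate_gene_models(cfg, genome)
    pwms = simulate_pwms(cfg)
    genome, planted = plant_motif_sites(cfg, genome, genes, pwms)
    regions, sweep_ids = derive_sweep_regions(cfg, genes, genome)
    gm, site_truth = simulate_variants(cfg, genome, genes, regions)
    coverage = simulate_coverage(cfg, genome)
    truth = TruthTable(sweep_gene_ids=sweep_ids, planted_sites=planted, sites=site_truth)
    return SimResult(cfg, genome, genes, gm, coverage, pwms, truth)


def write_study(sim: SimResult, outdir) -> dict[str, Path]:
    """Serialize a SimResult to standard formats; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = {name: len(seq) for name, seq in sim.genome.items()}
    paths = {
        "fasta": outdir / "genome.fa",
        "fai": outdir / "genome.fa.fai",
        "gff3": outdir / "genes.gff3",
        "bed": outdir / "genes.bed",
        "vcf": outdir / "cohort.vcf",
        "coverage": outdir / "coverage.bed",
        "meme": outdir / "motifs.meme",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_planted": outdir / "truth_planted.tsv",
        "truth_sweep_genes": outdir / "truth_sweep_genes.txt",
    }
    dio.write_fasta(sim.genome, paths["fasta"])
    dio.write_fasta_index(sim.genome, paths["fai"])
    dio.write_gff3(sim.genes, paths["gff3"])
    dio.write_genes_bed(sim.genes, paths["bed"])
    dio.write_vcf(sim.gm, paths["vcf"], contig_lengths=lengths)
    dio.write_bed4(sim.coverage, paths["coverage"], value_col="frac_ge5")
    dio.write_meme(sim.pwms, paths["meme"])
    sim.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    sim.truth.planted_sites.to_csv(paths["truth_planted"], sep="\t", index=False)
    paths["truth_sweep_genes"].write_text(
        "".join(f"{g}\n" for g in sorted(sim.truth.sweep_gene_ids))
    )
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    sweeps = [
        SweepRegion(**r) if isinstance(r, dict) else SweepRegion(*r)
        for r in d.pop("sweep_regions", [])
    ]
    dips = [tuple(r) for r in d.pop("coverage_dip_regions", [])]
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(sweep_regions=sweeps, coverage_dip_regions=dips, **d)
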