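"""Two-round hard-filter cascade for a cohort VCF.

Stages, in cascade order:

1. site hard filters on the caller annotations (QD, FS, MQ,
   ReadPosRankSum) plus an optional biallelic restriction;
2. haploid consistency: sites called heterozygous in the haploid male are
   necessarily artifacts in a haplodiploid and are removed;
3. genotype-level masking: individual genotypes with DP or GQ below
   threshold are set to missing;
4. cohort-level filters on the diploid samples: mean depth over called
   genotypes, missing-genotype count, and minor-allele frequency computed
   from the post-masking called dosages.

All hard thresholds follow strict-inequality semantics: a record fails on
``QD < qd_min`` etc., so a value exactly at the threshold survives.  A
missing INFO annotation passes its predicate (the GATK VariantFiltration
convention) and the event is counted in the report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as dio
from .models import GenotypeMatrix


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the cascade; defaults are the study-style values."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    rprs_min: float = -8.0
    biallelic_only: bool = True
    min_mean_dp: float = 5.0
    max_missing_count: int = 4
    maf_min: float = 0.05
    gq_min: int = 9
    dp_min: int = 3

    def __post_init__(self):
        for name in ("qd_min", "fs_max", "mq_min", "rprs_min", "min_mean_dp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.max_missing_count < 0:
            raise ValueError("max_missing_count must be >= 0")


#: reproductions of the study's per-round settings
PRESETS: dict[str, FilterConfig] = {
    # first calling round: hard filters + haploid check, no missing genotypes
    "round1": FilterConfig(
        max_missing_count=0, maf_min=0.0, min_mean_dp=0.0, gq_min=0, dp_min=0
    ),
    # second round before the final vcftools pass: up to 8 missing
    "round2_gatk": FilterConfig(
        max_missing_count=8, maf_min=0.0, min_mean_dp=0.0, gq_min=0, dp_min=0
    ),
    # final stringent pass
    "round2_final": FilterConfig(),
}


@dataclass
class StageReport:
    stage: str
    n_input: int
    n_removed: int
    n_surviving: int
    reasons: Counter = field(default_factory=Counter)

    def check_conservation(self) -> bool:
        return self.n_input == self.n_removed + self.n_surviving


@dataclass
class FilterReport:
    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: StageReport) -> None:
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "n_input": s.n_input,
                    "n_removed": s.n_removed,
                    "n_surviving": s.n_surviving,
                    "reasons": ";".join(
                        f"{k}={v}" for k, v in sorted(s.reasons.items())
                    ),
                }
                for s in self.stages
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def stage_named(self, name: str) -> StageReport:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)


def _info_col(gm: GenotypeMatrix, key: str) -> np.ndarray:
    if key in gm.sites.columns:
        return gm.sites[key].to_numpy(dtype=float)
    return np.full(gm.n_sites, np.nan)


def apply_site_hard_filters(
    gm: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, StageReport]:
    """GATK-style hard filters; missing annotations pass and are counted."""
    qd = _info_col(gm, "QD")
    fs = _info_col(gm, "FS")
    mq = _info_col(gm, "MQ")
    rprs = _info_col(gm, "ReadPosRankSum")
    reasons = Counter()
    # NaN comparisons are False, i.e. a missing annotation never fails
    fail_qd = qd < cfg.qd_min
    fail_fs = fs > cfg.fs_max
    fail_mq = mq < cfg.mq_min
    fail_rprs = rprs < cfg.rprs_min
    n_alt = (
        gm.sites["n_alt"].to_numpy(dtype=int)
        if "n_alt" in gm.sites.columns
        else np.ones(gm.n_sites, dtype=int)
    )
    fail_bi = (n_alt != 1) if cfg.biallelic_only else np.zeros(gm.n_sites, dtype=bool)
    removed = fail_qd | fail_fs | fail_mq | fail_rprs | fail_bi
    reasons["QD"] = int(fail_qd.sum())
    reasons["FS"] = int(fail_fs.sum())
    reasons["MQ"] = int(fail_mq.sum())
    reasons["ReadPosRankSum"] = int(fail_rprs.sum())
    reasons["not_biallelic"] = int(fail_bi.sum())
    for key, arr in (("QD", qd), ("FS", fs), ("MQ", mq), ("ReadPosRankSum", rprs)):
        n_missing = int(np.isnan(arr).sum())
        if n_missing:
            reasons[f"missing_{key}"] = n_missing
    out = gm.subset_sites(~removed)
    rep = StageReport(
        "site_hard_filters", gm.n_sites, int(removed.sum()), out.n_sites, reasons
    )
    return out, rep


def apply_haploid_consistency(
    gm: GenotypeMatrix, haploid_sample: str | None = None
) -> tuple[GenotypeMatrix, StageReport]:
    """Drop sites heterozygous in the haploid individual.

    A missing haploid genotype retains the record (no evidence either way)
    but is counted in the report.
    """
    if haploid_sample is None:
        haploid_sample = gm.haploid_sample
    if haploid_sample is None:
        rep = StageReport("haploid_consistency", gm.n_sites, 0, gm.n_sites)
        return gm.copy(), rep
    col = gm.sample_index(haploid_sample)  # raises KeyError on unknown sample
    hap = gm.dosage[:, col]
    removed = hap == 1
    reasons = Counter(
        {"haploid_het": int(removed.sum()), "haploid_missing": int((hap < 0).sum())}
    )
    out = gm.subset_sites(~removed)
    rep = StageReport(
        "haploid_consistency", gm.n_sites, int(removed.sum()), out.n_sites, reasons
    )
    return out, rep


def apply_genotype_filters(
    gm: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, StageReport]:
    """Mask genotypes with DP < dp_min or GQ < gq_min (absent value fails).

    No records are removed at this stage; the report counts masked
    genotypes instead.
    """
    out = gm.copy()
    fail = (out.dp < cfg.dp_min) | (out.gq < cfg.gq_min)
    newly = fail & (out.dosage >= 0)
    out.dosage[fail] = -1
    reasons = Counter({"genotypes_masked": int(newly.sum())})
    rep = StageReport("genotype_filters", gm.n_sites, 0, gm.n_sites, reasons)
    return out, rep


def apply_cohort_filters(
    gm: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, StageReport]:
    """Mean-depth, missingness and MAF filters over the diploid cohort."""
    cols = gm.diploid_columns()
    dos = gm.dosage[:, cols]
    dp = gm.dp[:, cols]
    called = dos >= 0
    n_called = called.sum(axis=1)
    n_missing = (~called).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_dp = np.where(
            n_called > 0,
            np.where(called, np.maximum(dp, 0), 0).sum(axis=1) / np.maximum(n_called, 1),
            0.0,
        )
        alt = np.where(called, dos, 0).sum(axis=1)
        freq = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)

    all_missing = n_called == 0
    fail_dp = ~all_missing & (mean_dp < cfg.min_mean_dp)
    fail_miss = ~all_missing & (n_missing > cfg.max_missing_count)
    fail_maf = ~all_missing & (maf < cfg.maf_min)
    removed = all_missing | fail_dp | fail_miss | fail_maf
    reasons = Counter(
        {
            "all_missing": int(all_missing.sum()),
            "mean_dp": int(fail_dp.sum()),
            "missing_count": int(fail_miss.sum()),
            "maf": int(fail_maf.sum()),
        }
    )
    out = gm.subset_sites(~removed)
    rep = StageReport(
        "cohort_filters", gm.n_sites, int(removed.sum()), out.n_sites, reasons
    )
    return out, rep


def filter_cascade(
    gm: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    haploid_sample: str | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full cascade on an in-memory matrix."""
    if cfg is None:
        cfg = FilterConfig()
    report = FilterReport()
    out, rep = apply_site_hard_filters(gm, cfg)
    report.add(rep)
    out, rep = apply_haploid_consistency(out, haploid_sample)
    report.add(rep)
    out, rep = apply_genotype_filters(out, cfg)
    report.add(rep)
    out, rep = apply_cohort_filters(out, cfg)
    report.add(rep)
    return out, report


def run_filter_cascade(
    vcf_in,
    vcf_out,
    cfg: FilterConfig | None = None,
    haploid_sample: str | None = None,
    report_tsv=None,
) -> FilterReport:
    """File-level cascade: read VCF, filter, write survivors + report TSV."""
    gm = dio.read_vcf(vcf_in, haploid_sample=haploid_sample)
    out, report = filter_cascade(gm, cfg, haploid_sample)
    dio.write_vcf(out, vcf_out)
    if report_tsv is not None:
        report.to_tsv(report_tsv)
    return report


def relax(cfg: FilterConfig, **kwargs) -> FilterConfig:
    """Return a config with some thresholds replaced (convenience)."""
    return replace(cfg, **kwargs)


def demo_cohort() -> GenotypeMatrix:
    """A hand-constructed 20-record cohort exercising every cascade stage.

    Of the 20 records, six fail the site hard filters (low QD, high FS, low
    MQ, low ReadPosRankSum, a triallelic site, and one failing two
    annotations at once), two are heterozygous in the haploid male, and
    three fail cohort filters (five DP-masked genotypes, a singleton below
    the MAF cut, and mean depth 4); nine clean records survive.
    """
    n_dip = 18
    samples = [f"F{i + 1:02d}" for i in range(n_dip)] + ["MALE1"]
    records = [
        {"QD": 1.5},
        {"FS": 70.0},
        {"MQ": 39.0},
        {"RPRS": -9.0},
        {"alt": "C,G", "n_alt": 2},
        {"QD": 0.5, "FS": 100.0},
        {"dosage": [1] * 6 + [0] * 12 + [1]},
        {"dosage": [0] * 17 + [1] + [1]},
        {"dp": [2] * 5 + [20] * 14, "dosage": [0] * 5 + [1] * 6 + [0] * 7 + [0]},
        {"dosage": [1] + [0] * 17 + [0]},
        {"dp": [4] * 18 + [20]},
    ] + [{} for _ in range(9)]
    sites, dosage, dp, gq = [], [], [], []
    for i, rec in enumerate(records):
        sites.append(
            {
                "scaffold": "scaffold_1",
                "pos": 100 * (i + 1),
                "ref": "A",
                "alt": rec.get("alt", "C"),
                "n_alt": rec.get("n_alt", 1),
                "QD": rec.get("QD", 30.0),
                "FS": rec.get("FS", 5.0),
                "MQ": rec.get("MQ", 55.0),
                "ReadPosRankSum": rec.get("RPRS", 0.0),
            }
        )
        dosage.append(rec.get("dosage", [1] * 6 + [0] * 12 + [0]))
        dp.append(rec.get("dp", [20] * 19))
        gq.append(rec.get("gq", [90] * 19))
    return GenotypeMatrix(
        samples=samples,
        sites=pd.DataFrame(sites),
        dosage=np.array(dosage, dtype=np.int8),
        dp=np.array(dp, dtype=np.int32),
        gq=np.array(gq, dtype=np.int32),
        haploid_sample="MALE1",
    )
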