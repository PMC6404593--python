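"""Core in-memory containers shared across the pipeline.

The package works on three substrates: a genome (dict of scaffold name ->
integer-encoded base array), a list of :class:`GeneModel`, and a
:class:`GenotypeMatrix` holding per-site biallelic genotype dosages for a
cohort together with the site-level annotations that the filter cascade
consumes.

All internal coordinates are 0-based half-open.  GFF3 is converted on
read/write (1-based inclusive); VCF positions are converted to 0-based on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical base order used for integer-encoded sequence and PWM columns
BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
#: code used for N / masked bases
N_CODE = -1

MISSING = -1  # dosage code for an uncalled genotype


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, N_CODE, dtype=np.int8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.where(codes < 0, 4, codes)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on integer codes (A<->T, C<->G); N stays N."""
    out = np.where(codes >= 0, 3 - codes, codes)
    return out[::-1].astype(np.int8)


@dataclass(frozen=True)
class GeneModel:
    """A gene anchor: scaffold span, strand, and the derived TSS.

    ``tss`` is the half-open boundary coordinate at which transcription
    starts: ``start`` for a plus-strand gene, ``end`` for a minus-strand
    gene, so that the upstream interval is ``[tss - d, tss)`` on the plus
    strand and ``[tss, tss + d)`` on the minus strand.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenotypeMatrix:
    """Biallelic genotype dosages for a cohort, plus site annotations.

    Attributes
    ----------
    samples:
        Sample names, column order of the arrays.
    sites:
        One row per variant site with columns ``scaffold``, ``pos``
        (0-based), ``ref``, ``alt`` (comma-joined when multiallelic),
        ``n_alt`` and the float columns ``QD``, ``FS``, ``MQ``,
        ``ReadPosRankSum`` (NaN when absent).
    dosage:
        ``(n_sites, n_samples)`` int8; 0/1/2 alt-allele dosage, -1 missing.
    dp, gq:
        Per-genotype depth and genotype quality, -1 when absent.
    haploid_sample:
        Name of the haploid individual (written as a diploid homozygote by
        the caller emulation), or None.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    haploid_sample: str | None = None

    def __post_init__(self):
        n = len(self.sites)
        for name in ("dosage", "dp", "gq"):
            arr = getattr(self, name)
            if arr.shape != (n, len(self.samples)):
                raise ValueError(
                    f"{name} shape {arr.shape} does not match "
                    f"({n}, {len(self.samples)})"
                )
        if self.haploid_sample is not None and self.haploid_sample not in self.samples:
            raise KeyError(f"haploid sample {self.haploid_sample!r} not in samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def diploid_columns(self) -> np.ndarray:
        """Column indices of the diploid cohort (everything but the haploid)."""
        if self.haploid_sample is None:
            return np.arange(self.n_samples)
        h = self.sample_index(self.haploid_sample)
        return np.array([i for i in range(self.n_samples) if i != h])

    def allele_counts(self, columns: np.ndarray | None = None):
        """Return (called allele count, alt allele count) per site.

        Computed over ``columns`` (default: the diploid cohort), skipping
        missing genotypes; every called genotype contributes two alleles.
        """
        if columns is None:
            columns = self.diploid_columns()
        dos = self.dosage[:, columns]
        called = dos >= 0
        n_called = 2 * called.sum(axis=1)
        alt = np.where(called, dos, 0).sum(axis=1)
        return n_called, alt

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.loc[keep].reset_index(drop=True),
            dosage=self.dosage[keep].copy(),
            dp=self.dp[keep].copy(),
            gq=self.gq[keep].copy(),
            haploid_sample=self.haploid_sample,
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset_sites(np.ones(self.n_sites, dtype=bool))


@dataclass
class TruthTable:
    """Ground truth emitted by the simulator for downstream validation."""

    sweep_gene_ids: set[str] = field(default_factory=set)
    planted_sites: pd.DataFrame | None = None
    sites: pd.DataFrame | None = None
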