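"""Readers and writers for the standard formats the pipeline touches.

FASTA is read through pyfaidx, VCF through cyvcf2, MEME-minimal motif files
through Bio.motifs.  GFF3/BED gene models and BED4 coverage tracks are plain
tab-separated tables handled with pandas.  The VCF writer emits the small
v4.2 subset the simulator and filter cascade produce (INFO QD/FS/MQ/
ReadPosRankSum, FORMAT GT:DP:GQ).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .models import BASES, GeneModel, GenotypeMatrix, decode_seq, encode_seq

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: dict[str, np.ndarray], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, codes in genome.items():
            fh.write(f">{name}\n")
            seq = decode_seq(codes)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fasta_index(genome: dict[str, np.ndarray], path) -> None:
    """Write a samtools-faidx-style .fai for a FASTA produced by write_fasta."""
    offset = 0
    width = 60
    with open(path, "w") as fh:
        for name, codes in genome.items():
            offset += len(name) + 2  # ">name\n"
            n = len(codes)
            n_lines = (n + width - 1) // width if n else 0
            fh.write(f"{name}\t{n}\t{offset}\t{width}\t{width + 1}\n")
            offset += n + n_lines  # sequence bytes plus newlines


def read_fasta(path) -> dict[str, np.ndarray]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    genome = {name: encode_seq(str(fa[name][:])) for name in fa.keys()}
    fa.close()
    return genome


# ---------------------------------------------------------------------------
# Gene models (GFF3 1-based inclusive; BED6 0-based half-open)

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(genes: list[GeneModel], path, source: str = "divscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3_genes(path) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLS, header=None, dtype={"seqid": str}
    )
    df = df[df["type"] == "gene"]
    genes = []
    for row in df.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", f"{row.seqid}:{row.start}-{row.end}")
        genes.append(
            GeneModel(gene_id, str(row.seqid), int(row.start) - 1, int(row.end), row.strand)
        )
    return genes


def write_genes_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.scaffold}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["scaffold", "start", "end", "name", "score", "strand"],
        dtype={"scaffold": str},
    )
    return [
        GeneModel(r.name, r.scaffold, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# BED4 (coverage fraction / mask intervals)


def write_bed4(df: pd.DataFrame, path, value_col: str = "value") -> None:
    out = df[["scaffold", "start", "end", value_col]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed4(path, value_col: str = "value") -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["scaffold", "start", "end", value_col],
        dtype={"scaffold": str},
    )


def read_bed_intervals(path) -> pd.DataFrame:
    """Read the first three columns of any BED file as intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out = df.iloc[:, :3].copy()
    out.columns = ["scaffold", "start", "end"]
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    return out


# ---------------------------------------------------------------------------
# VCF

_INFO_KEYS = ("QD", "FS", "MQ", "ReadPosRankSum")

_VCF_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=divscan\n")
    if contig_lengths:
        for name, length in contig_lengths.items():
            buf.write(f"##contig=<ID={name},length={length}>\n")
    else:
        for name in pd.unique(gm.sites["scaffold"]):
            buf.write(f"##contig=<ID={name}>\n")
    for line in _VCF_HEADER_LINES:
        buf.write(line + "\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(gm.samples) + "\n")
    for i, row in enumerate(gm.sites.itertuples(index=False)):
        info_parts = []
        for key in _INFO_KEYS:
            val = getattr(row, "ReadPosRankSum" if key == "ReadPosRankSum" else key)
            if val is not None and np.isfinite(val):
                info_parts.append(f"{key}={val:.4g}")
        info = ";".join(info_parts) if info_parts else "."
        cells = []
        for s in range(gm.n_samples):
            gt = _GT_STRINGS[int(gm.dosage[i, s])]
            dp = int(gm.dp[i, s])
            gq = int(gm.gq[i, s])
            dp_s = str(dp) if dp >= 0 else "."
            gq_s = str(gq) if gq >= 0 else "."
            cells.append(f"{gt}:{dp_s}:{gq_s}")
        buf.write(
            f"{row.scaffold}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
            f"{info}\tGT:DP:GQ\t" + "\t".join(cells) + "\n"
        )
    Path(path).write_text(buf.getvalue())


def read_vcf(path, haploid_sample: str | None = None) -> GenotypeMatrix:
    """Parse a VCF into a GenotypeMatrix via cyvcf2.

    Multiallelic records are kept (``n_alt`` > 1) so the biallelic filter
    can count them; their dosage is the count of non-reference alleles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage, dp, gq = [], [], []
    for v in vcf:
        info = {k: v.INFO.get(k) for k in _INFO_KEYS}
        rows.append(
            {
                "scaffold": v.CHROM,
                "pos": v.POS - 1,
                "ref": v.REF,
                "alt": ",".join(v.ALT) if v.ALT else ".",
                "n_alt": len(v.ALT),
                **{k: (np.nan if info[k] is None else float(info[k])) for k in _INFO_KEYS},
            }
        )
        gts = v.genotypes  # [allele0, allele1, phased]
        dos_row = np.full(len(samples), -1, dtype=np.int8)
        for s, gt in enumerate(gts):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                dos_row[s] = sum(1 for a in alleles if a > 0)
        dosage.append(dos_row)
        fmt_dp = v.format("DP")
        fmt_gq = v.format("GQ")
        dp.append(_fmt_int_column(fmt_dp, len(samples)))
        gq.append(_fmt_int_column(fmt_gq, len(samples)))
    vcf.close()
    sites = pd.DataFrame(
        rows,
        columns=["scaffold", "pos", "ref", "alt", "n_alt", *_INFO_KEYS],
    )
    n = len(sites)
    shape = (n, len(samples))
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosage=np.array(dosage, dtype=np.int8).reshape(shape) if n else np.empty(shape, np.int8),
        dp=np.array(dp, dtype=np.int32).reshape(shape) if n else np.empty(shape, np.int32),
        gq=np.array(gq, dtype=np.int32).reshape(shape) if n else np.empty(shape, np.int32),
        haploid_sample=haploid_sample,
    )


def _fmt_int_column(arr, n_samples: int) -> np.ndarray:
    if arr is None:
        return np.full(n_samples, -1, dtype=np.int32)
    flat = np.asarray(arr).reshape(n_samples, -1)[:, 0].astype(float)
    out = np.where(np.isfinite(flat) & (flat >= 0), flat, -1)
    return out.astype(np.int32)


# ---------------------------------------------------------------------------
# PWMs (MEME minimal format and plain 4 x w TSV)


def write_meme(pwms, path, background: np.ndarray | None = None) -> None:
    """Write PWMs (objects with .motif_id and .matrix of shape (w, 4))."""
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg))
            + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            # large nsites: Bio.motifs reconstructs counts as freq * nsites,
            # so a small value would quantise the probabilities on re-read
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.matrix.shape[0]} "
                f"nsites= 100000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path):
    """Read a MEME-minimal motif file; returns a list of motif_scan.PWM."""
    from .motif_scan import PWM

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array(
            [[m.pwm[b][i] for b in BASES] for i in range(m.length)], dtype=float
        )
        out.append(PWM(m.name, mat))
    return out


def read_pwm_tsv(path, motif_id: str | None = None):
    """Read a plain 4 x w (rows A,C,G,T) or w x 4 matrix TSV as one PWM."""
    from .motif_scan import PWM

    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] == 4 and mat.shape[1] != 4:
        mat = mat.T
    if motif_id is None:
        motif_id = Path(path).stem
    return PWM(motif_id, mat, renormalize=True)
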