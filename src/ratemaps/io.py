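"""Readers/writers for BED, bedGraph, GFF3, VCF and the map table format.

Internal coordinates are 0-based half-open; GFF3 and VCF are converted at
this boundary (both are 1-based on disk).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HaplotypePanel
from .synthdata import AnnotationSet, MotifSet, SubstitutionSet
from .variants import PolymorphismSet

__all__ = [
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_gff3",
    "read_gff3",
    "write_vcf",
    "read_vcf",
    "write_map_table",
    "read_map_table",
]


def write_bed(path, intervals_by_scaffold: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for scaf in intervals_by_scaffold:
            for s, e in np.asarray(intervals_by_scaffold[scaf]).reshape(-1, 2):
                fh.write(f"{scaf}\t{int(s)}\t{int(e)}\n")


def read_bed(path) -> dict[str, np.ndarray]:
    out: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            scaf, s, e = line.split()[:3]
            out.setdefault(scaf, []).append([int(s), int(e)])
    return {k: np.asarray(v, dtype=np.int64) for k, v in out.items()}


def write_bedgraph(path, table: pd.DataFrame, value_col: str) -> None:
    """Write scaffold/start/end/value rows; NaN values are skipped."""
    sub = table[table[value_col].notna()]
    with open(path, "w") as fh:
        for _, row in sub.iterrows():
            fh.write(
                f"{row['scaffold']}\t{int(row['start'])}\t{int(row['end'])}\t{row[value_col]:.8g}\n"
            )


def read_bedgraph(path, value_col: str = "value") -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["scaffold", "start", "end", value_col], comment="#"
    )


def write_gff3(path, annotations: AnnotationSet, feature_type: str = "exon") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf, iv in annotations.intervals.items():
            for i, (s, e) in enumerate(np.asarray(iv).reshape(-1, 2)):
                fh.write(
                    f"{scaf}\tratemaps\t{feature_type}\t{int(s) + 1}\t{int(e)}\t.\t+\t.\t"
                    f"ID={feature_type}_{scaf}_{i}\n"
                )


def read_gff3(path, feature_type: str = "exon") -> AnnotationSet:
    out: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5 or f[2] != feature_type:
                continue
            out.setdefault(f[0], []).append([int(f[3]) - 1, int(f[4])])
    from .intervals import merge_intervals

    return AnnotationSet({k: merge_intervals(v) for k, v in out.items()})


def write_vcf(path, snps: PolymorphismSet, sample_prefix: str = "ind") -> None:
    """Minimal VCF 4.2 with GT fields (phased ``|`` or unphased ``/``)."""
    sep = "|" if snps.phased else "/"
    n_ind = snps.n_individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if snps.length:
            fh.write(f"##contig=<ID={snps.scaffold},length={snps.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"{sample_prefix}{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for i in range(snps.n_sites):
            gts = []
            for j in range(n_ind):
                a, b = snps.genotypes[i, j]
                gts.append(f"{'.' if a < 0 else a}{sep}{'.' if b < 0 else b}")
            fh.write(
                f"{snps.scaffold}\t{snps.positions[i] + 1}\t.\t{snps.ref[i]}\t{snps.alt[i]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, scaffold: str | None = None) -> PolymorphismSet:
    """Read biallelic SNPs for one scaffold (the first one by default)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    positions, refs, alts, gts = [], [], [], []
    scaf = scaffold
    length = None
    phased = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        if scaf is None:
            scaf = rec.CHROM
        if rec.CHROM != scaf:
            continue
        positions.append(rec.POS - 1)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        g = np.asarray(rec.genotypes)  # (n_ind, 3): allele, allele, phased
        gts.append(g[:, :2])
        phased = phased and bool(np.all(g[:, 2] == 1))
    try:
        idx = (vcf.seqnames or []).index(scaf)
        length = (vcf.seqlens or [None])[idx]
    except (ValueError, IndexError, TypeError):
        length = None
    n_sites = len(positions)
    gt_arr = (
        np.stack(gts).astype(np.int8) if n_sites else np.empty((0, 0, 2), dtype=np.int8)
    )
    return PolymorphismSet(
        scaf or "unknown",
        np.asarray(positions, dtype=np.int64),
        np.asarray(refs),
        np.asarray(alts),
        gt_arr,
        phased=phased,
        length=length,
    )


def write_map_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_map_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_substitutions_bed(path, subs: SubstitutionSet) -> None:
    write_bed(
        path,
        {
            scaf: np.column_stack([p, p + 1])
            for scaf, p in subs.positions.items()
            if p.size
        },
    )


def read_substitutions_bed(path) -> SubstitutionSet:
    iv = read_bed(path)
    return SubstitutionSet({k: v[:, 0].astype(np.int64) for k, v in iv.items()})


def write_motifs_bed(path, motifs: MotifSet) -> None:
    half = motifs.width // 2
    write_bed(
        path,
        {
            scaf: np.column_stack([np.maximum(m - half, 0), m + motifs.width - half])
            for scaf, m in motifs.midpoints.items()
            if m.size
        },
    )


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
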