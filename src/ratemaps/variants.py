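"""Biallelic SNP sets and the bespoke post-genotyping filters.

Two filters guard the LD analysis against genotyping artifacts that would
introduce artificial breaks in LD: dense SNP clusters (>= k SNPs within a
w-bp span) and sites showing an excess of heterozygotes under the exact
conditional Hardy-Weinberg test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "PolymorphismSet",
    "filter_snp_clusters",
    "hwe_excess_het_pvalue",
    "filter_hwe",
]


@dataclass
class PolymorphismSet:
    """Biallelic SNP records with per-individual diploid genotypes.

    ``genotypes`` has shape ``(n_sites, n_individuals, 2)`` with allele
    codes 0 (ref) / 1 (alt) and -1 for missing; positions are 0-based and
    sorted per scaffold.
    """

    scaffold: str
    positions: np.ndarray
    ref: np.ndarray  # dtype '<U1'
    alt: np.ndarray
    genotypes: np.ndarray
    phased: bool = True
    length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must be (n_sites, n_ind, 2)")
        if self.genotypes.shape[0] != self.positions.size:
            raise ValueError("genotype rows must match positions")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must strictly increase")

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, keep: np.ndarray) -> "PolymorphismSet":
        return PolymorphismSet(
            self.scaffold,
            self.positions[keep],
            self.ref[keep],
            self.alt[keep],
            self.genotypes[keep],
            self.phased,
            self.length,
        )

    @classmethod
    def from_panel(cls, panel: HaplotypePanel) -> "PolymorphismSet":
        """Pair consecutive haplotypes into phased diploid individuals."""
        if panel.n_hap % 2:
            raise ValueError("need an even number of haplotypes")
        n_ind = panel.n_hap // 2
        gt = panel.haplotypes.T.reshape(panel.n_sites, n_ind, 2).astype(np.int8)
        return cls(
            panel.scaffold,
            panel.positions,
            np.full(panel.n_sites, "A"),
            np.full(panel.n_sites, "G"),
            gt,
            phased=True,
            length=panel.length,
        )

    def to_panel(self) -> HaplotypePanel:
        if not self.phased:
            raise ValueError("cannot expand unphased genotypes to haplotypes")
        hap = self.genotypes.reshape(self.n_sites, -1).T.astype(np.uint8)
        length = self.length or (int(self.positions[-1]) + 1 if self.n_sites else 1)
        return HaplotypePanel(self.scaffold, length, self.positions, hap)


def filter_snp_clusters(
    snps: PolymorphismSet, k: int = 3, w: int = 10
) -> tuple[PolymorphismSet, int]:
    """Remove every SNP lying in any w-bp span holding >= k SNPs.

    A span of ``w`` consecutive bp contains positions ``p .. p+w-1``; the
    i-th through (i+k-1)-th SNPs share such a span iff their positions
    differ by at most ``w - 1``.
    """
    if k < 2 or w < 1:
        raise ValueError("require k >= 2 and w >= 1")
    pos = snps.positions
    bad = np.zeros(pos.size, dtype=bool)
    for i in range(pos.size - k + 1):
        if pos[i + k - 1] - pos[i] <= w - 1:
            bad[i : i + k] = True
    return snps.subset(~bad), int(bad.sum())


def hwe_excess_het_pvalue(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact one-sided heterozygote-excess Hardy-Weinberg p-value.

    Conditions on the minor-allele count; p is the probability, under the
    exact (Levene-Haldane) distribution, of at least the observed number of
    heterozygotes. Monomorphic and singleton sites return 1.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n < 2:
        raise ValueError("need >= 2 genotyped diploids")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor <= 1:
        return 1.0
    # enumerate heterozygote counts with the parity of the minor-allele count
    weights: dict[int, int] = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        n_hom_minor = (n_minor - h) // 2
        n_hom_major = n - h - n_hom_minor
        if n_hom_major < 0:
            continue
        weights[h] = (
            math.factorial(n)
            // (math.factorial(n_hom_minor) * math.factorial(h) * math.factorial(n_hom_major))
            * 2**h
        )
    total = sum(weights.values())
    tail = sum(wgt for h, wgt in weights.items() if h >= n_het)
    return tail / total


def filter_hwe(
    snps: PolymorphismSet, p_threshold: float = 0.01
) -> tuple[PolymorphismSet, int]:
    """Remove sites whose heterozygote-excess exact p falls below threshold.

    Sites with any missing genotype are skipped (kept, with a warning).
    """
    import warnings

    keep = np.ones(snps.n_sites, dtype=bool)
    skipped = 0
    for i in range(snps.n_sites):
        gt = snps.genotypes[i]
        if np.any(gt < 0):
            skipped += 1
            continue
        het = int(np.sum(gt[:, 0] != gt[:, 1]))
        hom_alt = int(np.sum((gt[:, 0] == 1) & (gt[:, 1] == 1)))
        hom_ref = gt.shape[0] - het - hom_alt
        if hwe_excess_het_pvalue(het, hom_ref, hom_alt) < p_threshold:
            keep[i] = False
    if skipped:
        warnings.warn(f"{skipped} sites with missing genotypes skipped by HWE filter")
    return snps.subset(keep), int((~keep).sum())
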