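"""Phased haplotype panels at typed positions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HaplotypePanel"]


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes at segregating sites on one scaffold.

    ``haplotypes`` has shape ``(n_hap, n_sites)``; ``positions`` are 0-based
    and strictly increasing.
    """

    scaffold: str
    length: int
    positions: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotypes must be (n_hap, n_sites)")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must strictly increase")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.size

    def derived_counts(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int64)

    def segregating(self) -> "HaplotypePanel":
        """Drop sites that are monomorphic in the sample."""
        c = self.derived_counts()
        keep = (c > 0) & (c < self.n_hap)
        return HaplotypePanel(
            self.scaffold, self.length, self.positions[keep], self.haplotypes[:, keep]
        )

    def window(self, start: int, end: int) -> "HaplotypePanel":
        keep = (self.positions >= start) & (self.positions < end)
        return HaplotypePanel(
            self.scaffold, self.length, self.positions[keep], self.haplotypes[:, keep]
        )

    def pairwise_diversity(self) -> float:
        """Mean pairwise difference per site over the whole region (pi/bp).

        Uses the unbiased per-site estimator ``2 p (1-p) n / (n-1)`` summed
        over segregating sites and divided by the region length.
        """
        n = self.n_hap
        if n < 2:
            raise ValueError("need >= 2 haplotypes")
        p = self.haplotypes.mean(axis=0)
        per_site = 2.0 * p * (1.0 - p) * n / (n - 1)
        return float(per_site.sum() / self.length)

    def mean_r2(self, max_pairs: int = 2000, seed: int = 0) -> float:
        """Mean squared allele-frequency correlation over SNP pairs."""
        seg = self.segregating()
        s = seg.n_sites
        if s < 2:
            return float("nan")
        pairs = [(i, j) for i in range(s) for j in range(i + 1, s)]
        if len(pairs) > max_pairs:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in idx]
        h = seg.haplotypes.astype(np.float64)
        vals = []
        for i, j in pairs:
            a, b = h[:, i], h[:, j]
            va, vb = a.var(), b.var()
            if va == 0 or vb == 0:
                continue
            cov = ((a - a.mean()) * (b - b.mean())).mean()
            vals.append(cov * cov / (va * vb))
        return float(np.mean(vals)) if vals else float("nan")
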