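"""Synthetic data generators for every pipeline input.

These emulate the statistical structure the downstream analyses assume:
branch substitutions dropped at window-varying rates, coalescent haplotype
panels (see :mod:`ratemaps.coalescent`), exon annotations, and hotspot-motif
placements enriched in high-recombination regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescent import simulate_haplotypes  # noqa: F401  (re-export)
from .genome import GenomeSpec, TrueRateTrack
from .intervals import AccessibilityMask, intersect_intervals, merge_intervals

__all__ = [
    "SubstitutionSet",
    "AnnotationSet",
    "MotifSet",
    "simulate_substitutions",
    "simulate_annotations",
    "place_motifs",
    "simulate_haplotypes",
]


@dataclass
class SubstitutionSet:
    """Per-scaffold sorted 0-based substitution positions."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, scaffold: str) -> np.ndarray:
        return self.positions.get(scaffold, np.empty(0, dtype=np.int64))

    def total(self) -> int:
        return int(sum(p.size for p in self.positions.values()))


@dataclass
class AnnotationSet:
    """Per-scaffold sorted, non-overlapping feature intervals (e.g. exons)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, scaffold: str) -> np.ndarray:
        return self.intervals.get(scaffold, np.empty((0, 2), dtype=np.int64))

    def total_bp(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values())
        )


@dataclass
class MotifSet:
    """Per-scaffold sorted motif midpoints (0-based), fixed width."""

    midpoints: dict[str, np.ndarray] = field(default_factory=dict)
    width: int = 12

    def get(self, scaffold: str) -> np.ndarray:
        return self.midpoints.get(scaffold, np.empty(0, dtype=np.int64))

    def total(self) -> int:
        return int(sum(p.size for p in self.midpoints.values()))


def _tracks_by_scaffold(
    spec: GenomeSpec, track: TrueRateTrack | dict[str, TrueRateTrack]
) -> dict[str, TrueRateTrack]:
    if isinstance(track, TrueRateTrack):
        if len(spec.names) != 1 or track.scaffold != spec.names[0]:
            raise ValueError("single track requires a single matching scaffold")
        return {track.scaffold: track}
    missing = set(spec.names) - set(track)
    if missing:
        raise ValueError(f"no rate track for scaffolds: {sorted(missing)}")
    return dict(track)


def simulate_substitutions(
    spec: GenomeSpec,
    mu_track: TrueRateTrack | dict[str, TrueRateTrack],
    branch_gens: float,
    seed: int,
    mask: AccessibilityMask | None = None,
) -> SubstitutionSet:
    """Drop single-lineage substitutions at window-varying rates.

    Each accessible site mutates independently with probability
    ``mu * branch_gens`` (error if that product exceeds 1 anywhere:
    the per-site substitution probability would be saturated).
    """
    if branch_gens <= 0:
        raise ValueError("branch_gens must be positive")
    tracks = _tracks_by_scaffold(spec, mu_track)
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, length in zip(spec.names, spec.lengths):
        track = tracks[name]
        if np.any(track.rates * branch_gens > 1.0):
            raise ValueError("mu * branch_gens > 1: substitution probability saturated")
        acc = (
            mask.get(name)
            if mask is not None
            else np.array([[0, length]], dtype=np.int64)
        )
        pos_chunks: list[np.ndarray] = []
        for k in range(track.rates.size):
            p = float(track.rates[k] * branch_gens)
            if p <= 0:
                continue
            seg = intersect_intervals(
                [(int(track.breaks[k]), int(min(track.breaks[k + 1], length)))], acc
            )
            for s, e in seg:
                n_sites = int(e - s)
                count = rng.binomial(n_sites, p)
                if count:
                    pos_chunks.append(
                        np.sort(rng.choice(n_sites, size=count, replace=False)) + s
                    )
        out[name] = (
            np.sort(np.concatenate(pos_chunks)) if pos_chunks else np.empty(0, dtype=np.int64)
        )
    return SubstitutionSet(out)


def simulate_annotations(
    spec: GenomeSpec, exon_density: float, mean_exon_len: int, seed: int
) -> AnnotationSet:
    """Scatter exon-like intervals to a target genome-wide density.

    Exon counts are Poisson, lengths geometric with the given mean, and
    starts uniform; overlapping draws are merged, so the realized fraction
    sits slightly below ``exon_density`` (negligibly for densities < 0.2).
    """
    if not (0.0 <= exon_density < 1.0):
        raise ValueError("exon_density must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name, length in zip(spec.names, spec.lengths):
        if exon_density == 0.0:
            out[name] = np.empty((0, 2), dtype=np.int64)
            continue
        n_exons = rng.poisson(exon_density * length / mean_exon_len)
        if n_exons == 0:
            out[name] = np.empty((0, 2), dtype=np.int64)
            continue
        lens = rng.geometric(1.0 / mean_exon_len, size=n_exons)
        starts = rng.integers(0, length, size=n_exons)
        ends = np.minimum(starts + lens, length)
        out[name] = merge_intervals(np.column_stack([starts, ends]))
    return AnnotationSet(out)


def place_motifs(
    spec: GenomeSpec,
    rec_track: TrueRateTrack | dict[str, TrueRateTrack],
    enrichment: float,
    n_motifs: int,
    seed: int,
    width: int = 12,
) -> MotifSet:
    """Place motif midpoints preferentially in high-recombination regions.

    Sampling density at position x is proportional to
    ``1 + (enrichment - 1) * rate(x) / max(rate)``; ``enrichment = 1``
    gives uniform placement.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if n_motifs > sum(spec.lengths):
        raise ValueError("more motifs than genome positions")
    tracks = _tracks_by_scaffold(spec, rec_track)
    rng = np.random.default_rng(seed)
    # one global weight per rate-track segment, across scaffolds
    rmax = max(float(t.rates.max()) for t in tracks.values())
    seg_scaf: list[str] = []
    seg_bounds: list[tuple[int, int]] = []
    seg_w: list[float] = []
    for name, length in zip(spec.names, spec.lengths):
        t = tracks[name]
        for k in range(t.rates.size):
            s, e = int(t.breaks[k]), int(min(t.breaks[k + 1], length))
            if e <= s:
                continue
            rel = t.rates[k] / rmax if rmax > 0 else 0.0
            seg_scaf.append(name)
            seg_bounds.append((s, e))
            seg_w.append((1.0 + (enrichment - 1.0) * rel) * (e - s))
    w = np.asarray(seg_w)
    w /= w.sum()
    picks = rng.choice(len(seg_w), size=n_motifs, p=w)
    mids: dict[str, list[int]] = {name: [] for name in spec.names}
    for k in picks:
        s, e = seg_bounds[k]
        mids[seg_scaf[k]].append(int(rng.integers(s, e)))
    return MotifSet(
        {name: np.sort(np.asarray(v, dtype=np.int64)) for name, v in mids.items()},
        width=width,
    )
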