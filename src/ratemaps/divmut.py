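"""Windowed neutral divergence, diversity, and mutation-rate conversion.

Under neutrality the per-site divergence ``d`` accumulated along a single
lineage over ``T`` years at per-generation mutation rate ``mu`` and
generation time ``G`` years is ``d = mu * (T / G)``; the conversions below
use this identity in both directions. ``d`` is divergence to the
reconstructed ancestor, so ``T`` enters un-doubled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import AccessibilityMask, GenomicWindow, merge_intervals, sliding_windows, subtract_intervals
from .panel import HaplotypePanel
from .synthdata import AnnotationSet, SubstitutionSet

__all__ = [
    "DivergenceMap",
    "build_accessibility_mask",
    "windowed_divergence",
    "windowed_diversity",
    "mutation_rate_from_divergence",
    "divergence_time_from_rate",
    "rate_conversion_table",
    "mutation_rate_map",
]

# Windows with fewer accessible sites than this fraction of their span are
# reported as missing: the divergence ratio would be dominated by noise.
MIN_ACCESSIBLE_FRACTION = 0.10


@dataclass
class DivergenceMap:
    """Per-window divergent/accessible counts and the ratio ``d``.

    ``d`` is NaN where a window is masked below the accessibility threshold
    or has no accessible sites; ``partial`` flags truncated terminal windows.
    """

    table: pd.DataFrame  # scaffold, start, end, divergent, accessible, d, partial

    def genome_wide_d(self) -> float:
        t = self.table
        acc = t["accessible"].sum()
        return float(t["divergent"].sum() / acc) if acc > 0 else float("nan")

    def with_mu(self, g_years: float, t_years: float) -> pd.DataFrame:
        out = self.table.copy()
        out["mu"] = mutation_rate_from_divergence(out["d"].to_numpy(), g_years, t_years)
        return out


def build_accessibility_mask(
    annotations: AnnotationSet,
    callable_mask: AccessibilityMask,
    flank: int = 10_000,
    extra_masks: dict[str, np.ndarray] | None = None,
    scaffold_lengths: dict[str, int] | None = None,
) -> AccessibilityMask:
    """Callable sites minus flanked functional regions minus extra masks.

    Each annotated feature is extended by ``flank`` bp on both sides before
    subtraction (default 10 kb, keeping clear of direct selection).
    Features extending beyond scaffold bounds are clipped.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    out: dict[str, np.ndarray] = {}
    for scaf, callable_iv in callable_mask.intervals.items():
        feats = annotations.get(scaf)
        length = None if scaffold_lengths is None else scaffold_lengths.get(scaf)
        if feats.shape[0]:
            lo = np.maximum(feats[:, 0] - flank, 0)
            hi = feats[:, 1] + flank
            if length is not None:
                hi = np.minimum(hi, length)
            flanked = merge_intervals(np.column_stack([lo, hi]))
        else:
            flanked = np.empty((0, 2), dtype=np.int64)
        acc = subtract_intervals(callable_iv, flanked)
        if extra_masks and scaf in extra_masks:
            acc = subtract_intervals(acc, extra_masks[scaf])
        out[scaf] = acc
    return AccessibilityMask(out)


def windowed_divergence(
    subs: SubstitutionSet,
    snps: "np.ndarray | dict[str, np.ndarray] | None",
    mask: AccessibilityMask,
    window: int,
    step: int | None = None,
    scaffold_lengths: dict[str, int] | None = None,
    min_accessible_fraction: float = MIN_ACCESSIBLE_FRACTION,
    drop_segregating_from_denominator: bool = False,
) -> DivergenceMap:
    """Sliding-window neutral divergence: divergent / accessible sites.

    Substitution positions that coincide with segregating polymorphisms
    (``snps``, per-scaffold position arrays) are excluded from the
    numerator; by default they stay in the denominator (the site remains
    alignable/callable — set ``drop_segregating_from_denominator`` to
    remove them there too).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    step = window if step is None else step
    if step > window:
        raise ValueError("step must not exceed window")
    if scaffold_lengths is None:
        scaffold_lengths = {
            s: int(iv[-1, 1]) for s, iv in mask.intervals.items() if iv.shape[0]
        }
    snp_pos: dict[str, np.ndarray] = {}
    if snps is not None:
        snp_pos = dict(snps) if isinstance(snps, dict) else {next(iter(scaffold_lengths)): snps}

    rows = []
    for scaf, length in scaffold_lengths.items():
        sub_p = subs.get(scaf)
        acc_mask = mask
        if drop_segregating_from_denominator and scaf in snp_pos:
            acc_mask = mask.subtract({scaf: np.column_stack([snp_pos[scaf], snp_pos[scaf] + 1])})
        keep = mask.contains(scaf, sub_p)
        sub_p = sub_p[keep]
        if scaf in snp_pos:
            sub_p = sub_p[~np.isin(sub_p, snp_pos[scaf])]
        for win, partial in sliding_windows(scaf, length, window, step):
            acc = acc_mask.accessible_bp(win)
            lo = np.searchsorted(sub_p, win.start, side="left")
            hi = np.searchsorted(sub_p, win.end, side="left")
            div = int(hi - lo)
            d = (
                div / acc
                if acc > 0 and acc >= min_accessible_fraction * len(win)
                else float("nan")
            )
            rows.append((scaf, win.start, win.end, div, acc, d, partial))
    return DivergenceMap(
        pd.DataFrame(
            rows,
            columns=["scaffold", "start", "end", "divergent", "accessible", "d", "partial"],
        )
    )


def windowed_diversity(
    panel: HaplotypePanel,
    mask: AccessibilityMask,
    window: int,
    step: int | None = None,
) -> pd.DataFrame:
    """Per-window nucleotide diversity pi (per accessible site).

    pi per window sums the unbiased per-site heterozygosity
    ``2 p (1-p) n / (n-1)`` over accessible segregating sites and divides by
    the number of accessible sites; windows with none are NaN.
    """
    if panel.n_hap < 2:
        raise ValueError("need >= 2 haplotypes")
    n = panel.n_hap
    p = panel.haplotypes.mean(axis=0)
    per_site = 2.0 * p * (1.0 - p) * n / (n - 1)
    accessible_site = mask.contains(panel.scaffold, panel.positions)
    rows = []
    for win, partial in sliding_windows(panel.scaffold, panel.length, window, step):
        acc = mask.accessible_bp(win)
        inwin = (panel.positions >= win.start) & (panel.positions < win.end) & accessible_site
        pi = float(per_site[inwin].sum() / acc) if acc > 0 else float("nan")
        rows.append((panel.scaffold, win.start, win.end, pi, acc, partial))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "pi", "accessible", "partial"])


def mutation_rate_from_divergence(d, g_years: float, t_years: float):
    """mu = d * G / T (mutations per bp per generation)."""
    if g_years <= 0 or t_years <= 0:
        raise ValueError("G and T must be positive")
    return np.asarray(d, dtype=float) * g_years / t_years if np.ndim(d) else float(d) * g_years / t_years


def divergence_time_from_rate(d, g_years: float, mu: float):
    """T = d * G / mu (years)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if g_years <= 0:
        raise ValueError("G must be positive")
    return np.asarray(d, dtype=float) * g_years / mu if np.ndim(d) else float(d) * g_years / mu


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    from decimal import ROUND_HALF_UP, Decimal

    exp = int(np.floor(np.log10(abs(x))))
    scaled = Decimal(repr(x)).scaleb(-exp + sig - 1)
    # absorb binary float error (e.g. 537.4999999999999) before half-up
    scaled = scaled.quantize(Decimal(1).scaleb(-8), rounding=ROUND_HALF_UP)
    q = scaled.quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(q.scaleb(exp - sig + 1))


def rate_conversion_table(
    d: float,
    g_years: list[float],
    t_years: list[float],
    mu_pedigree: list[float],
    sig: int = 3,
) -> pd.DataFrame:
    """Cross-tabulated rate/time conversions for one divergence value.

    One row per generation time: divergence-based mutation rates
    ``mu(G, T)`` for each divergence time, and pedigree-rate-based
    divergence times ``T(G, mu)`` in Mya for each pedigree mutation rate.
    Values are rounded half-up to ``sig`` significant figures.
    """
    if not (g_years and t_years and mu_pedigree):
        raise ValueError("all parameter lists must be non-empty")
    rows = []
    for g in g_years:
        row: dict[str, float] = {"G_years": g}
        for mu in mu_pedigree:
            row[f"T_mya_at_mu_{mu:g}"] = _round_sig(
                divergence_time_from_rate(d, g, mu) / 1e6, sig
            )
        for t in t_years:
            row[f"mu_at_T_{t / 1e6:g}mya"] = _round_sig(
                mutation_rate_from_divergence(d, g, t), sig
            )
        rows.append(row)
    return pd.DataFrame(rows)


def mutation_rate_map(
    divmap: DivergenceMap, g_years: float, t_years: float
) -> pd.DataFrame:
    """Divergence map converted to per-window mutation rates (mu column)."""
    return divmap.with_mu(g_years, t_years)
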