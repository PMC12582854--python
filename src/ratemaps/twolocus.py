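"""Demography-aware two-locus likelihood lookup tables.

For a pair of biallelic loci separated by population-scaled recombination
rate rho = 4 N_ref r, the sampling probability of each folded two-locus
haplotype-count configuration ``(n00, n01, n10, n11)`` is estimated by
Monte-Carlo simulation of the two-locus coalescent under a
piecewise-constant demographic history.

Conditioning on both loci being segregating is done in the low-mutation
limit: each simulated genealogy pair contributes every (branch-A, branch-B)
combination with weight ``len_A * len_B``, which is the exact conditional
contribution of that genealogy, rather than sampling a single mutation per
locus (same expectation, far lower variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel

__all__ = ["TwoLocusTable", "build_two_locus_table", "enumerate_folded_configs", "fold_config"]

DEFAULT_RHO_GRID = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)


def fold_config(n00: int, n01: int, n10: int, n11: int) -> tuple[int, int, int, int]:
    """Canonical folded orientation of a two-locus count configuration.

    Alleles at each locus are unpolarized, so configurations related by
    swapping allele labels at either locus are identified; the canonical
    form is the lexicographically smallest of the four relabelings.
    """
    variants = [
        (n00, n01, n10, n11),
        (n10, n11, n00, n01),  # swap locus-A labels
        (n01, n00, n11, n10),  # swap locus-B labels
        (n11, n10, n01, n00),  # swap both
    ]
    return min(variants)


def enumerate_folded_configs(n_hap: int) -> list[tuple[int, int, int, int]]:
    """All folded configurations with both loci segregating."""
    seen = set()
    for n00 in range(n_hap + 1):
        for n01 in range(n_hap + 1 - n00):
            for n10 in range(n_hap + 1 - n00 - n01):
                n11 = n_hap - n00 - n01 - n10
                if not (0 < n10 + n11 < n_hap):  # locus A segregating
                    continue
                if not (0 < n01 + n11 < n_hap):  # locus B segregating
                    continue
                seen.add(fold_config(n00, n01, n10, n11))
    return sorted(seen)


@dataclass
class TwoLocusTable:
    """P(folded config | rho) on a rho grid, from Monte-Carlo sampling."""

    n_hap: int
    rho_grid: np.ndarray
    configs: list[tuple[int, int, int, int]]
    prob: np.ndarray  # (n_grid, n_configs), rows sum to 1
    demography: str
    reps: int
    ref_size: float

    def __post_init__(self) -> None:
        self.rho_grid = np.asarray(self.rho_grid, dtype=float)
        if self.rho_grid.size < 2:
            raise ValueError("rho grid needs at least 2 points")
        if self.rho_grid[0] != 0 or np.any(np.diff(self.rho_grid) <= 0):
            raise ValueError("rho grid must start at 0 and strictly ascend")
        sums = self.prob.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("config probabilities must sum to 1 per grid point")
        self._index = {c: i for i, c in enumerate(self.configs)}

    def config_index(self, config: tuple[int, int, int, int]) -> int:
        return self._index[fold_config(*config)]

    def log_prob_interp(self, config_idx: np.ndarray, rho: np.ndarray) -> np.ndarray:
        """log P(config | rho), log-probabilities interpolated linearly in rho.

        Interpolation is linear on the log scale (the convention of
        composite-likelihood LD estimators: between grid points the
        expected objective then decreases away from the truth by the
        Kullback-Leibler divergence). rho values beyond the grid ends are
        clamped to the end points.
        """
        rho = np.clip(np.asarray(rho, dtype=float), self.rho_grid[0], self.rho_grid[-1])
        hi = np.clip(np.searchsorted(self.rho_grid, rho, side="right"), 1, self.rho_grid.size - 1)
        lo = hi - 1
        w = (rho - self.rho_grid[lo]) / (self.rho_grid[hi] - self.rho_grid[lo])
        logp = np.log(self.prob)
        return (1 - w) * logp[lo, config_idx] + w * logp[hi, config_idx]

    def expected_r2(self) -> np.ndarray:
        """E[r^2 of the sampled configuration] per grid point (diagnostic)."""
        out = np.zeros(self.rho_grid.size)
        c = np.asarray(self.configs, dtype=float)
        n = float(self.n_hap)
        pa = (c[:, 2] + c[:, 3]) / n
        pb = (c[:, 1] + c[:, 3]) / n
        d = c[:, 3] / n - pa * pb
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2 = np.where(denom > 0, d * d / denom, 0.0)
        for g in range(self.rho_grid.size):
            out[g] = float((self.prob[g] * r2).sum())
        return out


def _sample_event_time(
    model: DemographicModel, t0: float, coal_pairs: float, const_rate: float, u: float
) -> float:
    """Next-event time for coalescence hazard k(k-1)/2 / 2N(t) + const."""
    target = -math.log(u)
    t = t0
    acc = 0.0
    times = model.times
    idx = int(np.searchsorted(np.asarray(times), t, side="right") - 1)
    while True:
        rate = coal_pairs / (2.0 * model.sizes[idx]) + const_rate
        t_next = times[idx + 1] if idx + 1 < len(times) else math.inf
        span = t_next - t
        if rate > 0 and acc + rate * span >= target:
            return t + (target - acc) / rate
        acc += rate * span
        t = t_next
        idx += 1


def _simulate_two_locus_branches(
    n_hap: int, r_between: float, model: DemographicModel, rng: np.random.Generator
):
    """One two-locus genealogy; returns per-locus (leafset masks, lengths).

    Lineages carry ancestral material at locus A, locus B, or both;
    recombination (rate ``r_between`` per dual-carrier per generation)
    splits a dual carrier. Returns, for each locus, the leaf-set bitmask
    and branch length of every non-root node in that locus' marginal tree.
    """
    # per-locus trees: node -> (time, leafset mask); parents assigned on merge
    masks_a: list[int] = [1 << i for i in range(n_hap)]
    times_a: list[float] = [0.0] * n_hap
    lens_a: list[float | None] = [None] * n_hap  # filled when parent created
    masks_b = list(masks_a)
    times_b = list(times_a)
    lens_b: list[float | None] = [None] * n_hap

    # active lineages: (a_node or -1, b_node or -1)
    active: list[list[int]] = [[i, i] for i in range(n_hap)]
    count_a = count_b = n_hap
    t = 0.0
    full_mask = (1 << n_hap) - 1
    while count_a > 1 or count_b > 1:
        k = len(active)
        n_dual = sum(1 for a, b in active if a >= 0 and b >= 0)
        coal_pairs = k * (k - 1) / 2.0
        rec_rate = n_dual * r_between
        t = _sample_event_time(model, t, coal_pairs, rec_rate, rng.random())
        coal_hazard = coal_pairs / (2.0 * model.size_at(t))
        if rng.random() * (coal_hazard + rec_rate) < rec_rate:
            # recombination: split a random dual carrier
            duals = [i for i, (a, b) in enumerate(active) if a >= 0 and b >= 0]
            i = duals[rng.integers(len(duals))]
            a, b = active[i]
            active[i] = [a, -1]
            active.append([-1, b])
            continue
        i, j = rng.choice(k, size=2, replace=False)
        (a1, b1), (a2, b2) = active[int(i)], active[int(j)]
        new = [-1, -1]
        if a1 >= 0 and a2 >= 0:
            node = len(masks_a)
            masks_a.append(masks_a[a1] | masks_a[a2])
            times_a.append(t)
            lens_a.append(None)
            lens_a[a1] = t - times_a[a1]
            lens_a[a2] = t - times_a[a2]
            new[0] = node
            if masks_a[node] == full_mask:
                count_a = 1
                new[0] = -1  # locus A fully coalesced: material now inert
            else:
                count_a -= 1
        else:
            new[0] = a1 if a1 >= 0 else a2
        if b1 >= 0 and b2 >= 0:
            node = len(masks_b)
            masks_b.append(masks_b[b1] | masks_b[b2])
            times_b.append(t)
            lens_b.append(None)
            lens_b[b1] = t - times_b[b1]
            lens_b[b2] = t - times_b[b2]
            new[1] = node
            if masks_b[node] == full_mask:
                count_b = 1
                new[1] = -1
            else:
                count_b -= 1
        else:
            new[1] = b1 if b1 >= 0 else b2
        keep = [x for idx2, x in enumerate(active) if idx2 not in (int(i), int(j))]
        if new != [-1, -1]:
            keep.append(new)
        active = keep

    out = []
    for masks, lens in ((masks_a, lens_a), (masks_b, lens_b)):
        m = [mk for mk, ln in zip(masks, lens) if ln is not None and ln > 0]
        l = [ln for ln in lens if ln is not None and ln > 0]
        out.append((m, l))
    return out


def build_two_locus_table(
    n_hap: int,
    model: DemographicModel,
    grid=DEFAULT_RHO_GRID,
    reps: int = 20_000,
    seed: int = 0,
    ref_size: float | None = None,
    smoothing: float = 0.5,
) -> TwoLocusTable:
    """Monte-Carlo two-locus lookup table under a demographic model.

    Parameters
    ----------
    n_hap : sample size in haplotypes.
    model : piecewise-constant demographic history.
    grid : ascending rho values starting at 0 (rho = 4 * ref_size * r).
    reps : genealogies per grid point.
    ref_size : diploid size defining the rho scaling (default: the model's
        ancestral size).
    smoothing : total pseudo-weight (in units of the mean per-replicate
        weight) spread over all feasible configs, so Monte-Carlo zeros do
        not produce -inf composite log-likelihoods.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    grid = np.asarray(grid, dtype=float)
    if ref_size is None:
        ref_size = model.ancestral_size
    configs = enumerate_folded_configs(n_hap)
    index = {c: i for i, c in enumerate(configs)}
    rng = np.random.default_rng(seed)
    prob = np.zeros((grid.size, len(configs)))
    # packed-key fold: elementwise min over the four relabelings, computed on
    # base-(n_hap+1) packed integers (lexicographic order is preserved)
    base = n_hap + 1
    key_lut = np.full(base ** 4, -1, dtype=np.int64)
    for c, ci in index.items():
        key_lut[((c[0] * base + c[1]) * base + c[2]) * base + c[3]] = ci
    for g, rho in enumerate(grid):
        r_between = rho / (4.0 * ref_size)
        weights = np.zeros(len(configs))
        for _ in range(reps):
            (ma, la), (mb, lb) = _simulate_two_locus_branches(n_hap, r_between, model, rng)
            A = np.array([[(mk >> i) & 1 for i in range(n_hap)] for mk in ma], dtype=np.int64)
            B = np.array([[(mk >> i) & 1 for i in range(n_hap)] for mk in mb], dtype=np.int64)
            la_arr = np.asarray(la)
            lb_arr = np.asarray(lb)
            n11 = A @ B.T
            na = A.sum(axis=1)[:, None]
            nb = B.sum(axis=1)[None, :]
            n10 = na - n11
            n01 = nb - n11
            n00 = n_hap - n11 - n10 - n01
            w = la_arr[:, None] * lb_arr[None, :]
            k1 = ((n00 * base + n01) * base + n10) * base + n11
            k2 = ((n10 * base + n11) * base + n00) * base + n01
            k3 = ((n01 * base + n00) * base + n11) * base + n10
            k4 = ((n11 * base + n10) * base + n01) * base + n00
            key = np.minimum(np.minimum(k1, k2), np.minimum(k3, k4))
            ci = key_lut[key.ravel()]
            np.add.at(weights, ci, w.ravel())
        if weights.sum() <= 0:
            raise RuntimeError("two-locus conditioning produced no weight; increase reps")
        weights = weights + smoothing * weights.sum() / reps / len(configs)
        prob[g] = weights / weights.sum()
    return TwoLocusTable(
        n_hap=n_hap,
        rho_grid=grid,
        configs=configs,
        prob=prob,
        demography=model.name,
        reps=reps,
        ref_size=float(ref_size),
    )


def pair_config(col_a: np.ndarray, col_b: np.ndarray) -> tuple[int, int, int, int]:
    """Folded count configuration of two 0/1 haplotype columns."""
    a = np.asarray(col_a, dtype=np.int64)
    b = np.asarray(col_b, dtype=np.int64)
    n11 = int((a & b).sum())
    n10 = int((a & (1 - b)).sum())
    n01 = int(((1 - a) & b).sum())
    n00 = a.size - n11 - n10 - n01
    return fold_config(n00, n01, n10, n11)
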