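"""Sequential (SMC') coalescent-with-recombination simulator.

Simulates phased haplotype panels under a piecewise-constant demographic
history and an arbitrary piecewise-constant recombination map. The first
marginal genealogy is drawn from the standard coalescent; moving along the
sequence, recombination breakpoints arrive at rate ``r(x) * L(tree)`` per bp
(``L`` = total branch length in generations) and each breakpoint triggers a
local tree update: the lineage above the recombination point is erased and
the detached subtree re-coalesces into the remaining genealogy (the SMC'
variant, which permits re-coalescence into the erased branch's own span).

Mutations follow the infinite-sites model: Poisson down each marginal tree
with per-bp per-generation rate ``mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel
from .genome import TrueRateTrack
from .panel import HaplotypePanel

__all__ = ["simulate_haplotypes", "sample_tree", "Tree"]


@dataclass
class Tree:
    """Rooted binary genealogy over ``n`` leaves (ids ``0..n-1``)."""

    parent: np.ndarray  # int, -1 at root
    time: np.ndarray  # node times, generations
    children: list[list[int]]
    root: int

    @property
    def n_leaves(self) -> int:
        return (self.parent.size + 1) // 2

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros(self.parent.size)
        for v in range(self.parent.size):
            p = self.parent[v]
            if p >= 0:
                out[v] = self.time[p] - self.time[v]
        return out

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self, v: int) -> list[int]:
        n = self.n_leaves
        stack = [v]
        out = []
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
            else:
                stack.extend(self.children[u])
        return sorted(out)

    def tmrca(self) -> float:
        return float(self.time[self.root])


def sample_tree(n: int, model: DemographicModel, rng: np.random.Generator) -> Tree:
    """Draw a coalescent genealogy of ``n`` lineages under ``model``."""
    if n < 2:
        raise ValueError("need at least two lineages")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t = model.sample_coalescent_time(t, k * (k - 1) / 2.0, rng.random())
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        time[nxt] = t
        children[nxt] = [a, b]
        parent[a] = nxt
        parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Tree(parent, time, children, root=active[0])


def _smc_prime_update(tree: Tree, model: DemographicModel, rng: np.random.Generator) -> None:
    """Apply one SMC' recombination update in place."""
    # recombination point: branch proportional to length, height uniform
    bl = tree.branch_lengths()
    probs = bl / bl.sum()
    c = int(rng.choice(bl.size, p=probs))
    u = tree.time[c] + rng.random() * bl[c]

    # detach c from its parent p and splice p out of the tree
    p = int(tree.parent[c])
    tree.children[p].remove(c)
    d = tree.children[p][0]
    g = int(tree.parent[p])
    if g >= 0:
        tree.children[g].remove(p)
        tree.children[g].append(d)
        tree.parent[d] = g
        root = tree.root
    else:
        tree.parent[d] = -1
        root = d
    tree.parent[c] = -1
    tree.children[p] = []

    # remaining edges: (node, low, high); root edge extends to infinity
    edges = []
    for v in range(tree.parent.size):
        if v == c or v == p:
            continue
        pv = tree.parent[v]
        if pv >= 0:
            edges.append((v, float(tree.time[v]), float(tree.time[pv])))
    edges.append((root, float(tree.time[root]), math.inf))

    # re-coalescence time: piecewise-constant hazard k(t) / (2 N(t))
    bounds = sorted(
        {lo for _, lo, _ in edges if lo > u}
        | {hi for _, _, hi in edges if u < hi < math.inf}
        | {float(tt) for tt in model.times if tt > u}
    )
    bounds.append(math.inf)
    target = -math.log(rng.random())
    acc = 0.0
    t = u
    t_star = None
    for b in bounds:
        k = sum(1 for _, lo, hi in edges if lo <= t < hi)
        rate = k / (2.0 * model.size_at(t))
        span = b - t
        if rate > 0 and acc + rate * span >= target:
            t_star = t + (target - acc) / rate
            break
        acc += rate * span
        t = b
    assert t_star is not None  # root edge guarantees termination
    crossing = [v for v, lo, hi in edges if lo <= t_star < hi]
    x = int(crossing[rng.integers(len(crossing))])

    # rejoin: reuse spliced node id p as the new coalescence node
    px = int(tree.parent[x])
    tree.time[p] = t_star
    tree.children[p] = [c, x]
    tree.parent[c] = p
    if px >= 0:
        tree.children[px].remove(x)
        tree.children[px].append(p)
        tree.parent[p] = px
        tree.parent[x] = p
        tree.root = root
    else:
        tree.parent[p] = -1
        tree.parent[x] = p
        tree.root = p if x == root else root
    if x == root and px < 0:
        tree.root = p


def _drop_mutations(
    tree: Tree,
    span: tuple[float, float],
    mu: float,
    rng: np.random.Generator,
    sink: dict[int, tuple[int, ...]],
) -> None:
    a, b = span
    if b <= a or mu <= 0:
        return
    lo, hi = int(math.ceil(a)), int(math.ceil(b))
    if hi <= lo:
        return  # no integer site in this span
    total = tree.total_length()
    n_mut = rng.poisson(mu * (b - a) * total)
    if n_mut == 0:
        return
    bl = tree.branch_lengths()
    probs = bl / bl.sum()
    branches = rng.choice(bl.size, size=n_mut, p=probs)
    positions = rng.integers(lo, hi, size=n_mut)
    for pos, v in zip(positions, branches):
        pos = int(pos)
        if pos in sink:  # infinite sites: at most one mutation per bp
            continue
        sink[pos] = tuple(tree.leaves_below(int(v)))


def simulate_haplotypes(
    model: DemographicModel,
    mu: float,
    rec_track: TrueRateTrack | float,
    n_hap: int,
    length: int,
    seed: int,
    scaffold: str = "scaffold_1",
) -> HaplotypePanel:
    """Simulate a phased 0/1 haplotype panel (infinite-sites, SMC').

    Parameters
    ----------
    model : demographic history (diploid sizes, generations).
    mu : mutation rate per bp per generation.
    rec_track : recombination rate track in crossovers/bp/generation, or a
        constant rate.
    n_hap : number of sampled haplotypes (>= 2).
    length : region length in bp.
    seed : RNG seed; identical seeds give identical panels.
    """
    if n_hap < 2:
        raise ValueError("need n_hap >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    if not isinstance(model, DemographicModel):
        raise TypeError("model must be a DemographicModel")
    if isinstance(rec_track, (int, float)):
        rec_track = TrueRateTrack.constant(scaffold, length, float(rec_track))
    if rec_track.length < length:
        raise ValueError("recombination track shorter than requested region")

    rng = np.random.default_rng(seed)
    tree = sample_tree(n_hap, model, rng)
    sink: dict[int, tuple[int, ...]] = {}
    pos = 0.0
    while pos < length:
        total = tree.total_length()
        g_here = rec_track.cumulative(np.array([pos]))[0]
        if rec_track.total - g_here <= 0:
            nxt = float(length)
        else:
            g_next = g_here + rng.exponential(1.0 / total)
            nxt = min(float(length), rec_track.inverse_cumulative(g_next))
        _drop_mutations(tree, (pos, nxt), mu, rng, sink)
        if nxt >= length:
            break
        _smc_prime_update(tree, model, rng)
        pos = max(nxt, np.nextafter(pos, math.inf))

    positions = np.array(sorted(sink), dtype=np.int64)
    hap = np.zeros((n_hap, positions.size), dtype=np.uint8)
    for j, p in enumerate(positions):
        hap[list(sink[int(p)]), j] = 1
    return HaplotypePanel(scaffold=scaffold, length=int(length), positions=positions, haplotypes=hap)
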