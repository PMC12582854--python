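"""Piecewise-constant demographic histories for coalescent simulation.

Time is measured in generations before the present; population sizes are
diploid effective sizes, so a pair of lineages coalesces at rate
``1 / (2 N(t))`` per generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DemographicModel",
    "equilibrium",
    "bottleneck_decline",
    "AYE_AYE_ANCESTRAL_N",
    "AYE_AYE_CURRENT_N",
    "AYE_AYE_DECLINE_GENERATIONS",
    "PYRHO_POPSIZES_STRING",
    "PYRHO_EPOCHTIMES_STRING",
]

# Aye-aye bottleneck-decline history: ancestral size, present-day size, and
# the number of generations over which the decline occurred.
AYE_AYE_ANCESTRAL_N = 11_695
AYE_AYE_CURRENT_N = 1_285
AYE_AYE_DECLINE_GENERATIONS = 1_133

# Population-size-history strings in the upstream LD estimator's own
# convention; stored verbatim for provenance, not interpreted here.
PYRHO_POPSIZES_STRING = (
    "2570, 2944.784, 3374.224, 3866.288, 4430.111, 5076.157, 5816.415, 6585, 23389"
)
PYRHO_EPOCHTIMES_STRING = "1,2,3,4,5,6,71,133"


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant size history.

    ``sizes[i]`` is the diploid effective size on the epoch starting at
    ``times[i]`` generations before present; ``times[0]`` must be 0 and
    times strictly ascend. The last epoch extends to infinity.
    """

    sizes: tuple[float, ...]
    times: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.sizes) == 0:
            raise ValueError("demography needs at least one epoch")
        if len(self.sizes) != len(self.times):
            raise ValueError("sizes and times must have equal length")
        if self.times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must be positive")
        t = np.asarray(self.times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("epoch times must strictly ascend")

    def size_at(self, t: float) -> float:
        """Diploid size at time ``t`` generations before present."""
        idx = int(np.searchsorted(np.asarray(self.times), t, side="right") - 1)
        return float(self.sizes[idx])

    @property
    def ancestral_size(self) -> float:
        return float(self.sizes[-1])

    def sample_coalescent_time(
        self, t0: float, pair_rate_pairs: float, u: float
    ) -> float:
        """Invert the piecewise-exponential coalescent waiting time.

        Given ``k`` lineages, pass ``pair_rate_pairs = k (k-1) / 2`` and a
        uniform deviate ``u``; returns the absolute time (> ``t0``) at which
        the next coalescence would occur if no other event intervenes.
        """
        target = -np.log(u)  # required integrated hazard
        t = t0
        acc = 0.0
        times = self.times
        n_ep = len(times)
        idx = int(np.searchsorted(np.asarray(times), t, side="right") - 1)
        while True:
            rate = pair_rate_pairs / (2.0 * self.sizes[idx])
            t_next = times[idx + 1] if idx + 1 < n_ep else np.inf
            span = t_next - t
            if acc + rate * span >= target:
                return t + (target - acc) / rate
            acc += rate * span
            t = t_next
            idx += 1

    def to_msprime(self):
        """Equivalent msprime.Demography (test-time cross-validation only)."""
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=self.sizes[0])
        for size, time in zip(self.sizes[1:], self.times[1:]):
            dem.add_population_parameters_change(
                time=time, initial_size=size, population="pop"
            )
        return dem


def equilibrium(n: float = AYE_AYE_ANCESTRAL_N) -> DemographicModel:
    """Constant-size model (default: the aye-aye ancestral size)."""
    return DemographicModel(sizes=(float(n),), times=(0.0,), name=f"equilibrium_N{n:g}")


def bottleneck_decline(
    n_ancestral: float = AYE_AYE_ANCESTRAL_N,
    n_current: float = AYE_AYE_CURRENT_N,
    decline_generations: float = AYE_AYE_DECLINE_GENERATIONS,
    n_steps: int = 32,
    kind: str = "exponential",
) -> DemographicModel:
    """Bottleneck-then-decline history discretized to piecewise-constant epochs.

    The population declines from ``n_ancestral`` to ``n_current`` over the
    final ``decline_generations`` generations, at a constant rate —
    exponential in N by default (``kind="exponential"``); ``kind="linear"``
    interpolates N linearly instead.
    """
    if kind not in ("exponential", "linear"):
        raise ValueError("kind must be 'exponential' or 'linear'")
    # Epoch boundaries from present (0) back to the bottleneck.
    bounds = np.linspace(0.0, decline_generations, n_steps + 1)
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    frac = mids / decline_generations  # 0 at present, 1 at bottleneck
    if kind == "exponential":
        sizes = n_current * (n_ancestral / n_current) ** frac
    else:
        sizes = n_current + (n_ancestral - n_current) * frac
    all_sizes = tuple(float(s) for s in sizes) + (float(n_ancestral),)
    all_times = tuple(float(t) for t in bounds[:-1]) + (float(decline_generations),)
    return DemographicModel(sizes=all_sizes, times=all_times, name=f"bottleneck_decline_{kind}")
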