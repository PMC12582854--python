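"""Synthetic genome descriptions and ground-truth rate tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicWindow

__all__ = ["GenomeSpec", "TrueRateTrack"]


@dataclass(frozen=True)
class GenomeSpec:
    """Scaffold names, lengths (bp) and per-scaffold GC fractions."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    gc: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lengths) == len(self.gc)):
            raise ValueError("names, lengths and gc must have equal length")
        if any(L <= 0 for L in self.lengths):
            raise ValueError("scaffold lengths must be positive")
        if any(not (0.0 <= g <= 1.0) for g in self.gc):
            raise ValueError("GC fractions must lie in [0, 1]")

    @classmethod
    def single(cls, length: int, name: str = "scaffold_1", gc: float = 0.41) -> "GenomeSpec":
        return cls((name,), (int(length),), (gc,))

    def length_of(self, name: str) -> int:
        return self.lengths[self.names.index(name)]

    def gc_of(self, name: str) -> float:
        return self.gc[self.names.index(name)]

    def sequence(self, name: str, seed: int) -> str:
        """Draw a random sequence with the scaffold's GC composition."""
        rng = np.random.default_rng(seed)
        g = self.gc_of(name)
        p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=self.length_of(name), p=p)
        return bases.tobytes().decode()


@dataclass
class TrueRateTrack:
    """Piecewise-constant ground-truth rate along one scaffold.

    Units are the caller's (mutations/bp/generation or crossovers/bp/
    generation). Windows must tile the scaffold contiguously.
    """

    scaffold: str
    breaks: np.ndarray  # window boundaries, length k+1, breaks[0] == 0
    rates: np.ndarray  # length k, >= 0
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=np.float64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.breaks.ndim != 1 or self.breaks.size != self.rates.size + 1:
            raise ValueError("need len(breaks) == len(rates) + 1")
        if self.breaks[0] != 0 or np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must start at 0 and strictly ascend")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        self._cum = np.concatenate([[0.0], np.cumsum(self.rates * np.diff(self.breaks))])

    @classmethod
    def constant(cls, scaffold: str, length: int, rate: float) -> "TrueRateTrack":
        return cls(scaffold, np.array([0.0, float(length)]), np.array([float(rate)]))

    @classmethod
    def from_windows(cls, windows: list[GenomicWindow], rates: list[float]) -> "TrueRateTrack":
        if not windows:
            raise ValueError("empty track")
        breaks = [windows[0].start] + [w.end for w in windows]
        for a, b in zip(windows[:-1], windows[1:]):
            if a.end != b.start or a.scaffold != b.scaffold:
                raise ValueError("windows must tile the scaffold contiguously")
        if windows[0].start != 0:
            raise ValueError("track must start at position 0")
        return cls(windows[0].scaffold, np.asarray(breaks, dtype=float), np.asarray(rates, dtype=float))

    @property
    def length(self) -> float:
        return float(self.breaks[-1])

    def rate_at(self, positions: np.ndarray) -> np.ndarray:
        """Rate at each physical position (vectorized)."""
        pos = np.asarray(positions, dtype=np.float64)
        idx = np.clip(np.searchsorted(self.breaks, pos, side="right") - 1, 0, self.rates.size - 1)
        return self.rates[idx]

    def cumulative(self, positions: np.ndarray) -> np.ndarray:
        """Integrated rate from 0 to each position (e.g. genetic distance)."""
        pos = np.asarray(positions, dtype=np.float64)
        idx = np.clip(np.searchsorted(self.breaks, pos, side="right") - 1, 0, self.rates.size - 1)
        return self._cum[idx] + (pos - self.breaks[idx]) * self.rates[idx]

    def inverse_cumulative(self, cum: float) -> float:
        """Physical position at which the integrated rate reaches ``cum``."""
        if cum >= self._cum[-1]:
            return self.length
        idx = int(np.searchsorted(self._cum, cum, side="right") - 1)
        # skip zero-rate windows (cumulative flat there)
        while self.rates[idx] == 0:
            idx += 1
        return float(self.breaks[idx] + (cum - self._cum[idx]) / self.rates[idx])

    @property
    def total(self) -> float:
        """Total integrated rate over the scaffold."""
        return float(self._cum[-1])

    def mean_rate(self) -> float:
        return self.total / self.length
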