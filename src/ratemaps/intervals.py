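"""Half-open genomic intervals, windows, and accessibility masks.

All coordinates are 0-based half-open ``[start, end)`` throughout the
package; 1-based formats (VCF, GFF3) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicWindow",
    "AccessibilityMask",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "sliding_windows",
]


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """A half-open window ``[start, end)`` on a scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def _as_array(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be (start, end) pairs")
    return arr


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge overlapping/adjacent half-open intervals."""
    arr = _as_array(intervals)
    if arr.shape[0] == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(
    base: Iterable[tuple[int, int]], remove: Iterable[tuple[int, int]]
) -> np.ndarray:
    """Set difference ``base \\ remove`` of half-open interval sets."""
    base_m = merge_intervals(base)
    rem_m = merge_intervals(remove)
    if base_m.shape[0] == 0 or rem_m.shape[0] == 0:
        return base_m
    out: list[list[int]] = []
    j = 0
    for s, e in base_m:
        cur = s
        while j < rem_m.shape[0] and rem_m[j, 1] <= cur:
            j += 1
        k = j
        while k < rem_m.shape[0] and rem_m[k, 0] < e:
            rs, re = rem_m[k]
            if rs > cur:
                out.append([cur, min(rs, e)])
            cur = max(cur, re)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append([cur, e])
    return _as_array(out)


def intersect_intervals(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> np.ndarray:
    """Intersection of two half-open interval sets."""
    am = merge_intervals(a)
    bm = merge_intervals(b)
    out: list[list[int]] = []
    i = j = 0
    while i < am.shape[0] and j < bm.shape[0]:
        s = max(am[i, 0], bm[j, 0])
        e = min(am[i, 1], bm[j, 1])
        if s < e:
            out.append([int(s), int(e)])
        if am[i, 1] < bm[j, 1]:
            i += 1
        else:
            j += 1
    return _as_array(out)


def sliding_windows(
    scaffold: str, length: int, window: int, step: int | None = None
) -> Iterator[tuple[GenomicWindow, bool]]:
    """Yield ``(window, is_partial)`` sliding windows covering a scaffold.

    The last window is truncated at the scaffold end and flagged partial.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    step = window if step is None else step
    if not (0 < step <= window):
        raise ValueError("require 0 < step <= window")
    start = 0
    while start < length:
        end = min(start + window, length)
        yield GenomicWindow(scaffold, start, end), end - start < window
        if end >= length:
            break
        start += step


@dataclass
class AccessibilityMask:
    """Per-scaffold sets of accessible half-open intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[tuple[int, int]]]) -> "AccessibilityMask":
        return cls({scaf: merge_intervals(iv) for scaf, iv in d.items()})

    @classmethod
    def full(cls, lengths: Mapping[str, int]) -> "AccessibilityMask":
        """Fully accessible mask for the given scaffold lengths."""
        return cls({s: np.array([[0, L]], dtype=np.int64) for s, L in lengths.items()})

    def get(self, scaffold: str) -> np.ndarray:
        return self.intervals.get(scaffold, np.empty((0, 2), dtype=np.int64))

    def accessible_bp(self, win: GenomicWindow) -> int:
        """Number of accessible sites inside a window."""
        iv = self.get(win.scaffold)
        if iv.shape[0] == 0:
            return 0
        s = np.clip(iv[:, 0], win.start, win.end)
        e = np.clip(iv[:, 1], win.start, win.end)
        return int(np.maximum(e - s, 0).sum())

    def contains(self, scaffold: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: which positions fall in an accessible interval."""
        iv = self.get(scaffold)
        positions = np.asarray(positions, dtype=np.int64)
        if iv.shape[0] == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < iv[idx[ok], 1]
        return out

    def subtract(self, scaffold_intervals: Mapping[str, Iterable[tuple[int, int]]]) -> "AccessibilityMask":
        out = {}
        for scaf, iv in self.intervals.items():
            rem = scaffold_intervals.get(scaf, [])
            out[scaf] = subtract_intervals(iv, rem)
        return AccessibilityMask(out)

    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))
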