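"""Haar multi-scale decomposition and scale-specific correlation analysis.

Feature tracks (nucleotide diversity, neutral divergence, recombination
rate, GC content, exon content) binned at 1 kb are decomposed with the
orthonormal Haar pyramid

    s[j,k] = (s[j-1,2k] + s[j-1,2k+1]) / sqrt(2)
    d[j,k] = (s[j-1,2k] - s[j-1,2k+1]) / sqrt(2)

so that level-j detail coefficients isolate variation at the 2^j-bin
(2^j kb) scale and total energy is conserved. Scale-specific structure is
then summarized by pairwise Kendall rank correlations of detail
coefficients and by through-origin linear models of recombination details
on the remaining features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTrack",
    "WaveletDecomposition",
    "bin_feature_tracks",
    "log_transform_rates",
    "split_halves",
    "haar_dwt",
    "inverse_haar_dwt",
    "kendall_detail_correlations",
    "scale_linear_models",
]

DEFAULT_BIN = 1000
MAX_LEVEL = 12
# halves with more than this fraction of imputed (masked) bins are flagged
IMPUTATION_FLAG_FRACTION = 0.20


@dataclass
class FeatureTrack:
    """One binned feature along a scaffold; NaN marks masked bins."""

    scaffold: str
    name: str
    values: np.ndarray
    accessible_frac: np.ndarray | None = None
    bin_size: int = DEFAULT_BIN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def masked_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def imputed(self) -> tuple[np.ndarray, float]:
        """Masked bins replaced by the track mean; returns imputed fraction."""
        v = self.values.copy()
        bad = np.isnan(v)
        if bad.all():
            raise ValueError("track is entirely masked")
        v[bad] = np.nanmean(self.values)
        return v, float(bad.mean())


@dataclass
class WaveletDecomposition:
    """Orthonormal Haar pyramid output for one track (or track half)."""

    name: str
    levels: int
    details: list[np.ndarray]  # details[j-1] = level-j coefficients
    smooth: np.ndarray
    imputed_fraction: float = 0.0
    flagged: bool = False

    def detail(self, level: int) -> np.ndarray:
        if not (1 <= level <= self.levels):
            raise ValueError(f"level must be in 1..{self.levels}")
        return self.details[level - 1]

    def energy(self) -> float:
        return float(sum((d**2).sum() for d in self.details) + (self.smooth**2).sum())

    @staticmethod
    def scale_kb(level: int, bin_size: int = DEFAULT_BIN) -> float:
        return 2**level * bin_size / 1000.0


def haar_dwt(values: np.ndarray, levels: int | None = None, name: str = "") -> WaveletDecomposition:
    """Orthonormal Haar pyramid of a dyadic-length vector.

    ``len(values)`` must equal ``2**J`` for some J >= ``levels``; callers
    truncate first (see :func:`split_halves`). Energy is conserved exactly.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    j_max = int(np.log2(n)) if n > 0 else 0
    if n == 0 or 2**j_max != n:
        raise ValueError("input length must be a power of two")
    if levels is None:
        levels = min(MAX_LEVEL, j_max)
    if levels > j_max:
        raise ValueError("more levels than log2(length)")
    details = []
    s = v
    for _ in range(levels):
        a = s[0::2]
        b = s[1::2]
        details.append((a - b) / np.sqrt(2.0))
        s = (a + b) / np.sqrt(2.0)
    return WaveletDecomposition(name=name, levels=levels, details=details, smooth=s)


def inverse_haar_dwt(dec: WaveletDecomposition) -> np.ndarray:
    """Exact inverse of :func:`haar_dwt`."""
    s = dec.smooth
    for d in reversed(dec.details):
        out = np.empty(2 * s.size)
        out[0::2] = (s + d) / np.sqrt(2.0)
        out[1::2] = (s - d) / np.sqrt(2.0)
        s = out
    return s


def split_halves(track: FeatureTrack, max_level: int = MAX_LEVEL) -> tuple[WaveletDecomposition, WaveletDecomposition]:
    """Decompose the two scaffold halves, truncated to dyadic length.

    Each half keeps its largest power-of-two number of bins measured from
    the scaffold midpoint outward; masked bins are mean-imputed first and
    halves with > 20% imputation flagged.
    """
    v, _ = track.imputed()
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 bins to split")
    mid = n // 2
    j = min(max_level, int(np.log2(mid)))
    size = 2**j
    halves = []
    for lo, hi in ((mid - size, mid), (mid, mid + size)):
        seg = v[lo:hi]
        imput = float(np.isnan(track.values[lo:hi]).mean())
        dec = haar_dwt(seg, levels=j, name=track.name)
        dec.imputed_fraction = imput
        dec.flagged = imput > IMPUTATION_FLAG_FRACTION
        halves.append(dec)
    return halves[0], halves[1]


def log_transform_rates(track: FeatureTrack) -> FeatureTrack:
    """ln(x + eps) with eps = half the smallest positive value.

    Applied to rate-like tracks (recombination, diversity, divergence)
    before linear modeling; composition tracks (GC, exon) are left alone.
    """
    v = track.values
    pos = v[np.isfinite(v) & (v > 0)]
    if pos.size == 0:
        raise ValueError("cannot log-transform an all-zero track")
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("rates must be non-negative")
    eps = 0.5 * float(pos.min())
    out = np.where(np.isfinite(v), np.log(v + eps), np.nan)
    return FeatureTrack(track.scaffold, track.name + "_log", out, track.accessible_frac, track.bin_size)


def bin_feature_tracks(
    scaffold: str,
    length: int,
    sequence: str | None = None,
    exons: np.ndarray | None = None,
    pi: pd.DataFrame | None = None,
    divergence: pd.DataFrame | None = None,
    recombination: pd.DataFrame | None = None,
    mask=None,
    bin_size: int = DEFAULT_BIN,
    min_accessible_fraction: float = 0.1,
) -> dict[str, FeatureTrack]:
    """Assemble the five feature tracks on a common 1 kb grid.

    ``pi``/``divergence``/``recombination`` are windowed tables whose
    windows must already be on the bin grid (columns start/end plus
    pi/d/rate_cM_Mb respectively); GC and exon content are recomputed per
    bin from the sequence and exon intervals. Bins whose accessible
    fraction falls below the threshold are masked (NaN) in the rate tracks.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    n_bins = int(np.ceil(length / bin_size))
    edges = np.arange(n_bins + 1) * bin_size
    edges[-1] = max(edges[-1], length)

    acc_frac = np.ones(n_bins)
    if mask is not None:
        from .intervals import GenomicWindow

        for i in range(n_bins):
            span = min(bin_size, length - i * bin_size)
            acc_frac[i] = mask.accessible_bp(
                GenomicWindow(scaffold, i * bin_size, i * bin_size + span)
            ) / span
    low_acc = acc_frac < min_accessible_fraction

    tracks: dict[str, FeatureTrack] = {}
    if sequence is not None:
        if len(sequence) != length:
            raise ValueError("sequence length mismatch")
        gc = np.zeros(n_bins)
        arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
        is_gc = (arr == b"G") | (arr == b"C")
        for i in range(n_bins):
            seg = is_gc[edges[i] : min(edges[i + 1], length)]
            gc[i] = seg.mean() if seg.size else np.nan
        tracks["gc"] = FeatureTrack(scaffold, "gc", gc, acc_frac, bin_size)
    if exons is not None:
        exon_bp = np.zeros(n_bins)
        for s, e in np.asarray(exons, dtype=np.int64).reshape(-1, 2):
            s, e = max(0, int(s)), min(length, int(e))
            lo, hi = s // bin_size, (e - 1) // bin_size if e > s else s // bin_size
            for i in range(lo, hi + 1):
                exon_bp[i] += max(0, min(e, edges[i + 1]) - max(s, edges[i]))
        widths = np.minimum(edges[1:], length) - edges[:-1]
        tracks["exon"] = FeatureTrack(scaffold, "exon", exon_bp / widths, acc_frac, bin_size)

    def _grid_track(df: pd.DataFrame, col: str, name: str) -> FeatureTrack:
        vals = np.full(n_bins, np.nan)
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        if np.any(starts % bin_size):
            raise ValueError(f"{name} windows are not on the {bin_size} bp grid")
        v = df[col].to_numpy(dtype=float)
        for s, e, x in zip(starts // bin_size, -(-ends // bin_size), v):
            vals[int(s) : min(int(e), n_bins)] = x
        vals[low_acc] = np.nan
        return FeatureTrack(scaffold, name, vals, acc_frac, bin_size)

    if pi is not None:
        tracks["diversity"] = _grid_track(pi, "pi", "diversity")
    if divergence is not None:
        tracks["divergence"] = _grid_track(divergence, "d", "divergence")
    if recombination is not None:
        tracks["recombination"] = _grid_track(recombination, "rate_cM_Mb", "recombination")
    return tracks


def _kendall(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b with exact p for small tie-free samples."""
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    method = "exact" if n <= 10 and np.unique(x).size == n and np.unique(y).size == n else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def kendall_detail_correlations(
    decomps: dict[str, WaveletDecomposition], alpha: float = 0.01
) -> pd.DataFrame:
    """Pairwise Kendall tau-b of detail coefficients per scale.

    Returns long-format rows (scale level, kb label, pair, tau, p,
    significant-at-alpha flag); constant coefficient vectors give NaN tau
    and are never flagged.
    """
    names = list(decomps)
    levels = min(d.levels for d in decomps.values())
    rows = []
    for j in range(1, levels + 1):
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                da = decomps[a].detail(j)
                db = decomps[b].detail(j)
                if da.size < 2:
                    continue
                tau, p = _kendall(da, db)
                rows.append(
                    {
                        "level": j,
                        "scale_kb": WaveletDecomposition.scale_kb(j),
                        "a": a,
                        "b": b,
                        "tau": tau,
                        "p": p,
                        "significant": bool(p < alpha) if np.isfinite(p) else False,
                    }
                )
    return pd.DataFrame(rows)


def scale_linear_models(
    decomps: dict[str, WaveletDecomposition], response: str = "recombination"
) -> pd.DataFrame:
    """Through-origin OLS of response details on the other features, per scale.

    The intercept is forced through the origin (detail coefficients of
    mean-stationary tracks are centered by construction), so adjusted R^2
    uses the uncentered total sum of squares. Returns long-format rows with
    per-predictor coefficients, two-sided t-test p-values and the model's
    adjusted R^2.
    """
    import statsmodels.api as sm

    if response not in decomps:
        raise ValueError(f"no decomposition named {response!r}")
    predictors = [k for k in decomps if k != response]
    levels = min(d.levels for d in decomps.values())
    rows = []
    for j in range(1, levels + 1):
        y = decomps[response].detail(j)
        X = np.column_stack([decomps[k].detail(j) for k in predictors])
        if y.size <= len(predictors):
            continue
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            corr = np.corrcoef(X, rowvar=False)
            bad = [
                f"{predictors[p]}~{predictors[q]}"
                for p in range(len(predictors))
                for q in range(p + 1, len(predictors))
                if abs(corr[p, q]) > 0.999999
            ]
            raise ValueError(f"rank-deficient design at level {j}: {bad or 'unknown collinearity'}")
        fit = sm.OLS(y, X).fit()
        for k, name in enumerate(predictors):
            rows.append(
                {
                    "level": j,
                    "scale_kb": WaveletDecomposition.scale_kb(j),
                    "predictor": name,
                    "coef": float(fit.params[k]),
                    "p": float(fit.pvalues[k]),
                    "sign": int(np.sign(fit.params[k])),
                    "adj_r2": float(fit.rsquared_adj),
                }
            )
    return pd.DataFrame(rows)
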