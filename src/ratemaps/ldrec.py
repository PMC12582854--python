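"""LD-based recombination-rate estimation, rescaling, and benchmarking.

Per-window population recombination rates (rho = 4 N_e r per bp) are
estimated by maximizing a pairwise composite log-likelihood over a per-bp
rho grid: for every SNP pair within a fixed span, the folded two-locus
configuration is scored against a demography-aware Monte-Carlo lookup table
at ``rho_bp * distance``. Rates are converted to cM/Mb through Watterson's
theta, genome-wide outliers removed, and the map rescaled so its total
genetic length matches the pedigree-based map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .demography import DemographicModel, bottleneck_decline, equilibrium
from .genome import TrueRateTrack
from .intervals import sliding_windows
from .panel import HaplotypePanel
from .synthdata import MotifSet
from .twolocus import TwoLocusTable, build_two_locus_table, pair_config

__all__ = [
    "RecombinationMap",
    "WelchTTestReport",
    "BenchmarkConfig",
    "watterson_theta",
    "composite_log_likelihood",
    "estimate_rho_window",
    "estimate_map",
    "rho_to_r",
    "filter_outlier_windows",
    "rescale_map",
    "aggregate_windows",
    "compare_motif_rates",
    "benchmark_estimator",
]

# per-bp candidate grid: 0 plus log-spaced values spanning plausible rho/bp
DEFAULT_RHO_BP_GRID = np.concatenate([[0.0], np.logspace(-7, -2, 41)])

# pedigree-based sex-averaged autosomal genetic map length (cM)
PEDIGREE_MAP_LENGTH_CM = 1525.0
# pedigree-based sex-averaged crossover rate (cM/Mb)
PEDIGREE_RATE_CM_MB = 0.85


def watterson_theta(s: int, n_hap: int, length: int) -> float:
    """Watterson's theta per site: S / (H_{n-1} * L)."""
    if n_hap < 2:
        raise ValueError("need n_hap >= 2")
    if length <= 0:
        raise ValueError("length must be positive")
    harmonic = sum(1.0 / i for i in range(1, n_hap))
    return s / (harmonic * length)


@dataclass
class RecombinationMap:
    """Windowed recombination rates with cumulative map support.

    ``table`` columns: scaffold, start, end, rate_cM_Mb (NaN = undefined);
    optionally rho_bp. Genetic lengths use cM/Mb * Mb.
    """

    table: pd.DataFrame

    def copy(self) -> "RecombinationMap":
        return RecombinationMap(self.table.copy())

    def window_cm(self) -> np.ndarray:
        t = self.table
        return (t["rate_cM_Mb"] * (t["end"] - t["start"]) / 1e6).to_numpy()

    def total_cm(self) -> float:
        return float(np.nansum(self.window_cm()))

    def mean_rate(self) -> float:
        """Length-weighted genome-mean rate over defined windows (cM/Mb)."""
        t = self.table
        ok = t["rate_cM_Mb"].notna()
        w = (t.loc[ok, "end"] - t.loc[ok, "start"]).to_numpy(dtype=float)
        return float(np.average(t.loc[ok, "rate_cM_Mb"], weights=w))

    def with_cumulative(self) -> pd.DataFrame:
        """Table plus per-scaffold cumulative cM (non-decreasing)."""
        out = self.table.copy()
        cm = np.nan_to_num(self.window_cm())
        out["cumulative_cM"] = (
            pd.Series(cm, index=out.index).groupby(out["scaffold"]).cumsum()
        )
        return out


@dataclass
class WelchTTestReport:
    mean_in: float
    mean_out: float
    n_in: int
    n_out: int
    t: float
    df: float
    p: float


def composite_log_likelihood(
    panel: HaplotypePanel,
    table: TwoLocusTable,
    rho_bp: np.ndarray,
    pair_span: int = 30,
    start: int | None = None,
    end: int | None = None,
) -> np.ndarray:
    """Pairwise composite log-likelihood at each candidate per-bp rho.

    Sums ``log P(config_ij | rho_bp * dist_ij)`` over SNP pairs at most
    ``pair_span`` SNPs apart whose left SNP lies in ``[start, end)``;
    distances are in bp and the lookup table is interpolated linearly in
    rho (clamped at the grid ends).
    """
    seg = panel.segregating()
    pos = seg.positions
    if start is None:
        start = 0
    if end is None:
        end = panel.length
    left_ok = np.where((pos >= start) & (pos < end))[0]
    cfg_idx: list[int] = []
    dist: list[int] = []
    for i in left_ok:
        for j in range(i + 1, min(i + pair_span + 1, pos.size)):
            cfg_idx.append(table.config_index(pair_config(seg.haplotypes[:, i], seg.haplotypes[:, j])))
            dist.append(int(pos[j] - pos[i]))
    if not cfg_idx:
        return np.full(np.asarray(rho_bp).size, np.nan)
    cfg_arr = np.asarray(cfg_idx)
    dist_arr = np.asarray(dist, dtype=float)
    rho_bp = np.asarray(rho_bp, dtype=float)
    out = np.empty(rho_bp.size)
    for k, rb in enumerate(rho_bp):
        out[k] = float(table.log_prob_interp(cfg_arr, rb * dist_arr).sum())
    return out


def estimate_rho_window(
    panel: HaplotypePanel,
    table: TwoLocusTable,
    pair_span: int = 30,
    rho_grid_bp: np.ndarray = DEFAULT_RHO_BP_GRID,
    start: int | None = None,
    end: int | None = None,
) -> float:
    """Composite-likelihood rho-hat per bp for one window (NaN if < 2 SNPs)."""
    seg = panel.segregating()
    s, e = (0 if start is None else start), (panel.length if end is None else end)
    if ((seg.positions >= s) & (seg.positions < e)).sum() < 2:
        return float("nan")
    ll = composite_log_likelihood(panel, table, rho_grid_bp, pair_span, start, end)
    if np.all(np.isnan(ll)):
        return float("nan")
    return float(np.asarray(rho_grid_bp)[int(np.nanargmax(ll))])


def rho_to_r(rho_bp: float, mu: float, theta_site: float) -> tuple[float, float]:
    """Convert per-bp rho to per-generation r and cM/Mb via theta/(4 mu).

    N_e = theta / (4 mu); r = rho / (4 N_e) = rho * mu / theta;
    1e-8 crossovers/bp/gen == 1 cM/Mb.
    """
    if mu <= 0 or theta_site <= 0:
        raise ValueError("mu and theta must be positive")
    if rho_bp < 0:
        raise ValueError("rho must be non-negative")
    r = rho_bp * mu / theta_site
    return r, r * 1e8


def estimate_map(
    panel: HaplotypePanel,
    table: TwoLocusTable,
    mu: float,
    window: int = 100_000,
    step: int | None = None,
    pair_span: int = 30,
    rho_grid_bp: np.ndarray = DEFAULT_RHO_BP_GRID,
) -> RecombinationMap:
    """Windowed recombination map from one panel (rho-hat and cM/Mb).

    Watterson's theta from the whole panel supplies the N_e used in the
    rho -> r conversion, mirroring a user-specified mutation rate.
    """
    theta = watterson_theta(panel.segregating().n_sites, panel.n_hap, panel.length)
    rows = []
    for win, _ in sliding_windows(panel.scaffold, panel.length, window, step):
        rho = estimate_rho_window(panel, table, pair_span, rho_grid_bp, win.start, win.end)
        if np.isnan(rho) or theta <= 0:
            rate = float("nan")
        else:
            _, rate = rho_to_r(rho, mu, theta)
        rows.append((panel.scaffold, win.start, win.end, rho, rate))
    return RecombinationMap(
        pd.DataFrame(rows, columns=["scaffold", "start", "end", "rho_bp", "rate_cM_Mb"])
    )


def filter_outlier_windows(
    rmap: RecombinationMap, fold: float = 100.0
) -> tuple[RecombinationMap, pd.DataFrame]:
    """Drop windows whose rate exceeds ``fold`` x the genome mean.

    The genome mean is the length-weighted mean over defined windows;
    assembly errors manifest as isolated windows at 100-300x that mean.
    Returns the filtered map and the removed rows.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    mean = rmap.mean_rate()
    bad = rmap.table["rate_cM_Mb"] > fold * mean
    removed = rmap.table[bad].copy()
    return RecombinationMap(rmap.table[~bad].reset_index(drop=True)), removed


def rescale_map(rmap: RecombinationMap, target_cm: float) -> tuple[RecombinationMap, float]:
    """Multiply all rates so the total map length equals ``target_cm``.

    Relative rates are untouched; returns (rescaled map, factor applied).
    """
    if target_cm <= 0:
        raise ValueError("target map length must be positive")
    current = rmap.total_cm()
    if current <= 0:
        raise ValueError("cannot rescale an empty or zero-length map")
    factor = target_cm / current
    out = rmap.copy()
    out.table["rate_cM_Mb"] = out.table["rate_cM_Mb"] * factor
    if "rho_bp" in out.table:
        out.table["rho_bp"] = out.table["rho_bp"] * factor
    return out, factor


def aggregate_windows(
    rmap: RecombinationMap, window: int = 1_000_000, step: int = 500_000
) -> RecombinationMap:
    """bp-length-weighted mean rate on a sliding coarse grid."""
    if step > window:
        raise ValueError("step must not exceed window")
    rows = []
    for scaf, sub in rmap.table.groupby("scaffold", sort=False):
        length = int(sub["end"].max())
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        rates = sub["rate_cM_Mb"].to_numpy(dtype=float)
        for win, _ in sliding_windows(scaf, length, window, step):
            ov = np.minimum(ends, win.end) - np.maximum(starts, win.start)
            ov = np.maximum(ov, 0).astype(float)
            ok = (ov > 0) & ~np.isnan(rates)
            if ok.any():
                rate = float(np.average(rates[ok], weights=ov[ok]))
            else:
                rate = float("nan")
            rows.append((scaf, win.start, win.end, rate))
    return RecombinationMap(pd.DataFrame(rows, columns=["scaffold", "start", "end", "rate_cM_Mb"]))


def compare_motif_rates(fine_map: RecombinationMap, motifs: MotifSet) -> WelchTTestReport:
    """Welch two-sample t-test of window rates by motif overlap."""
    t = fine_map.table
    half = motifs.width // 2
    in_motif = np.zeros(len(t), dtype=bool)
    for scaf, sub in t.groupby("scaffold", sort=False):
        mids = motifs.get(scaf)
        if mids.size == 0:
            continue
        lo = mids - half
        hi = mids + half
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        hit = (starts[:, None] < hi[None, :]) & (ends[:, None] > lo[None, :])
        in_motif[sub.index.to_numpy()] = hit.any(axis=1)
    ok = t["rate_cM_Mb"].notna().to_numpy()
    a = t.loc[ok & in_motif, "rate_cM_Mb"].to_numpy(dtype=float)
    b = t.loc[ok & ~in_motif, "rate_cM_Mb"].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both motif and non-motif groups need >= 2 windows")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb > 0:
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        df = float(a.size + b.size - 2)
    return WelchTTestReport(
        mean_in=float(a.mean()),
        mean_out=float(b.mean()),
        n_in=int(a.size),
        n_out=int(b.size),
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
    )


@dataclass
class BenchmarkConfig:
    """Estimator benchmark design: decline vs equilibrium, two mutation rates.

    Defaults mirror the study design (five diploids, 0.85 cM/Mb truth, ten
    replicates); ``region_length`` is reducible for desk-scale runs.
    """

    demographies: dict[str, DemographicModel] = field(
        default_factory=lambda: {
            "bottleneck_decline": bottleneck_decline(),
            "equilibrium": equilibrium(),
        }
    )
    mutation_rates: tuple[float, ...] = (0.4e-8, 1.1e-8)
    true_rate_cm_mb: float = PEDIGREE_RATE_CM_MB
    n_diploids: int = 5
    replicates: int = 10
    region_length: int = 1_600_000
    estimate_window: int = 100_000
    pair_span: int = 30
    table_reps: int = 8_000
    table_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)


def benchmark_estimator(config: BenchmarkConfig, seed: int = 0) -> pd.DataFrame:
    """Recovery benchmark of the composite-likelihood estimator.

    For every demography x mutation-rate combination, simulates
    ``replicates`` panels at the fixed true rate, estimates a windowed map
    per replicate, and reports the length-weighted mean rate, its median
    across replicates, bias, and ratio to truth (all before any rescaling).
    """
    from .coalescent import simulate_haplotypes

    r_true = config.true_rate_cm_mb * 1e-8
    rows = []
    combo = 0
    for dem_name, model in config.demographies.items():
        table = build_two_locus_table(
            2 * config.n_diploids,
            model,
            grid=config.table_grid,
            reps=config.table_reps,
            seed=seed,
        )
        for mu in config.mutation_rates:
            combo += 1
            for rep in range(config.replicates):
                rep_seed = (seed * 1_000_003 + combo * 1009 + rep) % (2**31)
                panel = simulate_haplotypes(
                    model, mu, r_true, 2 * config.n_diploids, config.region_length, rep_seed
                )
                rmap = estimate_map(
                    panel,
                    table,
                    mu,
                    window=config.estimate_window,
                    pair_span=config.pair_span,
                )
                est = rmap.mean_rate() if rmap.table["rate_cM_Mb"].notna().any() else float("nan")
                rows.append(
                    {
                        "demography": dem_name,
                        "mu": mu,
                        "replicate": rep,
                        "n_snps": panel.segregating().n_sites,
                        "estimate_cM_Mb": est,
                    }
                )
    out = pd.DataFrame(rows)
    summary = (
        out.groupby(["demography", "mu"])["estimate_cM_Mb"]
        .agg(["mean", "median"])
        .reset_index()
    )
    summary["true_cM_Mb"] = config.true_rate_cm_mb
    summary["bias"] = summary["mean"] - config.true_rate_cm_mb
    summary["ratio_to_truth"] = summary["median"] / config.true_rate_cm_mb
    return out.merge(summary, on=["demography", "mu"], suffixes=("", "_summary"))
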