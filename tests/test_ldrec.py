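"""Composite-likelihood estimator, map transforms, and the motif t-test."""

import numpy as np
import pandas as pd
import pytest

from ratemaps.coalescent import simulate_haplotypes
from ratemaps.demography import equilibrium
from ratemaps.genome import TrueRateTrack
from ratemaps.ldrec import (
    RecombinationMap,
    aggregate_windows,
    compare_motif_rates,
    composite_log_likelihood,
    estimate_rho_window,
    filter_outlier_windows,
    rescale_map,
    rho_to_r,
    watterson_theta,
)
from ratemaps.panel import HaplotypePanel
from ratemaps.synthdata import MotifSet
from ratemaps.twolocus import pair_config


class TestWattersonTheta:
    def test_zero_segregating(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_pair_of_haplotypes(self):
        assert watterson_theta(5, 2, 100) == pytest.approx(0.05)

    def test_harmonic_number_value(self):
        h9 = sum(1.0 / i for i in range(1, 10))
        assert h9 == pytest.approx(2.828968, abs=1e-6)
        assert watterson_theta(100, 10, 10_000) == pytest.approx(3.5349e-3, rel=1e-4)


def _brute_force_objective(panel, table, rho_bp_values, pair_span):
    """Direct pair enumeration of the composite log-likelihood."""
    seg = panel.segregating()
    out = []
    for rho_bp in rho_bp_values:
        total = 0.0
        for i in range(seg.n_sites):
            for j in range(i + 1, min(i + pair_span + 1, seg.n_sites)):
                cfg = pair_config(seg.haplotypes[:, i], seg.haplotypes[:, j])
                rho_pair = rho_bp * (seg.positions[j] - seg.positions[i])
                idx = np.array([table.config_index(cfg)])
                total += float(table.log_prob_interp(idx, np.array([rho_pair]))[0])
        out.append(total)
    return np.asarray(out)


class TestCompositeLikelihood:
    def test_objective_and_argmax_match_brute_force(self, small_table, rng):
        pos = np.sort(rng.choice(20_000, size=20, replace=False))
        hap = rng.integers(0, 2, size=(6, 20)).astype(np.uint8)
        panel = HaplotypePanel("s", 20_000, pos, hap)
        grid = np.array([0.0, 1e-6, 1e-5, 1e-4, 1e-3])
        ours = composite_log_likelihood(panel, small_table, grid, pair_span=5)
        brute = _brute_force_objective(panel, small_table, grid, pair_span=5)
        assert np.allclose(ours, brute, rtol=1e-12)
        est = estimate_rho_window(panel, small_table, pair_span=5, rho_grid_bp=grid)
        assert est == grid[int(np.argmax(brute))]

    def test_zero_recombination_panels_cluster_at_low_rho(self, eq_table, eq_model):
        """rho = 0 panels give clearly smaller estimates than study-scale rho.

        A single window without recombination is one shared genealogy, so
        every SNP pair is correlated and individual windows cannot pin the
        estimate to the grid floor; the distribution over windows must
        still sit far below estimates from data at the study-scale
        rho = 4 N r (0.85 cM/Mb at N = 11,695).
        """
        grid = np.concatenate([[0.0], np.logspace(-6, -3, 16)])
        rho_study = 4 * 11_695 * 0.85e-8  # ~3.98e-4 per bp
        est0, est_r = [], []
        for s in range(50):
            panel = simulate_haplotypes(eq_model, 3e-8, 0.0, 10, 20_000, seed=7000 + s)
            if panel.segregating().n_sites < 2:
                continue
            est0.append(estimate_rho_window(panel, eq_table, rho_grid_bp=grid))
        for s in range(20):
            panel = simulate_haplotypes(eq_model, 3e-8, 0.85e-8, 10, 20_000, seed=7500 + s)
            if panel.segregating().n_sites < 2:
                continue
            est_r.append(estimate_rho_window(panel, eq_table, rho_grid_bp=grid))
        med0, medr = np.median(est0), np.median(est_r)
        assert med0 < rho_study / 2
        assert med0 < medr / 2

    def test_estimate_invariant_to_relabeling_and_order(self, small_table, rng):
        pos = np.sort(rng.choice(10_000, size=15, replace=False))
        hap = rng.integers(0, 2, size=(6, 15)).astype(np.uint8)
        panel = HaplotypePanel("s", 10_000, pos, hap)
        grid = np.concatenate([[0.0], np.logspace(-6, -3, 10)])
        base = estimate_rho_window(panel, small_table, rho_grid_bp=grid)
        flipped = HaplotypePanel("s", 10_000, pos, 1 - hap)
        shuffled = HaplotypePanel("s", 10_000, pos, hap[rng.permutation(6)])
        assert estimate_rho_window(flipped, small_table, rho_grid_bp=grid) == base
        assert estimate_rho_window(shuffled, small_table, rho_grid_bp=grid) == base

    def test_too_few_snps_is_nan_not_zero(self, small_table):
        panel = HaplotypePanel("s", 1000, np.array([5]), np.ones((6, 1), dtype=np.uint8))
        assert np.isnan(estimate_rho_window(panel, small_table))


class TestRhoToR:
    def test_zero_rho(self):
        assert rho_to_r(0.0, 1e-8, 1e-4) == (0.0, 0.0)

    def test_unit_definition(self):
        # theta = 4 N mu with N chosen so rho -> r is the identity * 1e8
        n_e, mu = 10_000.0, 1e-8
        theta = 4 * n_e * mu
        r, cm_mb = rho_to_r(4 * n_e * 1e-8, mu, theta)
        assert r == pytest.approx(1e-8)
        assert cm_mb == pytest.approx(1.0)

    def test_round_trip_with_study_constants(self):
        n_e, r_true, mu = 11_695.0, 0.85e-8, 0.4e-8
        rho_bp = 4 * n_e * r_true
        assert rho_bp == pytest.approx(3.9763e-4, rel=1e-4)
        theta = 4 * n_e * mu
        _, cm_mb = rho_to_r(rho_bp, mu, theta)
        assert cm_mb == pytest.approx(0.85, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rho_to_r(1e-4, 0.0, 1e-4)
        with pytest.raises(ValueError):
            rho_to_r(-1.0, 1e-8, 1e-4)


def _uniform_map(rates, width=1000):
    rows = [("s", i * width, (i + 1) * width, r) for i, r in enumerate(rates)]
    return RecombinationMap(
        pd.DataFrame(rows, columns=["scaffold", "start", "end", "rate_cM_Mb"])
    )


class TestOutlierFilter:
    def test_single_extreme_window_removed(self):
        rmap = _uniform_map([1.0] * 1000 + [200.0])
        filtered, removed = filter_outlier_windows(rmap, fold=100)
        assert len(removed) == 1 and removed["rate_cM_Mb"].iloc[0] == 200.0
        assert len(filtered.table) == 1000

    def test_uniform_map_untouched(self):
        rmap = _uniform_map([1.0] * 100)
        filtered, removed = filter_outlier_windows(rmap, fold=100)
        assert removed.empty and len(filtered.table) == 100

    def test_infinite_fold_is_identity(self):
        rmap = _uniform_map([1.0, 500.0, 2.0])
        filtered, removed = filter_outlier_windows(rmap, fold=np.inf)
        assert removed.empty


class TestRescale:
    def test_factor_ten(self):
        rmap = _uniform_map([1.0] * 100, width=1_525_000)  # 152.5 cM total
        rescaled, factor = rescale_map(rmap, 1525.0)
        assert factor == pytest.approx(10.0)
        assert rescaled.total_cm() == pytest.approx(1525.0, rel=1e-6)

    def test_paper_factor_implies_input_total(self):
        # factor 14.444 onto 1525 cM implies a pre-rescale total of 105.58 cM
        implied_total = 1525.0 / 14.444
        assert implied_total == pytest.approx(105.58, abs=0.005)
        rmap = _uniform_map([implied_total / 100 / 1.0] * 100, width=1_000_000)
        rescaled, factor = rescale_map(rmap, 1525.0)
        assert factor == pytest.approx(14.444, rel=1e-4)

    def test_relative_rates_preserved(self, rng):
        rates = rng.uniform(0.1, 5.0, size=50)
        rmap = _uniform_map(list(rates))
        rescaled, _ = rescale_map(rmap, 321.0)
        new = rescaled.table["rate_cM_Mb"].to_numpy()
        assert np.allclose(new / new[0], rates / rates[0])
        assert rescaled.total_cm() == pytest.approx(321.0, rel=1e-6)

    def test_zero_map_raises(self):
        rmap = _uniform_map([0.0] * 10)
        with pytest.raises(ValueError):
            rescale_map(rmap, 100.0)


class TestAggregate:
    def test_uniform_fine_map_unchanged(self):
        rmap = _uniform_map([2.5] * 10_000)  # 10 Mb of 1 kb windows
        coarse = aggregate_windows(rmap, window=1_000_000, step=500_000)
        assert len(coarse.table) == 19
        assert np.allclose(coarse.table["rate_cM_Mb"], 2.5)

    def test_matches_per_bp_weighted_oracle(self, rng):
        rates = rng.uniform(0, 3, size=40)
        rmap = _uniform_map(list(rates), width=700)  # 28 kb, off-grid width
        coarse = aggregate_windows(rmap, window=10_000, step=5_000)
        per_bp = np.repeat(rates, 700)
        for _, row in coarse.table.iterrows():
            s, e = int(row["start"]), int(row["end"])
            assert row["rate_cM_Mb"] == pytest.approx(per_bp[s:e].mean())

    def test_cumulative_map_non_decreasing_ends_at_total(self):
        rmap = _uniform_map([1.0, 0.0, 3.0, 2.0], width=250_000)
        cum = rmap.with_cumulative()["cumulative_cM"].to_numpy()
        assert np.all(np.diff(cum) >= 0)
        assert cum[-1] == pytest.approx(rmap.total_cm())


class TestMotifComparison:
    def test_identical_groups_t_zero(self):
        rmap = _uniform_map([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        motifs = MotifSet({"s": np.array([100, 1100, 2100])}, width=10)
        rep = compare_motif_rates(rmap, motifs)
        assert rep.t == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_welch_formula(self):
        rmap = _uniform_map([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
        motifs = MotifSet({"s": np.array([100, 1100, 2100])}, width=10)
        rep = compare_motif_rates(rmap, motifs)
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert rep.t == pytest.approx(t_hand)
        assert rep.df == pytest.approx(df_hand)

    def test_empty_group_raises(self):
        rmap = _uniform_map([1.0, 2.0])
        with pytest.raises(ValueError):
            compare_motif_rates(rmap, MotifSet({"s": np.array([], dtype=int)}))
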