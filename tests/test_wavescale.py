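"""Haar pyramid, Kendall correlations, and through-origin linear models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratemaps.wavescale import (
    FeatureTrack,
    WaveletDecomposition,
    bin_feature_tracks,
    haar_dwt,
    inverse_haar_dwt,
    kendall_detail_correlations,
    log_transform_rates,
    scale_linear_models,
    split_halves,
)


class TestHaarDWT:
    def test_constant_input_all_details_zero(self):
        dec = haar_dwt(np.full(64, 3.7))
        assert all(np.allclose(d, 0) for d in dec.details)

    def test_hand_computed_pyramid(self):
        dec = haar_dwt(np.array([1.0, 3.0, 2.0, 2.0]))
        assert np.allclose(dec.detail(1), [-1.41421356, 0.0])
        assert np.allclose(dec.detail(2), [0.0])
        assert np.allclose(dec.smooth, [4.0])  # (1+3+2+2)/2

    def test_energy_conservation_and_reconstruction(self, rng):
        v = rng.normal(size=4096)
        dec = haar_dwt(v)
        assert dec.energy() == pytest.approx(float((v**2).sum()), rel=1e-9)
        assert np.allclose(inverse_haar_dwt(dec), v, atol=1e-9)

    def test_matches_pywavelets(self, rng):
        import pywt

        v = rng.normal(size=256)
        dec = haar_dwt(v)
        coeffs = pywt.wavedec(v, "haar")
        # pywt orders [smooth, d_J, ..., d_1] and negates the detail sign
        for level in range(1, len(dec.details) + 1):
            ref = coeffs[-level]
            ours = dec.detail(level)
            assert np.allclose(np.abs(ours), np.abs(ref), atol=1e-9)
            assert np.allclose(ours, -ref, atol=1e-9) or np.allclose(ours, ref, atol=1e-9)

    def test_level_coefficient_counts(self, rng):
        n = 1024
        dec = haar_dwt(rng.normal(size=n))
        for j in range(1, dec.levels + 1):
            assert dec.detail(j).size == n // 2**j

    def test_non_dyadic_raises(self):
        with pytest.raises(ValueError):
            haar_dwt(np.arange(100, dtype=float))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(3, 8), st.integers(0, 2**31 - 1))
    def test_energy_and_reconstruction_property(self, j, seed):
        v = np.random.default_rng(seed).normal(size=2**j)
        dec = haar_dwt(v)
        assert dec.energy() == pytest.approx(float((v**2).sum()), rel=1e-9)
        assert np.allclose(inverse_haar_dwt(dec), v, atol=1e-9)


class TestSplitHalves:
    def test_dyadic_input_splits_evenly(self):
        tr = FeatureTrack("s", "x", np.arange(8192, dtype=float))
        left, right = split_halves(tr)
        assert left.detail(1).size == 4096 // 2
        assert sum(d.size for d in left.details) + left.smooth.size == 4096

    def test_truncation_to_largest_power_of_two(self):
        tr = FeatureTrack("s", "x", np.arange(10_000, dtype=float))
        left, right = split_halves(tr)
        # halves of 4096 = 2^12 bins taken inward from the midpoint
        assert sum(d.size for d in left.details) + left.smooth.size == 4096
        assert sum(d.size for d in right.details) + right.smooth.size == 4096
        # the used bins are a subset of the original track
        assert np.allclose(inverse_haar_dwt(left), np.arange(904, 5000, dtype=float))
        assert np.allclose(inverse_haar_dwt(right), np.arange(5000, 9096, dtype=float))

    def test_heavy_imputation_flagged(self):
        v = np.arange(64, dtype=float)
        v[:20] = np.nan
        left, right = split_halves(FeatureTrack("s", "x", v))
        assert left.flagged and not right.flagged

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            split_halves(FeatureTrack("s", "x", np.array([1.0, 2.0])))


class TestKendall:
    @staticmethod
    def _decs(x, y):
        return {
            "a": WaveletDecomposition("a", 1, [np.asarray(x, dtype=float)], np.zeros(1)),
            "b": WaveletDecomposition("b", 1, [np.asarray(y, dtype=float)], np.zeros(1)),
        }

    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        rep = kendall_detail_correlations(self._decs(x, x * 2 + 1))
        assert rep["tau"].iloc[0] == pytest.approx(1.0)
        rep = kendall_detail_correlations(self._decs(x, -x))
        assert rep["tau"].iloc[0] == pytest.approx(-1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            rep = kendall_detail_correlations(self._decs(x, y))
            conc = disc = 0
            for i in range(6):
                for j in range(i + 1, 6):
                    s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
                    conc += s > 0
                    disc += s < 0
            tau_hand = (conc - disc) / 15
            assert rep["tau"].iloc[0] == pytest.approx(tau_hand)
            # exact p: enumerate all permutations of y against fixed x
            from itertools import permutations

            stats_all = []
            for perm in permutations(range(6)):
                yp = y[list(perm)]
                c = d = 0
                for i in range(6):
                    for j in range(i + 1, 6):
                        s = np.sign((x[i] - x[j]) * (yp[i] - yp[j]))
                        c += s > 0
                        d += s < 0
                stats_all.append((c - d) / 15)
            p_exact = np.mean(np.abs(stats_all) >= abs(tau_hand) - 1e-12)
            assert rep["p"].iloc[0] == pytest.approx(p_exact, abs=1e-9)

    def test_constant_vector_reported_missing(self):
        rep = kendall_detail_correlations(self._decs(np.ones(8), np.arange(8.0)))
        assert np.isnan(rep["tau"].iloc[0]) and not rep["significant"].iloc[0]

    def test_tau_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=32)
        y = rng.normal(size=32) + 0.5 * x
        base = kendall_detail_correlations(self._decs(x, y))["tau"].iloc[0]
        warped = kendall_detail_correlations(self._decs(np.exp(x), y**3 + 5 * y))["tau"].iloc[0]
        assert warped == pytest.approx(base)


class TestLinearModels:
    @staticmethod
    def _dec(name, arrays):
        return WaveletDecomposition(name, len(arrays), [np.asarray(a, float) for a in arrays], np.zeros(1))

    def test_noiseless_planted_coefficient(self, rng):
        x1 = rng.normal(size=64)
        zeros = np.zeros(64)
        decs = {
            "recombination": self._dec("recombination", [2.0 * x1]),
            "gc": self._dec("gc", [x1]),
            "exon": self._dec("exon", [zeros + 1e-12]),
        }
        rep = scale_linear_models(decs)
        coef_gc = rep[rep["predictor"] == "gc"]["coef"].iloc[0]
        assert coef_gc == pytest.approx(2.0)
        assert rep["adj_r2"].iloc[0] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        n = 10
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        decs = {
            "recombination": self._dec("recombination", [y]),
            "p1": self._dec("p1", [X[:, 0]]),
            "p2": self._dec("p2", [X[:, 1]]),
            "p3": self._dec("p3", [X[:, 2]]),
        }
        rep = scale_linear_models(decs)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = rep.set_index("predictor")["coef"]
        assert np.allclose([got["p1"], got["p2"], got["p3"]], beta)

    def test_type_one_error_rate_for_noise_response(self):
        rejections = 0
        n_seeds = 200
        for s in range(n_seeds):
            r = np.random.default_rng(s)
            decs = {
                "recombination": self._dec("y", [r.normal(size=50)]),
                "x": self._dec("x", [r.normal(size=50)]),
            }
            rep = scale_linear_models(decs)
            rejections += rep["p"].iloc[0] < 0.05
        # binomial(200, 0.05): observing <= 20 rejections has p > 0.999
        assert rejections <= 20

    def test_rank_deficient_design_raises(self):
        x = np.arange(16.0)
        decs = {
            "recombination": self._dec("recombination", [x + 1]),
            "a": self._dec("a", [x]),
            "b": self._dec("b", [2 * x]),
        }
        with pytest.raises(ValueError, match="rank-deficient"):
            scale_linear_models(decs)


class TestPlantedScaleCorrelation:
    def test_correlation_recovered_only_at_planted_scale(self):
        """Shared detail noise injected at level 5 is detected there only."""
        rng = np.random.default_rng(2024)
        n, planted = 4096, 5
        def build(shared):
            dec = haar_dwt(rng.normal(size=n))
            details = [d.copy() for d in dec.details]
            details[planted - 1] = shared + 0.05 * rng.normal(size=shared.size)
            return WaveletDecomposition("t", dec.levels, details, dec.smooth)

        shared = rng.normal(size=n // 2**planted)
        decs = {"a": build(shared), "b": build(shared)}
        rep = kendall_detail_correlations(decs, alpha=0.01)
        sig = rep[rep["significant"]]
        assert set(sig["level"]) == {planted}


class TestLogTransform:
    def test_epsilon_is_half_min_positive(self):
        tr = FeatureTrack("s", "x", np.array([0.0, 2.0, 4.0]))
        out = log_transform_rates(tr)
        assert np.allclose(out.values, np.log(np.array([0.0, 2.0, 4.0]) + 1.0))

    def test_monotone_order_preserved(self, rng):
        v = rng.uniform(0, 5, size=50)
        out = log_transform_rates(FeatureTrack("s", "x", v))
        assert np.array_equal(np.argsort(out.values), np.argsort(v))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            log_transform_rates(FeatureTrack("s", "x", np.zeros(10)))


class TestBinTracks:
    def test_gc_and_exon_content(self):
        seq = "G" * 1500 + "A" * 500
        tracks = bin_feature_tracks(
            "s", 2000, sequence=seq, exons=np.array([[0, 500], [1000, 1500]])
        )
        assert np.allclose(tracks["gc"].values, [1.0, 0.5])
        assert np.allclose(tracks["exon"].values, [0.5, 0.5])

    def test_matches_per_base_recount(self, rng):
        L = 10_000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        exons = np.array([[100, 1200], [3050, 3075], [8999, 9501]])
        tracks = bin_feature_tracks("s", L, sequence=seq, exons=exons)
        is_gc = np.array([c in "GC" for c in seq])
        in_exon = np.zeros(L, dtype=bool)
        for s, e in exons:
            in_exon[s:e] = True
        for i in range(10):
            assert tracks["gc"].values[i] == pytest.approx(is_gc[i * 1000 : (i + 1) * 1000].mean())
            assert tracks["exon"].values[i] == pytest.approx(in_exon[i * 1000 : (i + 1) * 1000].mean())

    def test_off_grid_windows_raise(self):
        df = pd.DataFrame({"start": [500], "end": [1500], "pi": [0.1]})
        with pytest.raises(ValueError, match="grid"):
            bin_feature_tracks("s", 2000, pi=df)
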