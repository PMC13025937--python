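"""BSA statistics: frozen-value oracles, brute-force cross-checks and
invariance properties (hypothesis tests are seeded/derandomized)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from sweetbsa.bsa_stats import (allele_frequencies, ed_statistic, g_statistic,
                                genome_scan, scan_threshold, smooth_ed4,
                                smooth_gprime)
from tests.conftest import make_table

counts = st.integers(min_value=0, max_value=200)


def g_oracle(a, b, c, d):
    """Direct 2x2 G-test computation, scalar, straight from the definition."""
    n = [a, b, c, d]
    total = sum(n)
    e = [(a + c) * (a + b) / total, (b + d) * (a + b) / total,
         (a + c) * (c + d) / total, (b + d) * (c + d) / total]
    return 2.0 * sum(x * math.log(x / ex) for x, ex in zip(n, e) if x > 0)


class TestEd:
    def test_frozen_values(self):
        ed, ed4 = ed_statistic(np.array([0.75]), np.array([0.25]))
        assert ed[0] == pytest.approx(math.sqrt(0.5))
        assert ed4[0] == pytest.approx(0.25)
        ed, ed4 = ed_statistic(np.array([1.0]), np.array([0.0]))
        assert ed[0] == pytest.approx(math.sqrt(2.0))
        assert ed4[0] == pytest.approx(4.0)

    def test_allele_frequencies_nan_at_zero_depth(self):
        f = allele_frequencies(np.array([0, 5]), np.array([0, 5]))
        assert np.isnan(f[0]) and f[1] == 0.5

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_matches_two_component_euclidean_definition(self, fh, fl):
        ed, ed4 = ed_statistic(np.array([fh]), np.array([fl]))
        expect = math.hypot(fh - fl, (1 - fh) - (1 - fl))
        assert ed[0] == pytest.approx(expect, abs=1e-12)
        assert ed4[0] == pytest.approx(expect ** 4, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_bulk_swap_invariant(self, fh, fl):
        a = ed_statistic(np.array([fh]), np.array([fl]))[1][0]
        b = ed_statistic(np.array([fl]), np.array([fh]))[1][0]
        assert a == pytest.approx(b, abs=1e-12)


class TestG:
    def test_frozen_values(self):
        # perfect 2x2 separation with n=20: G = 40*ln(2)
        assert g_statistic(10, 0, 0, 10)[()] == pytest.approx(
            27.725887222397812, abs=1e-12)
        assert g_statistic(12, 4, 5, 11)[()] == pytest.approx(
            6.366849434635139, abs=1e-12)

    def test_independence_gives_zero(self):
        assert g_statistic(10, 10, 10, 10)[()] == pytest.approx(0.0, abs=1e-12)
        assert g_statistic(30, 10, 15, 5)[()] == pytest.approx(0.0, abs=1e-10)

    def test_all_zero_counts_nan(self):
        assert np.isnan(g_statistic(0, 0, 0, 0)[()])

    @settings(derandomize=True, max_examples=300)
    @given(counts, counts, counts, counts)
    def test_matches_scalar_oracle(self, a, b, c, d):
        g = g_statistic(a, b, c, d)[()]
        if a + b + c + d == 0:
            assert np.isnan(g)
        else:
            assert g == pytest.approx(g_oracle(a, b, c, d), abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(counts, counts, counts, counts)
    def test_symmetries(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        g = g_statistic(a, b, c, d)[()]
        assert g_statistic(c, d, a, b)[()] == pytest.approx(g, abs=1e-9)  # bulk swap
        assert g_statistic(b, a, d, c)[()] == pytest.approx(g, abs=1e-9)  # allele relabel
        assert g >= -1e-9

    def test_cross_check_against_scipy_log_likelihood(self, rng):
        tables = rng.integers(0, 100, size=(300, 4))
        g = g_statistic(*tables.T)
        for row, ours in zip(tables, g):
            m = row.reshape(2, 2)
            if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
                continue  # scipy rejects empty margins; our 0*log0 convention covers them
            ref = chi2_contingency(m, correction=False,
                                   lambda_="log-likelihood")[0]
            assert ours == pytest.approx(ref, abs=1e-8)


class TestSmoothing:
    def test_ed4_window_mean_frozen_example(self):
        # window [0, 1 Mb) holds all three loci: mean of [1, 2, 3] = 2.
        # Loci at 100 kb and 500 kb map there; the locus at 900 kb maps to
        # the window anchored at 400 kb (centre exactly on it), whose loci
        # are [2, 3] -> mean 2.5.
        pos = np.array([100_000, 500_000, 900_000])
        sm, windows = smooth_ed4(pos, np.array([1.0, 2.0, 3.0]))
        assert np.allclose(sm, [2.0, 2.0, 2.5])
        first = windows.iloc[0]
        assert (first["start"], first["end"]) == (1, 1_000_000)
        assert first["n_loci"] == 3 and first["mean_ed4"] == pytest.approx(2.0)

    def test_ed4_locus_maps_to_window_with_nearest_centre(self):
        # locus at 1,200,000: containing windows anchor at 250k..1200k;
        # nearest centre is anchor 700k (centre 1.2 Mb, distance 0)
        pos = np.array([100_000, 700_001, 1_200_000])
        ed4 = np.array([0.0, 9.0, 3.0])
        sm, _ = smooth_ed4(pos, ed4)
        # window [700000, 1700000) holds loci 2 and 3 -> mean 6
        assert sm[2] == pytest.approx(6.0)

    def test_ed4_constant_track_unchanged(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 5_000_000), 200, replace=False))
        sm, _ = smooth_ed4(pos, np.full(200, 0.7))
        assert np.allclose(sm, 0.7)

    def test_gprime_tricube_frozen_fractions(self):
        # two loci separated by window/4: d = 0.5, w_far = (1 - 0.125)^3 = 343/512
        # normalised weights 512/855 (self) and 343/855 (neighbour)
        pos = np.array([1_000_000.0, 1_250_000.0])
        g = np.array([1.0, 0.0])
        out = smooth_gprime(pos, g, window=1_000_000)
        assert out[0] == pytest.approx(512 / 855, abs=1e-12)
        assert out[1] == pytest.approx(343 / 855, abs=1e-12)

    def test_gprime_isolated_locus_keeps_raw_value(self):
        out = smooth_gprime(np.array([1e6, 9e6]), np.array([5.0, 7.0]))
        assert np.allclose(out, [5.0, 7.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_gprime_is_a_convex_combination(self, seed):
        r = np.random.default_rng(seed)
        pos = np.sort(r.choice(np.arange(1, 3_000_000), 30, replace=False)).astype(float)
        g = r.exponential(size=30)
        out = smooth_gprime(pos, g)
        assert (out >= g.min() - 1e-12).all() and (out <= g.max() + 1e-12).all()

    def test_threshold_frozen_quantile(self):
        track = np.arange(1000, dtype=float)
        assert scan_threshold(track, 0.995) == pytest.approx(994.005)

    def test_threshold_empty_rejected(self):
        with pytest.raises(ValueError):
            scan_threshold(np.array([]))


class TestGenomeScan:
    def _spread_table(self, n=300, hot=10):
        r = np.random.default_rng(7)
        pos = np.sort(r.choice(np.arange(1, 30_000_000), n, replace=False))
        ad_high, ad_low = [], []
        hot_idx = set(range(n // 2, n // 2 + hot))
        for i in range(n):
            if i in hot_idx:
                ad_high.append((0, 30)); ad_low.append((30, 0))
            else:
                ad_high.append((15, 15)); ad_low.append((15, 15))
        return make_table("chr1", list(pos), ad_high, ad_low), pos, sorted(hot_idx)

    def test_divergent_cluster_is_flagged_by_both_methods(self):
        table, pos, hot = self._spread_table()
        for method in ("ED4", "Gprime"):
            scan = genome_scan(table, method)
            flagged = scan.loci.loc[scan.loci["above_threshold"], "pos"].to_numpy()
            assert len(flagged) > 0
            assert set(flagged) <= set(pos[hot[0] - 5:hot[-1] + 6])

    def test_fraction_above_threshold_near_half_percent(self):
        table, _, _ = self._spread_table(n=1000, hot=10)
        scan = genome_scan(table, "ED4")
        frac = scan.loci["above_threshold"].mean()
        assert frac <= 0.005 + 1e-9

    def test_zero_depth_loci_excluded(self):
        table = make_table("chr1", [100, 200, 300],
                           [(10, 10), (0, 0), (10, 10)],
                           [(10, 10), (5, 5), (10, 10)])
        scan = genome_scan(table, "Gprime")
        assert len(scan.loci) == 2 and 200 not in set(scan.loci["pos"])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            genome_scan(make_table("chr1", [1], [(1, 1)], [(1, 1)]), "LOD")
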