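"""RR-distribution and waveform comparison metrics, checked against
independent oracles (LP optimal transport, brute-force CDF sup, iterative
matrix square root)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog

from cardiosynth import (FeatureCloud, UnitHistogram, default_feature_extractor,
                         frechet_distance, kl, ks, mae_hr, remd, rhi, rmse,
                         rrmse, unit_histograms)
from cardiosynth.preprocess import segment


def hist(counts, start=0):
    counts = np.asarray(counts)
    return UnitHistogram(np.arange(start, start + len(counts) + 1), counts)


def transport_cost_lp(ca, cb):
    """Optimal-transport oracle: minimum work to morph histogram A into B
    (equal totals) with |i - j| ground distance, via linear programming."""
    n = len(ca)
    cost = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).ravel()
    a_eq = []
    for i in range(n):             # row sums = ca
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):             # col sums = cb
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    b_eq = np.concatenate([ca, cb])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, method="highs")
    assert res.success
    return res.fun


class TestRHI:
    def test_identical_is_one(self):
        h = hist([3, 1, 4])
        assert rhi(h, h) == 1.0

    def test_disjoint_is_zero(self):
        assert rhi(hist([2, 0]), hist([0, 3])) == 0.0

    def test_enumerated_example(self):
        assert rhi(hist([2, 0]), hist([1, 1])) == 0.5

    def test_mismatched_grid_raises(self):
        with pytest.raises(ValueError):
            rhi(hist([1, 1]), hist([1, 1], start=5))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rhi(hist([0, 0]), hist([1, 1]))


class TestRRMSE:
    def test_identical_zero(self):
        a = np.array([800.0, 900.0, 1000.0])
        assert rrmse(a, a) == 0.0

    def test_constant_offset(self):
        assert rrmse([1000.0, 1000.0], [1010.0, 1010.0]) == pytest.approx(0.01)

    def test_unequal_lengths_vs_quantile_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(600, 1200, size=40)
        b = rng.uniform(600, 1200, size=25)
        # independent oracle: linear interpolation of B's order statistics
        sa = np.sort(a)
        sb = np.sort(b)
        pos = np.linspace(0, len(b) - 1, len(a))
        b_interp = np.array([
            sb[int(np.floor(p))] * (1 - (p - np.floor(p)))
            + sb[min(int(np.floor(p)) + 1, len(b) - 1)] * (p - np.floor(p))
            for p in pos])
        expected = np.sqrt(np.mean((sa - b_interp) ** 2)) / sa.mean()
        assert rrmse(a, b) == pytest.approx(expected, abs=1e-9)


class TestREMD:
    def test_identical_zero(self):
        h = hist([2, 3, 1])
        assert remd(h, h) == 0.0

    def test_point_masses(self):
        m, k, n = 5, 4, 7
        counts_a = [n] + [0] * (m - 1)
        counts_b = [0] * k + [n] + [0] * (m - 1 - k)
        assert remd(hist(counts_a), hist(counts_b)) == pytest.approx(k / (m - 1))

    def test_symmetry_on_equal_totals(self):
        ha, hb = hist([1, 2, 3]), hist([3, 2, 1])
        assert remd(ha, hb) == pytest.approx(remd(hb, ha))

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=6),
           st.lists(st.integers(0, 5), min_size=2, max_size=6))
    def test_symmetry_property(self, ca, cb):
        n = min(len(ca), len(cb))
        ca, cb = ca[:n], cb[:n]
        if sum(ca) != sum(cb) or sum(ca) == 0:
            return
        assert remd(hist(ca), hist(cb)) == pytest.approx(
            remd(hist(cb), hist(ca)), abs=1e-12)

    def test_matches_lp_transport_on_all_small_histograms(self):
        # exhaustive: every pair of 3-bin histograms with equal total <= 6
        # plus random pairs up to 6 bins / total 10, against the LP oracle
        combos = [c for c in itertools.product(range(4), repeat=3)
                  if 0 < sum(c) <= 6]
        checked = 0
        for ca in combos:
            for cb in combos:
                if sum(ca) != sum(cb):
                    continue
                expected = transport_cost_lp(np.array(ca), np.array(cb)) \
                    / (sum(ca) * 2)
                assert remd(hist(ca), hist(cb)) == pytest.approx(
                    expected, abs=1e-9)
                checked += 1
        assert checked > 100
        rng = np.random.default_rng(1)
        for _ in range(20):
            nb = rng.integers(2, 7)
            ca = rng.multinomial(10, np.ones(nb) / nb)
            cb = rng.multinomial(10, np.ones(nb) / nb)
            expected = transport_cost_lp(ca, cb) / (10 * (nb - 1))
            assert remd(hist(ca), hist(cb)) == pytest.approx(expected, abs=1e-9)

    def test_single_bin_always_zero(self):
        # renormalization makes any two single-bin histograms coincide
        assert remd(hist([4]), hist([4])) == 0.0
        assert remd(hist([4]), hist([5])) == 0.0

    def test_renormalizes_b_to_a_total(self):
        # B has double mass but the same shape: distance 0
        assert remd(hist([1, 2]), hist([2, 4])) == 0.0


class TestKL:
    def test_identical_zero(self):
        h = hist([2, 2])
        assert kl(h, h) == pytest.approx(0.0, abs=1e-6)

    def test_two_term_closed_form(self):
        expected = 0.5 * np.log(2) + 0.5 * np.log(2.0 / 3.0)
        got = kl(hist([2, 2]), hist([1, 3]))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_asymmetric(self):
        ha, hb = hist([2, 2]), hist([1, 3])
        assert kl(ha, hb) != pytest.approx(kl(hb, ha), abs=1e-9)

    def test_empty_bins_finite_after_smoothing(self):
        assert np.isfinite(kl(hist([5, 0]), hist([0, 5])))


class TestKS:
    def test_identical_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert ks(a, a) == 0.0

    def test_disjoint_is_one(self):
        assert ks([1.0, 2, 3], [4.0, 5, 6]) == 1.0

    def test_matches_brute_force_sup(self):
        rng = np.random.default_rng(2)
        a = rng.normal(800, 40, size=37)
        b = rng.normal(820, 50, size=23)
        pooled = np.concatenate([a, b])
        sup = max(abs((a <= x).mean() - (b <= x).mean()) for x in pooled)
        assert ks(a, b) == pytest.approx(sup, abs=1e-12)


class TestRMSE:
    def test_identity_and_offset(self):
        x = np.arange(10.0)
        assert rmse(x, x) == 0.0
        assert rmse(x + 1.0, x) == pytest.approx(1.0)

    def test_against_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=100), rng.normal(size=100)
        expected = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 100)
        assert rmse(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))


class TestMAEHR:
    def test_identical_zero(self):
        assert mae_hr([1000.0, 1000.0], [1000.0, 1000.0]) == 0.0

    def test_two_beat_example(self):
        rr_g = 60000.0 / np.array([60.0, 60.0])
        rr_r = 60000.0 / np.array([62.0, 58.0])
        assert mae_hr(rr_g, rr_r) == pytest.approx(2.0)

    def test_single_interval(self):
        assert mae_hr([1000.0], [1200.0]) == pytest.approx(10.0)


class TestFrechet:
    def test_identical_clouds_zero(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(50, 3))
        c = FeatureCloud.from_features(f)
        assert frechet_distance(c, c) == pytest.approx(0.0, abs=1e-9)

    def test_one_dimensional_closed_form(self):
        cr = FeatureCloud(mu=np.array([0.0]), sigma=np.array([[1.0]]))
        cg = FeatureCloud(mu=np.array([1.0]), sigma=np.array([[1.0]]))
        assert frechet_distance(cr, cg) == pytest.approx(1.0)

    def test_against_iterative_sqrt_oracle(self):
        # Denman–Beavers iteration as an independent matrix-sqrt oracle
        rng = np.random.default_rng(5)
        fr = rng.normal(size=(200, 3))
        fg = rng.normal(size=(200, 3)) @ np.diag([1.0, 2.0, 0.5]) + 1.0
        cr = FeatureCloud.from_features(fr)
        cg = FeatureCloud.from_features(fg)

        def db_sqrt(m, iters=60):
            y, z = m.copy(), np.eye(len(m))
            for _ in range(iters):
                y, z = 0.5 * (y + np.linalg.inv(z)), 0.5 * (z + np.linalg.inv(y))
            return y

        s = db_sqrt(cr.sigma)
        cross = db_sqrt(s @ cg.sigma @ s)
        diff = cr.mu - cg.mu
        expected = diff @ diff + np.trace(cr.sigma + cg.sigma) \
            - 2 * np.trace(cross)
        assert frechet_distance(cr, cg) == pytest.approx(expected, abs=1e-6)

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(6)
        clouds = [FeatureCloud.from_features(rng.normal(size=(30, 4)) * s)
                  for s in (1.0, 2.0, 0.3)]
        for ca in clouds:
            for cb in clouds:
                d1, d2 = frechet_distance(ca, cb), frechet_distance(cb, ca)
                assert d1 >= 0
                assert d1 == pytest.approx(d2, abs=1e-8)

    def test_dimension_mismatch_raises(self):
        cr = FeatureCloud(mu=np.zeros(2), sigma=np.eye(2))
        cg = FeatureCloud(mu=np.zeros(3), sigma=np.eye(3))
        with pytest.raises(ValueError):
            frechet_distance(cr, cg)


class TestFeatureExtractor:
    def test_identical_sets_fd_zero(self, rsr_constant_pair):
        segs = segment(rsr_constant_pair.ecg, 512, 0.5)
        for kind in ("stft", "raw"):
            c = default_feature_extractor(segs, kind)
            assert frechet_distance(c, c) == pytest.approx(0.0, abs=1e-8)
            assert c.extractor == kind

    def test_permutation_invariant(self, rsr_constant_pair):
        segs = segment(rsr_constant_pair.ecg, 512, 0.5).segments
        c1 = FeatureCloud.from_features(segs)
        c2 = FeatureCloud.from_features(segs[::-1])
        assert np.allclose(c1.mu, c2.mu)
        assert np.allclose(c1.sigma, c2.sigma)

    def test_too_few_segments_raises(self):
        with pytest.raises(ValueError):
            default_feature_extractor(np.zeros((1, 512)))


class TestUnitHistograms:
    def test_shared_grid_and_totals(self):
        a = np.array([800.0, 801.4, 803.9])
        b = np.array([799.2, 805.0])
        ha, hb = unit_histograms(a, b)
        assert np.array_equal(ha.bin_edges, hb.bin_edges)
        assert ha.total == 3 and hb.total == 2
        assert ha.bin_edges[0] == 799 and ha.bin_edges[-1] == 806

    def test_metric_identities_on_fixture(self, rsr_variable_pair):
        rr = rsr_variable_pair.rr_schedule * 8.0      # ms at 125 Hz
        ha, hb = unit_histograms(rr, rr)
        assert rhi(ha, hb) == 1.0
        assert remd(ha, hb) == 0.0
        assert kl(ha, hb) == pytest.approx(0.0, abs=1e-6)
        assert ks(rr, rr) == 0.0
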