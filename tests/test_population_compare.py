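"""The histogram difference metric D, its Gaussian calibration, and the
exact Fisher test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from calsig import (
    NormalizedHistogram,
    ValidationError,
    build_histogram_pair,
    compare_conditions,
    difference_metric,
    fisher_exact_2x2,
    gaussian_calibration,
    gaussian_tv_distance,
    generate_gaussian_surrogate,
)


def hist_from_probs(probs, edges=None):
    probs = np.asarray(probs, dtype=float)
    if edges is None:
        edges = np.arange(len(probs) + 1, dtype=float)
    return NormalizedHistogram(edges=edges, probs=probs)


prob_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    min_size=2, max_size=20,
).filter(lambda v: sum(v) > 1e-6).map(
    lambda v: np.asarray(v) / np.sum(v))


class TestBuildHistogramPair:
    def test_identical_samples_identical_probs(self):
        ha, hb = build_histogram_pair([1, 2, 3], [1, 2, 3], bins=4)
        np.testing.assert_array_equal(ha.probs, hb.probs)
        np.testing.assert_array_equal(ha.edges, hb.edges)

    def test_disjoint_samples_share_no_bins(self):
        ha, hb = build_histogram_pair([0.0, 1.0], [10.0, 11.0], bins=20)
        assert np.all(ha.probs * hb.probs == 0)

    def test_unit_mass_and_mean_recovered(self):
        sample = generate_gaussian_surrogate(5000, 5.0, 1.0, seed=42)
        ha, _ = build_histogram_pair(sample, sample, bins=50)
        assert ha.probs.sum() == pytest.approx(1.0, abs=1e-12)
        centers = 0.5 * (ha.edges[:-1] + ha.edges[1:])
        assert np.sum(centers * ha.probs) == pytest.approx(5.0, abs=0.05)

    def test_zero_range_degenerates_to_one_bin(self):
        ha, hb = build_histogram_pair([2.0, 2.0], [2.0], bins=50)
        assert ha.n_bins == 1
        assert ha.probs[0] == hb.probs[0] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            build_histogram_pair([], [1.0])


class TestDifferenceMetric:
    def test_identical_histograms_give_zero(self):
        h = hist_from_probs([0.25, 0.5, 0.25])
        assert difference_metric(h, h).d == 0.0

    def test_disjoint_histograms_give_one(self):
        a = hist_from_probs([0.5, 0.5, 0.0, 0.0])
        b = hist_from_probs([0.0, 0.0, 0.5, 0.5])
        assert difference_metric(a, b).d == pytest.approx(1.0, abs=1e-15)

    def test_half_overlap_hand_computed(self):
        a = hist_from_probs([0.5, 0.5, 0.0])
        b = hist_from_probs([0.0, 0.5, 0.5])
        assert difference_metric(a, b).d == pytest.approx(0.5)

    def test_mismatched_edges_rejected(self):
        a = hist_from_probs([0.5, 0.5], edges=np.array([0.0, 1.0, 2.0]))
        b = hist_from_probs([0.5, 0.5], edges=np.array([0.0, 1.0, 3.0]))
        with pytest.raises(ValidationError):
            difference_metric(a, b)

    @settings(derandomize=True, max_examples=200)
    @given(pair=st.tuples(prob_vectors, prob_vectors))
    def test_metric_axioms(self, pair):
        # D is the total variation distance between the binned
        # distributions: bounded, symmetric, zero on the diagonal
        pa, pb = pair
        n = max(len(pa), len(pb))
        pa = np.pad(pa, (0, n - len(pa)))
        pb = np.pad(pb, (0, n - len(pb)))
        a, b = hist_from_probs(pa), hist_from_probs(pb)
        d_ab = difference_metric(a, b).d
        assert 0.0 <= d_ab <= 1.0 + 1e-12
        assert difference_metric(b, a).d == d_ab
        assert difference_metric(a, a).d == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(triple=st.tuples(prob_vectors, prob_vectors, prob_vectors))
    def test_triangle_inequality(self, triple):
        n = max(len(p) for p in triple)
        a, b, c = (hist_from_probs(np.pad(p, (0, n - len(p))))
                   for p in triple)
        dab = difference_metric(a, b).d
        dbc = difference_metric(b, c).d
        dac = difference_metric(a, c).d
        assert dac <= dab + dbc + 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(pair=st.tuples(prob_vectors, prob_vectors),
           merge_at=st.integers(min_value=0, max_value=18))
    def test_merging_adjacent_bins_never_increases_d(self, pair, merge_at):
        pa, pb = pair
        n = max(len(pa), len(pb), merge_at + 2)
        pa = np.pad(pa, (0, n - len(pa)))
        pb = np.pad(pb, (0, n - len(pb)))
        fine = difference_metric(hist_from_probs(pa), hist_from_probs(pb)).d

        def merged(p):
            q = np.concatenate([
                p[:merge_at], [p[merge_at] + p[merge_at + 1]],
                p[merge_at + 2:]])
            return hist_from_probs(q)

        coarse = difference_metric(merged(pa), merged(pb)).d
        assert coarse <= fine + 1e-12


class TestGaussianCalibration:
    def test_zero_offset_is_sampling_noise(self):
        tab = gaussian_calibration([0.0], n=5000, n_seeds=5, seed=3)
        assert tab.mean_d.iloc[0] < 0.1

    def test_monotone_in_offset(self):
        tab = gaussian_calibration([0.0, 0.5, 1.0, 2.0, 3.0], n=2000,
                                   n_seeds=5, seed=9)
        assert tab.mean_d.is_monotonic_increasing

    def test_determinism(self):
        a = gaussian_calibration([1.0], n=1000, n_seeds=3, seed=21)
        b = gaussian_calibration([1.0], n=1000, n_seeds=3, seed=21)
        assert a.equals(b)

    def test_analytic_total_variation_limit(self):
        # exact binned masses (no sampling): D grows toward the analytic
        # total variation distance 1 - 2*Phi(-delta/2) as bins refine
        for delta in (1.0, 2.0, 3.0):
            tv = gaussian_tv_distance(delta)
            prev = 0.0
            for bins in (10, 50, 1000):
                edges = np.linspace(5 - 6, 5 + delta + 6, bins + 1)
                pa = np.diff(stats.norm.cdf(edges, loc=5.0))
                pb = np.diff(stats.norm.cdf(edges, loc=5.0 + delta))
                d = 0.5 * np.abs(pa / pa.sum() - pb / pb.sum()).sum()
                assert prev <= d + 1e-12 <= tv + 1e-9
                prev = d
            assert prev == pytest.approx(tv, abs=1e-4)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        # margins (2,2,2): P(k=0) = P(k=2) = 1/6, P(k=1) = 4/6
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_row_swap_symmetry(self):
        table = np.array([[7, 2], [3, 9]])
        assert fisher_exact_2x2(table) == fisher_exact_2x2(table[::-1])

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0

    def test_matches_exact_fraction_enumeration_small_margins(self):
        # independent oracle: exact rational enumeration of every table
        rng = np.random.default_rng(0)
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            r1, r2, c1 = a + b, c + d, a + c
            denom = math.comb(r1 + r2, c1)
            probs = {
                k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
                for k in range(max(0, c1 - r2), min(r1, c1) + 1)
            }
            expected = float(sum(p for p in probs.values()
                                 if p <= probs[a]))
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                expected, rel=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            table = rng.integers(1, 25, (2, 2))
            ours = fisher_exact_2x2(table)
            ref = stats.fisher_exact(table, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-9)


class TestCompareConditions:
    def test_same_distribution_is_control_level(self):
        a = np.random.default_rng(10).lognormal(1.0, 0.5, 3000)
        b = np.random.default_rng(11).lognormal(1.0, 0.5, 3000)
        mat = compare_conditions({"a": a, "b": b})
        assert mat.loc["a", "b"] < 0.15
        assert mat.loc["a", "a"] == 0.0

    def test_far_offset_lognormals_near_one(self):
        a = np.random.default_rng(1).lognormal(0.0, 0.2, 2000)
        b = np.random.default_rng(2).lognormal(6.0, 0.2, 2000)
        mat = compare_conditions({"a": a, "b": b})
        assert mat.loc["a", "b"] > 0.95

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        conditions = {k: rng.gamma(2.0, 2.0, 500) for k in "abc"}
        mat = compare_conditions(conditions)
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)

    def test_empty_condition_excluded(self, caplog):
        a = np.arange(10.0)
        mat = compare_conditions({"a": a, "b": a + 1, "empty": []})
        assert "empty" not in mat.index
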