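import numpy as np
import pytest

from sadjerk import (
    SADCurve,
    UniformSeries,
    classic_flattening_window,
    compute_sad_curve,
    discrete_gradient,
    find_zero_crossings,
    merge_zero_points,
    select_windows,
    third_gradient,
)
from .conftest import make_random_series
from .oracles import (
    brute_select_windows,
    naive_gradient,
    naive_pairwise_merge,
    naive_sad_curve,
    naive_sign_scan,
)


class TestSADCurve:
    def test_window_one_gives_zero_sad(self, hr_like):
        sad = compute_sad_curve(hr_like, 20)
        assert sad.sad_values[0] == 0.0

    def test_constant_series_gives_all_zero_curve(self):
        sad = compute_sad_curve(UniformSeries(np.full(30, 100.0)), 10)
        assert np.array_equal(sad.sad_values, np.zeros(10))

    def test_spike_example_at_window_three(self):
        # filtered [0,1,1,1,0]: |0-0|+|0-1|+|3-1|+|0-1|+|0-0| = 4
        sad = compute_sad_curve(UniformSeries([0, 0, 3, 0, 0]), 3)
        assert sad.sad_values[2] == pytest.approx(4.0)

    def test_matches_brute_force_curve(self, hr_like):
        sad = compute_sad_curve(hr_like, 30)
        assert np.allclose(sad.sad_values, naive_sad_curve(hr_like.values, 30), atol=1e-8)

    def test_nonnegative_and_validated(self, hr_like):
        sad = compute_sad_curve(hr_like, 40)
        assert np.all(sad.sad_values >= 0)
        with pytest.raises(ValueError):
            compute_sad_curve(hr_like, 1)
        with pytest.raises(ValueError):
            compute_sad_curve(hr_like, len(hr_like) + 1)


class TestDiscreteGradient:
    def test_linear_ramp_is_constant_everywhere(self):
        v = 3.5 * np.arange(10) - 2
        assert np.allclose(discrete_gradient(v), 3.5)

    def test_central_difference_value(self):
        assert discrete_gradient([0, 1, 4])[1] == pytest.approx(2.0)

    def test_quadratic_interior_is_exact(self):
        i = np.arange(6.0)
        g = discrete_gradient(i**2)
        assert np.allclose(g[1:-1], 2 * i[1:-1])

    def test_agrees_with_handwritten_oracle(self, rng):
        v = rng.normal(0, 5, 40)
        assert np.allclose(discrete_gradient(v), naive_gradient(v))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            discrete_gradient([1.0])


class TestThirdGradient:
    @staticmethod
    def _curve(values):
        n = len(values)
        return SADCurve(np.arange(1, n + 1), np.asarray(values, float))

    # the one-sided boundary differences contaminate one extra index per
    # gradient application, so after three passes "interior" means [3:-3]

    def test_quadratic_vanishes_at_interior(self):
        i = np.arange(12.0)
        jerk = third_gradient(self._curve(i**2))
        assert np.allclose(jerk.values[3:-3], 0.0)

    def test_cubic_gives_exactly_six(self):
        i = np.arange(12.0)
        jerk = third_gradient(self._curve(i**3))
        assert np.allclose(jerk.values[3:-3], 6.0)

    def test_constant_gives_zeros(self):
        jerk = third_gradient(self._curve(np.zeros(8)))
        assert np.array_equal(jerk.values, np.zeros(8))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            third_gradient(self._curve([0.0, 1.0, 2.0]))


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, -1], [1]),
            ([1, 1, 1], []),
            ([1, 0, -1], [2]),
            ([1, 0, 1], []),          # touch-and-return does not count
            ([-1, 0, 0, 2], [3]),     # pass-through counts once, at the later index
            ([0, 0, 1, -1], [3]),     # leading zeros carry no sign
        ],
    )
    def test_examples(self, values, expected):
        assert find_zero_crossings(values) == expected

    def test_agrees_with_naive_scan_on_random_sequences(self, rng):
        for _ in range(1000):
            v = rng.choice([-1.0, 0.0, 1.0], size=rng.integers(2, 40))
            assert find_zero_crossings(v) == naive_sign_scan(v)


class TestMergeZeroPoints:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([10, 12], [11]),
            ([10, 14], [10, 14]),
            ([10, 12, 13], [12]),  # cascade: (10,12)->11, then (11,13)->12
            ([], []),
            ([5], [5]),
        ],
    )
    def test_examples(self, points, expected):
        merged, _ = merge_zero_points(points)
        assert merged == expected

    def test_merged_from_covers_inputs(self):
        merged, members = merge_zero_points([10, 12, 13, 20])
        assert merged == [12, 20]
        assert members == [[10, 12, 13], [20]]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            merge_zero_points([5, 3])

    def test_output_increasing_and_within_hull(self, rng):
        for _ in range(200):
            pts = np.unique(rng.integers(2, 100, size=rng.integers(1, 12))).tolist()
            merged, members = merge_zero_points(pts)
            assert merged == sorted(set(merged)) and len(merged) == len(set(merged))
            for value, group in zip(merged, members):
                assert min(group) <= value <= max(group)
            assert merged == naive_pairwise_merge(pts)


class TestSelectWindows:
    def test_constant_series_has_no_crossings_and_is_flagged(self):
        zp = select_windows(UniformSeries(np.full(100, 100.0)), N=20)
        assert zp.points == ()
        assert not zp.complete

    def test_matches_brute_force_pipeline(self, rng):
        for _ in range(10):
            series = make_random_series(rng, n=300)
            zp = select_windows(series, N=40)
            assert list(zp.points) == brute_select_windows(series.values, 40)

    def test_series_shorter_than_n_rejected(self):
        with pytest.raises(ValueError):
            select_windows(UniformSeries([1.0, 2.0, 3.0]), N=10)

    def test_deterministic(self, hr_like):
        a = select_windows(hr_like, N=60)
        b = select_windows(hr_like, N=60)
        assert a == b


class TestClassicFlatteningWindow:
    @staticmethod
    def _curve(values):
        n = len(values)
        return SADCurve(np.arange(1, n + 1), np.asarray(values, float))

    def test_constant_from_k_returns_k(self):
        # curve rises 0,1,...,9 then stays at 9 from window 10 onward
        sad = self._curve(np.minimum(np.arange(30.0), 9.0))
        assert classic_flattening_window(sad, rel_tol=0.01, span=5) == 10

    def test_strictly_linear_curve_never_flattens(self):
        sad = self._curve(np.arange(30.0))
        assert classic_flattening_window(sad, rel_tol=0.001, span=5) is None

    def test_matches_exhaustive_scan_on_saturating_curve(self):
        n = np.arange(1, 101)
        values = 1 - np.exp(-n / 20.0)
        values[0] = 0.0
        sad = self._curve(values)
        got = classic_flattening_window(sad, rel_tol=0.01, span=10)
        # independent scan of the same rule
        expected = None
        for i in range(len(values) - 10):
            if values[i] > 0 and abs(values[i + 10] - values[i]) / values[i] < 0.01:
                expected = int(n[i])
                break
        assert got == expected is not None and got == expected
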