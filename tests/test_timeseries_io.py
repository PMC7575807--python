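import numpy as np
import pytest

from sadjerk.timeseries_io import (
    GapError,
    SeriesError,
    UniformSeries,
    clean_and_resample,
    read_csv_series,
    read_pamap2_dat,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestUniformSeries:
    def test_validates_on_construction(self):
        with pytest.raises(SeriesError):
            UniformSeries([1.0])
        with pytest.raises(SeriesError):
            UniformSeries([1.0, float("nan")])
        with pytest.raises(SeriesError):
            UniformSeries([1.0, 2.0], sample_interval_s=0.0)

    def test_times_and_duration(self):
        s = UniformSeries([1, 2, 3], sample_interval_s=2.0, start_time_s=10.0)
        assert np.array_equal(s.times, [10.0, 12.0, 14.0])
        assert s.duration_s == 6.0


class TestReadCsv:
    def test_uniform_file_is_identity(self, tmp_path):
        p = write(tmp_path, "a.csv", "time_s,hr_bpm\n0,100\n1,101\n2,102\n")
        s = read_csv_series(p)
        assert np.array_equal(s.values, [100, 101, 102])
        assert s.sample_interval_s == 1.0

    def test_missing_value_is_interpolated(self, tmp_path):
        # value missing at t=1 -> dropped, spacing non-uniform -> resample at 1 s
        p = write(tmp_path, "a.csv", "time_s,hr_bpm\n0,100\n1,\n2,104\n3,106\n4,108\n")
        s = read_csv_series(p)
        assert len(s) == 5
        assert s.values[1] == pytest.approx(102.0)  # midpoint of 100 and 104

    def test_non_monotonic_time_rejected(self, tmp_path):
        p = write(tmp_path, "a.csv", "time_s,hr_bpm\n2,100\n1,101\n3,102\n")
        with pytest.raises(SeriesError, match="increasing"):
            read_csv_series(p)

    def test_missing_column_and_short_file(self, tmp_path):
        p = write(tmp_path, "a.csv", "t,v\n0,100\n1,101\n")
        with pytest.raises(SeriesError, match="column"):
            read_csv_series(p)
        p2 = write(tmp_path, "b.csv", "time_s,hr_bpm\n0,100\n1,\n2,\n")
        with pytest.raises(SeriesError, match="fewer than 2"):
            read_csv_series(p2)

    def test_custom_column_names(self, tmp_path):
        p = write(tmp_path, "a.csv", "sec,bpm\n0,90\n1,91\n")
        s = read_csv_series(p, time_column="sec", value_column="bpm")
        assert np.array_equal(s.values, [90, 91])


class TestReadPamap2:
    def test_direct_mapping(self, tmp_path):
        p = write(tmp_path, "s.dat", "0.00 1 100 9.9\n1.00 1 102 9.8\n")
        s = read_pamap2_dat(p)
        assert np.array_equal(s.values, [100, 102])
        assert s.sample_interval_s == 1.0

    def test_gap_is_linearly_interpolated(self, tmp_path):
        p = write(tmp_path, "s.dat", "0.0 1 100 0\n2.0 1 104 0\n")
        s = read_pamap2_dat(p)
        assert np.allclose(s.values, [100, 102, 104])

    def test_nan_rows_are_skipped(self, tmp_path):
        p = write(tmp_path, "s.dat", "0.0 1 100 0\n0.5 1 NaN 0\n1.0 1 102 0\n")
        s = read_pamap2_dat(p)
        assert np.array_equal(s.values, [100, 102])

    def test_all_missing_is_an_error(self, tmp_path):
        p = write(tmp_path, "s.dat", "0.0 1 NaN 0\n1.0 1 NaN 0\n")
        with pytest.raises(SeriesError, match="no usable heart-rate"):
            read_pamap2_dat(p)

    def test_unparseable_row_reports_line_number(self, tmp_path):
        p = write(tmp_path, "s.dat", "0.0 1 100 0\nbogus x y\n")
        with pytest.raises(SeriesError, match=":2:"):
            read_pamap2_dat(p)


class TestCleanAndResample:
    def test_already_uniform_is_identity(self):
        t = np.arange(10.0)
        v = np.arange(10.0) * 3 + 100
        s = clean_and_resample(t, v, 1.0)
        assert np.array_equal(s.values, v)

    def test_bin_mean(self):
        # 0.2 s and 0.7 s fall in bin 0 -> mean 102
        s = clean_and_resample([0.2, 0.7, 1.3], [100.0, 104.0, 106.0], 1.0)
        assert s.values[0] == pytest.approx(102.0)
        assert s.start_time_s == 0.0

    def test_long_gap_raises(self):
        with pytest.raises(GapError):
            clean_and_resample([0.0, 1.0, 12.0], [100, 101, 105], 1.0, max_gap_s=5.0)

    def test_non_monotonic_rejected(self):
        with pytest.raises(SeriesError, match="increasing"):
            clean_and_resample([0.0, 2.0, 1.0], [1, 2, 3], 1.0)

    def test_output_length_matches_span(self, rng):
        """Output length equals ceil(span / interval) within one sample."""
        for _ in range(50):
            n = int(rng.integers(5, 60))
            t = np.sort(rng.uniform(0, 100, n))
            t = t[np.concatenate(([True], np.diff(t) > 1e-6))]
            if t.size < 2 or np.any(np.diff(t) > 25):
                continue
            v = rng.normal(100, 5, t.size)
            s = clean_and_resample(t, v, 1.0, max_gap_s=30.0)
            span = t[-1] - t[0]
            assert abs(len(s) - np.ceil(span / 1.0)) <= 1

    def test_interpolated_values_bounded_by_neighbours(self):
        s = clean_and_resample([0.0, 4.0], [100.0, 108.0], 1.0)
        assert np.all(s.values >= 100.0) and np.all(s.values <= 108.0)
        assert np.allclose(s.values, [100, 102, 104, 106, 108])
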