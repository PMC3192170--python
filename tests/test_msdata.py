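"""Run I/O, XIC extraction, peak detection and integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enrichms.msdata import (
    XIC,
    PeakBounds,
    Run,
    SpectrumScan,
    detect_peak,
    extract_product_xic,
    integrate,
    read_run,
    union_bounds,
    write_run,
)

from .conftest import make_gaussian_xic, make_run


class TestRunIO:
    def test_tabular_round_trip_is_bit_exact(self, noise_free_run, tmp_path):
        path = tmp_path / "run.tsv"
        write_run(noise_free_run, path)
        loaded = read_run(path)
        assert loaded.metadata == noise_free_run.metadata
        assert len(loaded) == len(noise_free_run)
        for a, b in zip(noise_free_run.scans, loaded.scans):
            assert a.retention_time == b.retention_time
            assert a.precursor_target_mz == b.precursor_target_mz
            assert a.peaks == b.peaks

    def test_mzml_round_trip(self, noise_free_run, tmp_path):
        path = tmp_path / "run.mzML"
        write_run(noise_free_run, path)
        loaded = read_run(path)
        assert len(loaded) == len(noise_free_run)
        for a, b in zip(noise_free_run.scans, loaded.scans):
            assert a.retention_time == b.retention_time
            assert a.precursor_target_mz == b.precursor_target_mz
            assert a.peaks == b.peaks

    def test_mzml_single_scan_three_peaks(self, tmp_path):
        run = make_run([[(100.0, 1.0), (200.0, 2.0), (300.0, 3.0)]], rts=[1.5])
        path = tmp_path / "one.mzML"
        write_run(run, path)
        loaded = read_run(path)
        assert len(loaded) == 1
        assert loaded.scans[0].peaks == run.scans[0].peaks

    def test_empty_run_round_trips(self, tmp_path):
        for name in ("empty.tsv", "empty.mzML"):
            path = tmp_path / name
            write_run(Run(), path)
            assert len(read_run(path)) == 0

    def test_empty_scan_preserved(self, tmp_path):
        run = make_run([[], [(100.0, 5.0)]], rts=[1.0, 2.0])
        path = tmp_path / "sparse.tsv"
        write_run(run, path)
        loaded = read_run(path)
        assert loaded.scans[0].peaks == []
        assert loaded.scans[1].peaks == [(100.0, 5.0)]

    def test_malformed_mzml_names_offending_scan(self, tmp_path):
        path = tmp_path / "bad.mzML"
        good = tmp_path / "good.mzML"
        write_run(make_run([[(100.0, 1.0)]]), good)
        text = good.read_text().replace('name="selected ion m/z"', 'name="bogus"')
        path.write_text(text)
        with pytest.raises(ValueError, match="malformed spectrum"):
            read_run(path)

    def test_malformed_tabular_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("scan_index\trt_min\tprecursor_mz\tpeak_mz\tintensity\n1\t2\n")
        with pytest.raises(ValueError, match="line 2"):
            read_run(path)

    def test_scans_must_increase_in_time(self):
        scan = SpectrumScan(1.0, 500.0, [])
        with pytest.raises(ValueError):
            Run(scans=[scan, SpectrumScan(1.0, 500.0, [])])


class TestXICExtraction:
    def test_peak_captured_within_half_dalton(self):
        run = make_run([[(672.37, 100.0)]], precursor=1038.59)
        xic = extract_product_xic(run, 1038.59, 672.4, tolerance=0.5)
        assert xic.intensities.tolist() == [100.0]

    def test_query_off_target_gives_all_zero(self):
        run = make_run([[(672.37, 100.0)]] * 3, precursor=1038.59)
        xic = extract_product_xic(run, 1038.59, 500.0)
        assert np.all(xic.intensities == 0)
        assert len(xic) == 3

    def test_boundary_peak_included(self):
        run = make_run([[(672.9, 50.0)]], precursor=1038.59)
        xic = extract_product_xic(run, 1038.59, 672.4, tolerance=0.5)
        assert xic.intensities.tolist() == [50.0]

    def test_precursor_filter_excludes_other_targets(self):
        scans = [
            SpectrumScan(1.0, 1038.59, [(672.4, 10.0)]),
            SpectrumScan(2.0, 1047.65, [(681.4, 99.0)]),
            SpectrumScan(3.0, 1038.59, [(672.4, 20.0)]),
        ]
        xic = extract_product_xic(Run(scans=scans), 1038.59, 672.4)
        assert xic.intensities.tolist() == [10.0, 20.0]

    def test_scaling_intensities_scales_xic_linearly(self, noise_free_run):
        doubled = Run(
            scans=[
                SpectrumScan(s.retention_time, s.precursor_target_mz,
                             [(mz, 2 * i) for mz, i in s.peaks])
                for s in noise_free_run.scans
            ],
            metadata=noise_free_run.metadata,
        )
        xic1 = extract_product_xic(noise_free_run, 1038.594, 672.4)
        xic2 = extract_product_xic(doubled, 1038.594, 672.4)
        assert np.allclose(xic2.intensities, 2 * xic1.intensities)

    @given(st.floats(min_value=0.1, max_value=0.4),
           st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=30, deadline=None)
    def test_widening_tolerance_never_decreases_points(self, tol, extra):
        run = make_run(
            [[(672.1, 5.0), (672.5, 7.0), (673.0, 2.0)]] * 3, precursor=1038.59
        )
        narrow = extract_product_xic(run, 1038.59, 672.4, tolerance=tol)
        wide = extract_product_xic(run, 1038.59, 672.4, tolerance=tol + extra)
        assert np.all(wide.intensities >= narrow.intensities)


class TestPeakDetection:
    def test_gaussian_apex_at_elution_center(self, gaussian_xic):
        bounds = detect_peak(gaussian_xic)
        assert bounds.found
        assert bounds.apex_time == pytest.approx(10.0, abs=0.005)
        assert bounds.left_bound < 10.0 < bounds.right_bound

    def test_monotone_ramp_bounds_are_xic_extremes(self):
        t = np.linspace(0, 1, 11)
        xic = XIC(500.0, 0.5, t, np.linspace(1.0, 10.0, 11))
        bounds = detect_peak(xic)
        assert bounds.left_bound == t[0]
        assert bounds.right_bound == t[-1]

    def test_all_zero_xic_flagged_not_raised(self):
        xic = XIC(500.0, 0.5, np.arange(3.0), np.zeros(3))
        bounds = detect_peak(xic)
        assert not bounds.found

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            detect_peak(XIC(500.0, 0.5, np.arange(2.0), np.ones(2)))

    def test_valley_between_two_peaks_splits_them(self):
        t = np.linspace(0, 10, 101)
        y = 100 * np.exp(-((t - 3) ** 2) / 0.5) + 80 * np.exp(-((t - 7) ** 2) / 0.5)
        bounds = detect_peak(XIC(500.0, 0.5, t, y))
        assert bounds.apex_time == pytest.approx(3.0, abs=0.1)
        assert bounds.right_bound < 6.0


class TestIntegration:
    def test_gaussian_area_matches_closed_form(self, gaussian_xic):
        bounds = detect_peak(gaussian_xic)
        peak = integrate(gaussian_xic, bounds)
        expected = 1000.0 * 0.1 * math.sqrt(2 * math.pi)
        assert peak.area == pytest.approx(expected, rel=0.01)

    def test_flat_zero_signal_integrates_to_zero(self):
        xic = XIC(500.0, 0.5, np.arange(5.0), np.zeros(5))
        assert integrate(xic, (0.0, 4.0)).area == 0.0

    def test_doubling_intensities_doubles_area(self, gaussian_xic):
        doubled = XIC(500.0, 0.5, gaussian_xic.times, 2 * gaussian_xic.intensities)
        bounds = (float(gaussian_xic.times[0]), float(gaussian_xic.times[-1]))
        assert integrate(doubled, bounds).area == pytest.approx(
            2 * integrate(gaussian_xic, bounds).area, rel=1e-12
        )

    def test_inverted_bounds_rejected(self, gaussian_xic):
        with pytest.raises(ValueError, match="inverted"):
            integrate(gaussian_xic, (10.5, 9.5))

    def test_bounds_outside_range_rejected(self, gaussian_xic):
        with pytest.raises(ValueError, match="outside"):
            integrate(gaussian_xic, (0.0, 10.0))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_trapezoid_matches_riemann_sum_on_piecewise_linear(self, seed):
        """Independent oracle: dense midpoint Riemann sum over the same
        piecewise-linear profile agrees within 0.5%."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 30)
        t = np.sort(rng.uniform(0, 10, size=n))
        t += np.arange(n) * 1e-6  # enforce strictly increasing
        y = rng.uniform(1.0, 100.0, size=n)
        xic = XIC(500.0, 0.5, t, y)
        area = integrate(xic, (float(t[0]), float(t[-1]))).area
        dense_t = np.linspace(t[0], t[-1], 200_001)
        midpoints = (dense_t[:-1] + dense_t[1:]) / 2
        riemann = float(
            np.sum(np.interp(midpoints, t, y) * np.diff(dense_t))
        )
        assert area == pytest.approx(riemann, rel=0.005)


class TestBoundsUnion:
    def test_union_covers_both_windows(self):
        a = PeakBounds(1.0, 3.0, 2.0)
        b = PeakBounds(2.0, 4.0, 2.5)
        merged = union_bounds(a, b)
        assert (merged.left_bound, merged.right_bound) == (1.0, 4.0)

    def test_missing_peak_falls_back_to_other(self):
        found = PeakBounds(1.0, 3.0, 2.0)
        missing = PeakBounds(0.0, 5.0, 0.0, found=False)
        assert union_bounds(found, missing) == found
        assert union_bounds(missing, found) == found
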