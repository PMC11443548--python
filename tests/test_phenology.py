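"""Bloom phenology: threshold, cumulative sums, detection, seasons, box scan."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seabloom import (
    GeoField,
    PhenoConfig,
    Region,
    box_scan,
    compute_threshold,
    cumulative_anomaly,
    detect_phenology,
    fill_gaps_linear,
    run_phenology,
    season_windows,
)
from seabloom.calendars import eight_day_dates
from seabloom.synthetic import BloomTruth, make_bloom_study_series, make_chl_series


def season_series(values, start="2019-10-01"):
    return pd.Series(values, index=pd.date_range(start, periods=len(values), freq="8D"))


class TestThreshold:
    def test_constant_series(self):
        series = season_series(np.full(46, 0.10))
        assert compute_threshold(series) == pytest.approx(0.12)

    def test_explicit_median_of_constructed_list(self):
        # odd length, sorted midpoint 0.1 -> threshold 0.12
        values = np.array([0.02, 0.05, 0.08, 0.09, 0.10, 0.12, 0.20, 0.25, 0.30])
        assert float(np.median(values)) == 0.10
        series = season_series(values)
        assert compute_threshold(series) == pytest.approx(0.12)

    def test_threshold_is_exactly_1p2_times_median(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(-2, 0.5, 500)
        series = season_series(values)
        assert compute_threshold(series) == np.median(values) * 1.2

    def test_zero_percent_returns_median(self):
        series = season_series(np.array([0.1, 0.2, 0.3]))
        config = PhenoConfig(threshold_percent=0.0)
        assert compute_threshold(series, config) == pytest.approx(0.2)

    def test_empty_or_gapped_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_threshold(season_series(np.array([])))
        with pytest.raises(ValueError, match="gaps"):
            compute_threshold(season_series(np.array([0.1, np.nan])))


class TestCumulativeAnomaly:
    def test_series_at_threshold_gives_zero_sums(self):
        series = season_series(np.full(10, 0.12))
        np.testing.assert_allclose(cumulative_anomaly(series, 0.12).to_numpy(), 0.0)

    def test_below_threshold_strictly_decreasing(self):
        series = season_series(np.full(10, 0.08))
        sums = cumulative_anomaly(series, 0.12).to_numpy()
        assert (np.diff(sums) < 0).all()

    def test_hand_computed_values(self):
        series = season_series(np.array([0.1, 0.1, 0.3, 0.3, 0.1]))
        sums = cumulative_anomaly(series, 0.12).to_numpy()
        np.testing.assert_allclose(sums, [-0.02, -0.04, 0.14, 0.32, 0.30], atol=1e-12)


class TestDetect:
    def plateau_window(self):
        values = np.full(30, 0.10)
        values[12:19] = 0.30
        return season_series(values)

    def test_hand_traced_plateau_example(self):
        m = detect_phenology(self.plateau_window(), 0.12, "2019/2020")
        assert (m.initiation, m.peak, m.termination) == (12, 12, 19)
        assert m.duration == 7
        assert m.detected and not m.flags

    def test_all_below_threshold_is_no_bloom_not_error(self):
        m = detect_phenology(season_series(np.full(30, 0.05)), 0.12)
        assert not m.detected
        assert "no-bloom-detected" in m.flags
        assert m.initiation is None

    def test_entirely_above_threshold_flagged(self):
        m = detect_phenology(season_series(np.full(30, 0.5)), 0.12)
        assert m.detected and m.initiation == 0
        assert "starts-above-threshold" in m.flags

    def test_never_dropping_after_peak_terminates_at_window_end(self):
        values = np.linspace(0.05, 0.5, 30)
        m = detect_phenology(season_series(values), 0.12)
        assert m.termination == 29
        assert "terminates-at-window-end" in m.flags

    def test_duration_identity(self):
        m = detect_phenology(self.plateau_window(), 0.12)
        assert m.duration == m.termination - m.initiation

    def test_cumulative_sum_gradient_equals_direct_crossings(self):
        # sign changes of the cumsum gradient are threshold crossings
        rng = np.random.default_rng(5)
        values = 0.1 * rng.lognormal(0, 0.4, 60)
        series = season_series(values)
        threshold = 0.12
        grad = np.diff(np.concatenate([[0.0], cumulative_anomaly(series, threshold).to_numpy()]))
        m = detect_phenology(series, threshold)
        above = values > threshold
        assert m.initiation == int(np.argmax(grad > 0)) == int(np.argmax(above))
        after_peak = (np.arange(60) > m.peak) & (grad < 0)
        if "terminates-at-window-end" not in m.flags:
            assert m.termination == int(np.argmax(after_peak))
        else:
            assert not after_peak.any() and m.termination == 59

    def test_noiseless_generator_truth_recovered_exactly(self):
        bloom = BloomTruth(39, 51, 42, amplitude=0.2, baseline=0.1, season_label="1998")
        series, _ = make_chl_series(3, 0.1, [bloom], 0.0, 0.0, seed=0, start_year=1998)
        threshold, metrics = run_phenology(series)
        detected = [m for m in metrics if m.detected]
        assert len(detected) == 1
        m = detected[0]
        assert m.initiation_date == series.index[39]
        assert m.termination_date == series.index[51]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        pct_lo=st.floats(0.02, 0.2),
        pct_delta=st.floats(0.01, 0.4),
        seed=st.integers(0, 100),
    )
    def test_raising_threshold_never_earlier_init_nor_later_term(
        self, pct_lo, pct_delta, seed
    ):
        rng = np.random.default_rng(seed)
        values = 0.1 * rng.lognormal(0, 0.5, 46)
        series = season_series(values)
        lo = compute_threshold(series, PhenoConfig(threshold_percent=pct_lo))
        hi = compute_threshold(
            series, PhenoConfig(threshold_percent=min(pct_lo + pct_delta, 0.99))
        )
        m_lo = detect_phenology(series, lo)
        m_hi = detect_phenology(series, hi)
        if m_hi.detected and m_lo.detected:
            assert m_hi.initiation >= m_lo.initiation
            if (
                "terminates-at-window-end" not in m_lo.flags
                and "terminates-at-window-end" not in m_hi.flags
                and m_hi.peak == m_lo.peak
            ):
                assert m_hi.termination <= m_lo.termination


class TestSeasonWindows:
    def test_three_full_years_give_two_complete_windows(self):
        series = pd.Series(0.1, index=eight_day_dates(2000, 3))
        complete = [w for w in season_windows(series) if w.complete]
        assert [w.label for w in complete] == ["2000/2001", "2001/2002"]

    def test_windows_only_contain_october_to_may_steps(self):
        series = pd.Series(0.1, index=eight_day_dates(2000, 3))
        for w in season_windows(series):
            months = w.series.index.month
            assert set(months) <= {10, 11, 12, 1, 2, 3, 4, 5}

    def test_labels_monotone_increasing(self):
        series = pd.Series(0.1, index=eight_day_dates(2000, 6))
        labels = [w.label for w in season_windows(series)]
        assert labels == sorted(labels)

    def test_partial_first_season_flagged_incomplete(self):
        # record starting in January: the preceding Oct-May window is partial
        series = pd.Series(0.1, index=eight_day_dates(2000, 3))
        windows = season_windows(series)
        assert windows[0].label == "1999/2000"
        assert not windows[0].complete


class TestRecovery:
    def test_study_conditions_recover_planted_timings(self):
        hits_i = hits_t = total = 0
        for seed in range(20):
            series, truths = make_bloom_study_series(seed)
            _thr, metrics = run_phenology(fill_gaps_linear(series))
            by_season = {m.season: m for m in metrics}
            for b in truths:
                y = int(b.season_label)
                m = by_season.get(f"{y}/{y + 1}")
                total += 1
                if m is None or not m.detected:
                    continue
                hits_i += abs((m.initiation_date - series.index[b.initiation_index]).days) <= 8
                hits_t += abs((m.termination_date - series.index[b.termination_index]).days) <= 8
        assert hits_i / total >= 0.95
        assert hits_t / total >= 0.95


class TestBoxScan:
    def make_uniform_field(self, grid, n_times=2, value=0.2):
        times = pd.date_range("2019-11-01", periods=n_times, freq="8D")
        values = np.full((n_times,) + grid.shape, value)
        return GeoField(grid=grid, times=times, values=values)

    def test_position_count_closed_form(self, one_degree_grid):
        field = self.make_uniform_field(one_degree_grid)
        domain = Region(-40.0, -15.0, 30.0, 80.0)
        result = box_scan(field, domain, box_size=5.0, stride=1.0)
        assert result.n_positions == 21 * 46 == 966

    def test_domain_equal_to_box_gives_one_position(self, one_degree_grid):
        field = self.make_uniform_field(one_degree_grid)
        result = box_scan(field, Region(-30, -25, 50, 55), box_size=5.0)
        assert result.n_positions == 1

    def test_uniform_field_gives_identical_series_everywhere(self, one_degree_grid):
        field = self.make_uniform_field(one_degree_grid, value=0.37)
        result = box_scan(field, Region(-33, -25, 50, 58), box_size=5.0, stride=2.0)
        for series in result.series.values():
            np.testing.assert_allclose(series.to_numpy(), 0.37)

    def test_box_larger_than_domain_rejected(self, one_degree_grid):
        field = self.make_uniform_field(one_degree_grid)
        with pytest.raises(ValueError, match="larger"):
            box_scan(field, Region(-28, -25, 50, 55), box_size=5.0)
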