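import numpy as np
import pytest

import sarcopaint as sp
from sarcopaint.bands import BandFit, EpitopeMeasurement
from sarcopaint.errors import GridMismatchError, ValidationError
from sarcopaint.geometry import AxialProfile


def measurement(mid, zid, label, half):
    dummy = dict(sigma_nm=15.0, amplitude=100.0, offset=0.0,
                 center_se_nm=0.5, n_localizations=300)
    return EpitopeMeasurement(
        myofibril_id=mid, zdisc_id=zid, epitope_label=label,
        left_band=BandFit(center_nm=-half, **dummy),
        right_band=BandFit(center_nm=half, **dummy))


class TestSeries:
    def test_values_pooled_in_order(self):
        ms = [measurement(0, i, "a", v) for i, v in enumerate([98, 99, 97])]
        np.testing.assert_allclose(
            sp.half_distance_series(ms, "a"), [98, 99, 97])

    def test_empty_input_empty_series(self):
        assert len(sp.half_distance_series([], "a")) == 0

    def test_mixed_labels_filtered(self):
        ms = [measurement(0, 0, "a", 98), measurement(0, 0, "b", 50),
              measurement(0, 1, "a", 99)]
        np.testing.assert_allclose(sp.half_distance_series(ms, "b"), [50])

    def test_unknown_label_lists_known(self):
        ms = [measurement(0, 0, "a", 98)]
        with pytest.raises(ValidationError, match="'c'.*a"):
            sp.half_distance_series(ms, "c")


class TestBootstrap:
    def test_constant_data_zero_width(self):
        res = sp.bootstrap_mean([7.0] * 20, seed=1)
        assert res.mean_nm == res.ci_low_nm == res.ci_high_nm == 7.0

    def test_default_replicates_and_determinism(self):
        vals = list(np.random.default_rng(5).normal(100, 5, 40))
        a = sp.bootstrap_mean(vals, seed=9)
        b = sp.bootstrap_mean(vals, seed=9)
        assert a.n_replicates == 1000
        assert (a.mean_nm, a.ci_low_nm, a.ci_high_nm) == \
            (b.mean_nm, b.ci_low_nm, b.ci_high_nm)

    def test_interval_brackets_mean(self):
        vals = list(np.random.default_rng(2).normal(100, 5, 50))
        res = sp.bootstrap_mean(vals, seed=0)
        assert res.ci_low_nm <= res.mean_nm <= res.ci_high_nm

    def test_ci_width_matches_analytic_standard_error(self):
        """Mean bootstrap CI width over many draws approximates the
        normal-theory 2 * 1.96 * sigma / sqrt(n)."""
        widths = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vals = rng.normal(100, 5, 50)
            res = sp.bootstrap_mean(vals, n_replicates=500, seed=seed)
            widths.append(res.ci_high_nm - res.ci_low_nm)
        analytic = 2 * 1.96 * 5 / np.sqrt(50)
        assert abs(np.mean(widths) - analytic) / analytic < 0.35

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            res = sp.bootstrap_mean([3.0], seed=0)
        assert res.mean_nm == 3.0
        assert res.ci_low_nm == res.ci_high_nm == 3.0


class TestOrdering:
    def test_unanimous(self):
        ms = []
        for i in range(10):
            ms.append(measurement(0, i, "a", 90.0))
            ms.append(measurement(0, i, "b", 95.0))
        res = sp.ordering_fraction(ms, "a", "b")
        assert (res.n_closer, res.n_total) == (10, 10)
        assert res.mean_offset_nm == pytest.approx(5.0)

    def test_ties_count_as_not_closer(self):
        ms = []
        for i in range(5):
            ms.append(measurement(0, i, "a", 90.0))
            ms.append(measurement(0, i, "b", 90.0))
        with pytest.warns(UserWarning, match="ties"):
            res = sp.ordering_fraction(ms, "a", "b")
        assert res.n_closer == 0
        assert res.mean_offset_nm == 0.0

    def test_constructed_42_of_45(self):
        rng = np.random.default_rng(0)
        ms = []
        for i in range(45):
            delta = 8.0 if i < 42 else -8.0
            a = 90 + rng.normal(0, 1)
            ms.append(measurement(0, i, "a", a))
            ms.append(measurement(0, i, "b", a + delta))
        res = sp.ordering_fraction(ms, "a", "b")
        assert (res.n_closer, res.n_total) == (42, 45)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        ms = []
        for i in range(30):
            ms.append(measurement(0, i, "a", 90 + rng.normal(0, 4)))
            ms.append(measurement(0, i, "b", 92 + rng.normal(0, 4)))
        ab = sp.ordering_fraction(ms, "a", "b")
        ba = sp.ordering_fraction(ms, "b", "a")
        assert ba.n_closer == ab.n_total - ab.n_closer - ab.n_ties
        assert ba.mean_offset_nm == pytest.approx(-ab.mean_offset_nm)

    def test_no_matched_zdiscs_errors(self):
        ms = [measurement(0, 0, "a", 90), measurement(0, 1, "b", 95)]
        with pytest.raises(ValidationError):
            sp.ordering_fraction(ms, "a", "b")


class TestCompositeProfiles:
    def _window(self, center, peak_offset, bin_nm=13.0, half=10):
        edges = center + np.arange(-half, half + 1) * bin_nm
        counts = np.zeros(2 * half)
        mid = 0.5 * (edges[:-1] + edges[1:])
        counts[np.argmin(np.abs(mid - (center + peak_offset)))] = 50
        return AxialProfile(edges, counts, bin_nm)

    def test_identical_windows_double(self):
        p = self._window(0.0, 32.5)
        total = sp.align_and_sum_profiles([p, p], [0.0, 0.0])
        np.testing.assert_allclose(total.counts, 2 * p.counts)

    def test_recentering_aligns_shifted_windows(self):
        p1 = self._window(1000.0, 32.5)
        p2 = self._window(4500.0, 32.5)
        total = sp.align_and_sum_profiles([p1, p2], [1000.0, 4500.0])
        assert total.total == pytest.approx(100)
        assert np.count_nonzero(total.counts) == 1

    def test_mirror_windows_symmetric_sum(self):
        pos = self._window(0.0, 32.5)
        neg = self._window(0.0, -32.5)
        total = sp.align_and_sum_profiles([pos, neg], [0.0, 0.0])
        np.testing.assert_allclose(total.counts, total.counts[::-1])

    def test_count_conservation(self):
        ps = [self._window(c, 32.5) for c in (0.0, 500.0, 1000.0)]
        total = sp.align_and_sum_profiles(ps, [0.0, 500.0, 1000.0])
        assert total.total == pytest.approx(sum(p.total for p in ps))

    def test_inconsistent_grids_error(self):
        p1 = self._window(0.0, 32.5)
        p2 = AxialProfile(np.arange(-130, 143, 13.0),
                          np.zeros(20), 13.0)
        with pytest.raises(GridMismatchError):
            sp.align_and_sum_profiles([p1, p2], [0.0, 6.5])


class TestDistanceVsLength:
    def _dataset(self, slope, rng, n=40):
        ms, lengths = [], {}
        for i in range(n):
            L = rng.uniform(3200, 3800)
            sep = 196.0 + slope * L + rng.normal(0, 2)
            ms.append(measurement(0, i, "a", sep / 2))
            lengths[(0, i)] = L
        return ms, lengths

    def test_constant_separation_zero_slope(self, rng):
        ms, lengths = self._dataset(0.0, rng)
        fit = sp.distance_vs_length(ms, lengths, "a")
        assert abs(fit.slope) <= 2 * fit.slope_se

    def test_injected_slope_recovered(self, rng):
        ms, lengths = self._dataset(0.02, rng)
        fit = sp.distance_vs_length(ms, lengths, "a")
        assert abs(fit.slope - 0.02) <= 2 * fit.slope_se

    def test_slope_matches_closed_form(self, rng):
        ms, lengths = self._dataset(0.01, rng)
        fit = sp.distance_vs_length(ms, lengths, "a")
        x = fit.lengths_nm
        y = fit.separations_nm
        beta = np.sum((x - x.mean()) * (y - y.mean())) / \
            np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(beta, abs=1e-12)

    def test_degenerate_variance_errors(self):
        ms = [measurement(0, i, "a", 98) for i in range(5)]
        lengths = {(0, i): 3500.0 for i in range(5)}
        with pytest.raises(ValidationError):
            sp.distance_vs_length(ms, lengths, "a")
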