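import numpy as np
import pytest

import sarcopaint as sp
from sarcopaint.bands import BandParams, SkippedZDisc, refine_band
from sarcopaint.errors import BandFitError
from sarcopaint.geometry import AxialProfile, window_profile

from conftest import make_table


def hist_profile(samples, bin_nm=13.0, span=(-300.0, 300.0)):
    edges = np.arange(span[0], span[1] + bin_nm, bin_nm)
    counts, _ = np.histogram(samples, bins=edges)
    return AxialProfile(bin_edges=edges, counts=counts, bin_size_nm=bin_nm)


def grid_fit_oracle(u, y, mu_range, n_zoom=5, grid=25):
    """Independent Gaussian+baseline fit: nested grid over (mu, sigma)
    with (A, c) solved by linear least squares at each node."""
    mu_lo, mu_hi = mu_range
    sg_lo, sg_hi = 3.0, 60.0
    best = None
    for _ in range(n_zoom):
        for mu in np.linspace(mu_lo, mu_hi, grid):
            for sg in np.linspace(sg_lo, sg_hi, grid):
                g = np.exp(-((u - mu) ** 2) / (2 * sg ** 2))
                design = np.column_stack([g, np.ones_like(u)])
                coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                sse = np.sum((design @ coef - y) ** 2)
                if best is None or sse < best[0]:
                    best = (sse, mu, sg)
        _, mu_c, sg_c = best
        mu_half = (mu_hi - mu_lo) / grid
        sg_half = (sg_hi - sg_lo) / grid
        mu_lo, mu_hi = mu_c - mu_half, mu_c + mu_half
        sg_lo, sg_hi = max(1.0, sg_c - sg_half), sg_c + sg_half
    return best[1]


class TestSmoothing:
    def test_delta_reproduces_kernel_shape(self):
        edges = np.arange(0, 520, 13.0)
        counts = np.zeros(len(edges) - 1)
        counts[20] = 500
        prof = AxialProfile(edges, counts, 13.0)
        sm = sp.smooth_profile(prof, 25.0)
        assert np.argmax(sm.counts) == 20
        assert sm.total == pytest.approx(500, rel=1e-6)
        # Gaussian shape: symmetric around the delta bin
        np.testing.assert_allclose(sm.counts[15:20], sm.counts[25:20:-1],
                                   rtol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_conserves_total_counts(self, seed):
        rng = np.random.default_rng(seed)
        prof = hist_profile(rng.normal(0, 80, 3000))
        sm = sp.smooth_profile(prof, 25.0)
        assert abs(sm.total - prof.total) / prof.total <= 1e-6

    def test_undersmoothing_warns(self):
        prof = hist_profile(np.zeros(10))
        with pytest.warns(UserWarning, match="under-smoothing"):
            sp.smooth_profile(prof, 5.0)


class TestRoughBands:
    def _doublet(self, c1, c2, rng, sigma=15.0, n=2000):
        return hist_profile(np.concatenate([
            rng.normal(c1, sigma, n), rng.normal(c2, sigma, n)]))

    def test_two_well_separated_bumps(self, rng):
        sm = sp.smooth_profile(self._doublet(-50, 50, rng), 25.0)
        pos = sp.find_rough_bands(sm, BandParams())
        assert len(pos) == 2
        assert abs(pos[0] + 50) <= 13.0 and abs(pos[1] - 50) <= 13.0

    def test_flat_profile_empty(self):
        prof = AxialProfile(np.arange(0, 130, 13.0), np.zeros(9), 13.0)
        assert len(sp.find_rough_bands(prof, BandParams())) == 0

    def test_close_doublet_merges(self, rng):
        sm = sp.smooth_profile(self._doublet(-50, -45, rng), 25.0)
        pos = sp.find_rough_bands(sm, BandParams(min_separation_nm=30.0))
        assert len(pos) == 1


class TestRefineBand:
    def test_center_matches_sample_mean(self, rng):
        samples = rng.normal(100.0, 15.0, 2000)
        prof = hist_profile(samples, span=(-100, 300))
        fit = refine_band(prof, 100.0, BandParams())
        assert abs(fit.center_nm - samples.mean()) <= 1.0

    def test_symmetric_histogram_centered(self):
        edges = np.arange(-52.0, 53.0, 13.0)  # centers -45.5 .. 45.5
        counts = np.array([0, 0, 10, 40, 40, 10, 0, 0], dtype=float)
        # counts are mirror-symmetric around u0 = 0 (between the tall bins)
        prof = AxialProfile(edges, counts, 13.0)
        fit = refine_band(prof, 0.0, BandParams())
        assert fit.center_nm == pytest.approx(0.0, abs=1e-6)

    def test_too_few_nonzero_bins_fails(self):
        edges = np.arange(-52.0, 53.0, 13.0)
        counts = np.array([0, 0, 0, 40, 40, 0, 0, 0], dtype=float)
        prof = AxialProfile(edges, counts, 13.0)
        with pytest.raises(BandFitError):
            refine_band(prof, 0.0, BandParams())

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(-30, 30)
        sigma = rng.uniform(10, 20)
        n = rng.integers(500, 3000)
        samples = np.concatenate([rng.normal(mu, sigma, n),
                                  rng.uniform(-300, 300, n // 10)])
        prof = hist_profile(samples)
        params = BandParams(fit_half_nm=45.0)
        fit = refine_band(prof, float(mu), params)
        in_win = np.abs(prof.centers - mu) <= params.fit_half_nm
        oracle_mu = grid_fit_oracle(prof.centers[in_win],
                                    prof.counts[in_win].astype(float),
                                    (mu - 45.0, mu + 45.0))
        assert abs(fit.center_nm - oracle_mu) <= 0.2


class TestExtraction:
    def _one_zdisc_table(self, rng, offsets=(100.0,), n=400, sigma=12.0):
        parts = []
        for off in offsets:
            for s in (-1, 1):
                parts.append(rng.normal(s * off, sigma, n))
        x_nm = np.concatenate(parts)
        return make_table(x_nm / 130.0, np.zeros(len(x_nm)))

    def test_half_distance_arithmetic(self, rng):
        t = self._one_zdisc_table(rng, offsets=(100.0,))
        z = sp.ZDiscSet(np.array([0.0]))
        ms, skips = sp.extract_epitope_pairs(t, z, BandParams(),
                                             ("epi",))
        assert len(ms) == 1 and not skips
        m = ms[0]
        assert m.separation_nm == pytest.approx(2 * m.half_distance_nm)
        assert abs(m.half_distance_nm - 100.0) < 3.0
        assert m.left_band.center_nm < 0 < m.right_band.center_nm

    def test_inner_outer_assignment_in_four_band_stain(self, rng):
        t = self._one_zdisc_table(rng, offsets=(50.0, 98.0))
        z = sp.ZDiscSet(np.array([0.0]))
        ms, _ = sp.extract_epitope_pairs(
            t, z, BandParams(), ("inner", "outer"))
        by_label = {m.epitope_label: m.half_distance_nm for m in ms}
        assert abs(by_label["inner"] - 50.0) < 4.0
        assert abs(by_label["outer"] - 98.0) < 4.0
        assert by_label["inner"] < by_label["outer"]

    def test_row_permutation_invariance(self, rng):
        t = self._one_zdisc_table(rng, offsets=(50.0, 98.0))
        z = sp.ZDiscSet(np.array([0.0]))
        ms1, _ = sp.extract_epitope_pairs(t, z, BandParams(),
                                          ("inner", "outer"))
        perm = rng.permutation(len(t))
        ms2, _ = sp.extract_epitope_pairs(t.select(perm), z, BandParams(),
                                          ("inner", "outer"))
        for a, b in zip(ms1, ms2):
            assert a.half_distance_nm == pytest.approx(b.half_distance_nm,
                                                       abs=1e-9)

    def test_missing_band_skips_with_reason(self, rng):
        # only one band on one side: cannot form a pair
        x_nm = rng.normal(100.0, 12.0, 400)
        t = make_table(x_nm / 130.0, np.zeros(len(x_nm)))
        z = sp.ZDiscSet(np.array([0.0]))
        ms, skips = sp.extract_epitope_pairs(t, z, BandParams(), ("epi",))
        assert not ms
        assert skips == [SkippedZDisc(0, "missing_band")]


class TestWindowProfile:
    def test_windows_share_relative_grid(self):
        p1 = window_profile(np.array([10.0]), 1000.0, 600.0, 13.0)
        p2 = window_profile(np.array([10.0]), 4500.0, 600.0, 13.0)
        np.testing.assert_allclose(p1.bin_edges - 1000.0,
                                   p2.bin_edges - 4500.0, atol=1e-9)
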