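"""Space-use tests: surface normalization toys, multinomial sampling, kernel
UDs, isopleths, PHR identities against brute-force oracles, and overlap
summaries."""

import numpy as np
import pytest
from scipy.stats import chi2

from redback.spaceuse import (
    Raster,
    core_isopleth,
    kernel_ud,
    overlap_analysis,
    overlap_summary,
    phr,
    sample_use_points,
    use_surface,
)


@pytest.fixture(scope="module")
def wide_raster():
    return Raster.from_bounds(-10, 10, -10, 10, 0.1)


class TestUseSurface:
    def test_single_cell_gets_all_mass(self):
        r = Raster(x0=0, y0=0, cell=1.0, nx=1, ny=1)
        s = use_surface((0.5, 0.5), 1.0, r)
        assert s.p.shape == (1, 1) and s.p[0, 0] == 1.0

    def test_equidistant_cells_split_mass(self):
        r = Raster(x0=0, y0=0, cell=1.0, nx=2, ny=1)
        for kernel in ("halfnormal", "negexp"):
            s = use_surface((1.0, 0.5), 2.0, r, kernel=kernel)
            np.testing.assert_allclose(s.p, [[0.5, 0.5]])

    def test_three_cell_hand_computation(self):
        # 1-D toy: distances {0, 1, 2} m, sigma 1, half-normal kernel ->
        # weights {1, e^-0.5, e^-2}, normalized {0.576, 0.349, 0.0779}
        r = Raster(x0=0, y0=0, cell=1.0, nx=3, ny=1)
        s = use_surface((0.5, 0.5), 1.0, r)
        w = np.array([1.0, np.exp(-0.5), np.exp(-2.0)])
        np.testing.assert_allclose(s.p[0], w / w.sum(), atol=1e-6)
        assert s.p[0, 0] == pytest.approx(0.574, abs=1e-3)
        assert s.p[0, 1] == pytest.approx(0.348, abs=1e-3)
        assert s.p[0, 2] == pytest.approx(0.0777, abs=1e-3)

    def test_normalized_and_peaked_at_ac(self, wide_raster):
        s = use_surface((1.3, -2.7), 1.5, wide_raster)
        assert s.p.sum() == pytest.approx(1.0, abs=1e-9)
        iy, ix = np.unravel_index(np.argmax(s.p), s.p.shape)
        assert wide_raster.xs[ix] == pytest.approx(1.3, abs=0.06)
        assert wide_raster.ys[iy] == pytest.approx(-2.7, abs=0.06)

    def test_margin_rule_enforced_on_request(self):
        r = Raster.from_bounds(-1, 1, -1, 1, 0.1)
        with pytest.raises(ValueError, match="margin"):
            use_surface((0, 0), 2.0, r, require_margin=True)


class TestSamplePoints:
    def test_point_mass_surface_puts_all_points_in_cell(self):
        r = Raster(x0=0, y0=0, cell=1.0, nx=3, ny=1)
        s = use_surface((0.5, 0.5), 1e-6, r)
        pts = sample_use_points(s, 200, seed=0)
        assert ((pts[:, 0] >= 0) & (pts[:, 0] <= 1)).all()

    def test_uniform_two_cell_binomial_bounds(self):
        r = Raster(x0=0, y0=0, cell=1.0, nx=2, ny=1)
        s = use_surface((1.0, 0.5), 5.0, r)
        pts = sample_use_points(s, 1000, seed=1)
        n_left = (pts[:, 0] < 1.0).sum()
        # 99% binomial bounds around 500
        assert abs(n_left - 500) < 2.58 * np.sqrt(1000 * 0.25)

    def test_multinomial_frequencies_chi_square(self):
        """Empirical cell frequencies on the 3-cell toy stay below the 0.99
        chi-square quantile in at least 95% of seeded runs."""
        r = Raster(x0=0, y0=0, cell=1.0, nx=3, ny=1)
        s = use_surface((0.5, 0.5), 1.0, r)
        crit = chi2.ppf(0.99, df=2)
        n_ok = 0
        for seed in range(40):
            pts = sample_use_points(s, 1000, seed=seed)
            counts = np.array([((pts[:, 0] >= k) & (pts[:, 0] < k + 1)).sum() for k in range(3)])
            exp = s.p[0] * 1000
            stat = ((counts - exp) ** 2 / exp).sum()
            n_ok += stat < crit
        assert n_ok >= 38  # 95% of 40

    def test_nonpositive_count_rejected(self):
        r = Raster(x0=0, y0=0, cell=1.0, nx=2, ny=1)
        s = use_surface((1.0, 0.5), 1.0, r)
        with pytest.raises(ValueError):
            sample_use_points(s, 0)


class TestKernelUD:
    def test_mode_at_center_of_symmetric_points(self, wide_raster):
        rng = np.random.default_rng(2)
        pts = rng.normal([2.0, -1.0], 0.8, (2000, 2))
        pts = np.vstack([pts, 2 * np.array([2.0, -1.0]) - pts])  # exact symmetry
        ud = kernel_ud(pts, wide_raster)
        iy, ix = np.unravel_index(np.argmax(ud.p), ud.p.shape)
        assert wide_raster.xs[ix] == pytest.approx(2.0, abs=0.15)
        assert wide_raster.ys[iy] == pytest.approx(-1.0, abs=0.15)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1.0, (500, 2))
        r1 = Raster.from_bounds(-6, 6, -6, 6, 0.1)
        r2 = Raster.from_bounds(-1, 11, -6, 6, 0.1)
        ud1 = kernel_ud(pts, r1)
        ud2 = kernel_ud(pts + [5.0, 0.0], r2)
        np.testing.assert_allclose(ud1.p, ud2.p, atol=1e-12)

    def test_gaussian_mass_inside_true_half_contour(self, wide_raster):
        """Large-n points from an isotropic Gaussian: UD mass inside the
        analytic 50% circle (radius sigma*sqrt(2 ln 2)) is ~0.5."""
        rng = np.random.default_rng(4)
        sigma = 1.5
        pts = rng.normal(0, sigma, (20_000, 2))
        ud = kernel_ud(pts, wide_raster)
        gx, gy = np.meshgrid(wide_raster.xs, wide_raster.ys)
        inside = gx**2 + gy**2 <= 2 * np.log(2) * sigma**2
        assert ud.p[inside].sum() == pytest.approx(0.5, abs=0.03)

    def test_identical_points_fall_back_with_warning(self, wide_raster):
        pts = np.tile([[1.0, 1.0]], (10, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            ud = kernel_ud(pts, wide_raster)
        assert np.isfinite(ud.p).all() and ud.p.sum() == pytest.approx(1.0)

    def test_too_few_points_rejected(self, wide_raster):
        with pytest.raises(ValueError):
            kernel_ud(np.zeros((3, 2)), wide_raster)


class TestCoreIsopleth:
    def test_level_near_one_selects_all_nonzero_cells(self):
        r = Raster(x0=0, y0=0, cell=1.0, nx=4, ny=1)
        s = use_surface((0.5, 0.5), 1.0, r)
        mask = core_isopleth(s, 0.999999)
        assert mask.sum() == (s.p > 0).sum()

    def test_uniform_four_cells_level_half(self):
        from redback.spaceuse import UDGrid

        r = Raster(x0=0, y0=0, cell=1.0, nx=4, ny=1)
        ud = UDGrid(raster=r, p=np.full((1, 4), 0.25), bandwidth=1.0)
        assert core_isopleth(ud, 0.5).sum() == 2

    def test_gaussian_core_area_matches_analytic_circle(self):
        # smallest region with half the mass of an isotropic Gaussian has
        # area pi * 2 ln 2 * sigma^2
        sigma = 1.5
        r = Raster.from_bounds(-10, 10, -10, 10, 0.1)
        s = use_surface((0, 0), sigma, r)
        mask = core_isopleth(s, 0.5)
        analytic = np.pi * 2 * np.log(2) * sigma**2
        assert mask.sum() * r.cell_area == pytest.approx(analytic, rel=0.02)

    def test_shrinks_with_sigma(self):
        r = Raster.from_bounds(-10, 10, -10, 10, 0.1)
        areas = [
            core_isopleth(use_surface((0, 0), s, r), 0.5).sum() for s in (0.5, 1.0, 2.0)
        ]
        assert areas[0] < areas[1] < areas[2]

    def test_invalid_level_rejected(self):
        r = Raster(x0=0, y0=0, cell=1.0, nx=2, ny=1)
        s = use_surface((1, 0.5), 1.0, r)
        for level in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                core_isopleth(s, level)


class TestPHR:
    def test_self_overlap_at_half_core(self, wide_raster):
        s = use_surface((0, 0), 1.5, wide_raster)
        pts = sample_use_points(s, 1000, seed=5)
        ud = kernel_ud(pts, wide_raster)
        core = core_isopleth(ud, 0.5)
        assert phr(ud, core) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("level", [0.3, 0.5, 0.7, 0.9])
    def test_self_overlap_equals_level_for_any_level(self, wide_raster, level):
        s = use_surface((0.5, -0.5), 1.2, wide_raster)
        assert phr(s, core_isopleth(s, level)) == pytest.approx(level, abs=0.01)

    def test_distant_individuals_do_not_overlap(self, wide_raster):
        s1 = use_surface((-7, -7), 1.0, wide_raster)
        s2 = use_surface((7, 7), 1.0, wide_raster)
        assert phr(s2, core_isopleth(s1, 0.5)) < 1e-6

    def test_matches_monte_carlo_integration_oracle(self, wide_raster):
        """Two ACs 2 m apart, sigma 1: grid PHR equals a 10^6-sample
        Monte-Carlo integral of j's distribution over i's core within 0.01."""
        s_i = use_surface((0, 0), 1.0, wide_raster)
        s_j = use_surface((2, 0), 1.0, wide_raster)
        core = core_isopleth(s_i, 0.5)
        val = phr(s_j, core)
        rng = np.random.default_rng(6)
        samples = rng.normal((2, 0), 1.0, (1_000_000, 2))
        row, col = wide_raster.cell_of(samples)
        oracle = core[row, col].mean()
        assert val == pytest.approx(oracle, abs=0.01)

    def test_raster_mismatch_rejected(self, wide_raster):
        small = Raster(x0=0, y0=0, cell=1.0, nx=2, ny=1)
        s = use_surface((1, 0.5), 1.0, small)
        core = np.zeros(wide_raster.shape, dtype=bool)
        with pytest.raises(ValueError):
            phr(s, core)


class TestOverlapSummary:
    def _toy(self, acs, sigma=1.0, cell=0.2):
        r = Raster.from_bounds(-8, 12, -8, 12, cell)
        uds = [use_surface(tuple(a), sigma, r) for a in acs]
        cores = [core_isopleth(u, 0.5) for u in uds]
        return uds, cores, np.asarray(acs, dtype=float)

    def test_identical_acs_counted_and_warned(self):
        uds, cores, acs = self._toy([(0, 0), (0, 0)])
        with pytest.warns(UserWarning, match="coincident"):
            s = overlap_summary(uds, cores, acs)
        assert list(s.overlap_count) == [1, 1] and list(s.nn_dist) == [0.0, 0.0]

    def test_grid_neighbors_nn_distance(self):
        acs = [(x, y) for x in range(3) for y in range(3)]
        uds, cores, acs = self._toy(acs, sigma=0.5)
        s = overlap_summary(uds, cores, acs)
        assert np.allclose(s.nn_dist, 1.0)

    def test_counts_match_bruteforce_enumeration(self):
        """5-individual toy: overlap counts equal exhaustive pairwise core
        mask intersection."""
        acs = [(0, 0), (1.5, 0), (4, 0), (0, 1.2), (8, 8)]
        uds, cores, acs = self._toy(acs)
        s = overlap_summary(uds, cores, acs)
        n = len(acs)
        brute = np.zeros(n, dtype=int)
        for i in range(n):
            for j in range(n):
                if i != j and (cores[i] & cores[j]).any():
                    brute[i] += 1
        assert np.array_equal(s.overlap_count, brute)
        # PHR bounded and self-consistent
        m = s.phr_matrix
        off = m[~np.isnan(m)]
        assert ((off >= 0) & (off <= 1)).all()

    def test_single_individual_rejected(self):
        uds, cores, acs = self._toy([(0, 0)])
        with pytest.raises(ValueError):
            overlap_summary(uds, cores, acs)

    def test_pipeline_deterministic(self):
        acs = np.array([[0.0, 0.0], [1.0, 0.5], [3.0, 2.0]])
        r = Raster.from_bounds(-6, 9, -6, 8, 0.25)
        a = overlap_analysis(acs, [1.0, 1.3], r, n_points=200, seed=9)
        b = overlap_analysis(acs, [1.0, 1.3], r, n_points=200, seed=9)
        np.testing.assert_array_equal(a.mean_phr, b.mean_phr)
        np.testing.assert_array_equal(a.overlap_count, b.overlap_count)
        np.testing.assert_array_equal(a.nn_dist, b.nn_dist)
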