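"""Partial correlation, seed maps, and bilateral statistics."""

import numpy as np
import pytest

from icband import correlation as corr
from icband import preprocess, synthetic
from icband.core import LEFT, OUTSIDE, RIGHT, MovieStack, RoiMaskSet


def _residual_partial(x, y, z):
    """Independent oracle: Pearson correlation of regression residuals."""
    zc = np.c_[np.ones_like(z), z]
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


class TestPartialCorrelation:
    def test_identical_traces_with_independent_control(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        z = rng.standard_normal(1000)
        assert corr.partial_correlation(x, x.copy(), z) == pytest.approx(1.0, abs=1e-6)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(10, 100))
            g = rng.standard_normal((3, n))
            x = g[0] + 0.5 * g[2]
            y = g[1] - 0.3 * g[2]
            z = g[2]
            assert corr.partial_correlation(x, y, z) == pytest.approx(
                _residual_partial(x, y, z), abs=1e-10)

    def test_fully_mediated_dependence_vanishes(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(5000)
        x = z + 0.8 * rng.standard_normal(5000)
        y = z + 0.8 * rng.standard_normal(5000)
        # x and y share only the common component z
        assert abs(corr.partial_correlation(x, y, z)) < 0.05

    def test_constant_control_falls_back_to_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 100))
        plain = float(np.corrcoef(x, y)[0, 1])
        assert corr.partial_correlation(x, y, np.ones(100)) == pytest.approx(plain)

    def test_degenerate_inputs_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="non-constant"):
            corr.partial_correlation(x, np.ones(10), x)
        with pytest.raises(ValueError, match=r"\|r\| with control"):
            corr.partial_correlation(x, x[::-1], x)


def _toy_bilateral(n=500, seed=0):
    """Tiny two-hemisphere movie with a planted shared signal."""
    rng = np.random.default_rng(seed)
    labels = np.full((6, 12), OUTSIDE)
    labels[1:5, 1:5] = LEFT
    labels[1:5, 7:11] = RIGHT
    shared = rng.standard_normal(n)
    data = np.full((n, 6, 12), 100.0) + 0.2 * rng.standard_normal((n, 6, 12))
    data[:, labels == LEFT] += shared[:, None]
    data[:, labels == RIGHT] += shared[:, None]
    return MovieStack(data), RoiMaskSet(labels), shared


class TestGlobalBilateral:
    def test_duplicated_hemisphere_gives_unit_correlation(self):
        movie, masks, _ = _toy_bilateral()
        data = movie.data.copy()
        data[:, masks.right] = data[:, masks.left]
        r = corr.global_bilateral_correlation(MovieStack(data), masks)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_requires_outside_region(self):
        movie, masks, _ = _toy_bilateral()
        labels = masks.labels.copy()
        labels[labels == OUTSIDE] = 0
        with pytest.raises(ValueError, match="outside"):
            corr.global_bilateral_correlation(movie, RoiMaskSet(labels))

    def test_corrupted_frames_excluded(self):
        movie, masks, _ = _toy_bilateral()
        data = movie.data.copy()
        data[10] = 1e6        # wrecked frame
        shifts = np.zeros((movie.n_frames, 2))
        shifts[10] = (2.0, 2.0)
        motion = preprocess.MotionTrace(shifts)
        r_bad = corr.global_bilateral_correlation(MovieStack(data), masks)
        r_ok = corr.global_bilateral_correlation(MovieStack(data), masks, motion)
        clean = corr.global_bilateral_correlation(movie, masks)
        assert abs(r_ok - clean) < 0.01
        assert r_bad > r_ok   # the outlier frame inflates the correlation


class TestSeedMap:
    def test_seed_pixel_is_exactly_one(self):
        movie, masks, _ = _toy_bilateral()
        cmap = corr.seed_correlation_map(movie, (2, 2), masks)
        assert cmap.values[2, 2] == 1.0
        finite = cmap.values[cmap.finite_mask()]
        assert np.all((finite >= -1) & (finite <= 1))

    def test_matches_scalar_partial_correlation_everywhere(self):
        rng = np.random.default_rng(5)
        labels = np.zeros((16, 16), dtype=int)
        labels[2:14, 2:8] = LEFT
        labels[2:14, 8:14] = RIGHT
        labels[0, :] = OUTSIDE
        masks = RoiMaskSet(labels)
        movie = MovieStack(rng.standard_normal((500, 16, 16)) + 50.0)
        seed = (5, 4)
        cmap = corr.seed_correlation_map(movie, seed, masks)
        z = corr.outside_trace(movie, masks)
        x = movie.data[:, seed[0], seed[1]]
        for (i, j) in [(2, 2), (7, 9), (13, 13), (5, 4), (10, 5)]:
            if labels[i, j] in (LEFT, RIGHT):
                want = _residual_partial(x, movie.data[:, i, j], z)
                assert cmap.values[i, j] == pytest.approx(want, abs=1e-10)

    def test_out_of_roi_seed_rejected(self):
        movie, masks, _ = _toy_bilateral()
        with pytest.raises(ValueError, match="outside the analyzed ROI"):
            corr.seed_correlation_map(movie, (0, 0), masks)

    def test_contralateral_maximum_at_mirrored_band(self):
        cfg = synthetic.SyntheticSpontConfig(duration=120.0, coupling=1.0,
                                             noise_sigma=0.2, seed=17)
        movie, masks, _ = synthetic.generate_spontaneous_movie(cfg)
        seed = synthetic.tonotopic_pixel(masks, "left", 0.15)
        cmap = corr.seed_correlation_map(movie, seed, masks)
        _, loc = corr.max_symmetric_region_correlation(
            cmap, corr.symmetric_contra_roi(masks, seed))
        mirror = synthetic.tonotopic_pixel(masks, "right", 0.15)
        assert abs(loc[1] - mirror[1]) <= 3


class TestSeedGrid:
    def test_thousand_seeds_cover_field_uniformly(self):
        grid = corr.build_seed_grid((100, 100), n=1000)
        assert len(grid.seeds) >= 1000
        rows = np.unique(grid.seeds[:, 0])
        cols = np.unique(grid.seeds[:, 1])
        assert np.ptp(np.diff(rows)) <= 1 and np.ptp(np.diff(cols)) <= 1

    def test_single_seed_is_field_center(self):
        grid = corr.build_seed_grid((21, 31), n=1)
        assert grid.seeds.tolist() == [[10, 15]]

    def test_deterministic(self):
        a = corr.build_seed_grid((40, 60), 200)
        b = corr.build_seed_grid((40, 60), 200)
        assert np.array_equal(a.seeds, b.seeds)


class TestMaxRegionCorrelation:
    def _cmap(self, values, seed=(0, 0)):
        return corr.CorrelationMap(values.astype(float), seed=seed)

    def test_uniform_map_returns_value(self):
        region = np.ones((10, 10), dtype=bool)
        r, _ = corr.max_symmetric_region_correlation(self._cmap(np.full((10, 10), 0.4)),
                                                     region)
        assert r == pytest.approx(0.4)

    def test_planted_patch_found_by_bruteforce_agreement(self):
        vals = np.full((20, 20), 0.1)
        vals[7:12, 9:14] = 0.9
        region = np.ones_like(vals, dtype=bool)
        r, loc = corr.max_symmetric_region_correlation(self._cmap(vals), region)
        assert loc == (9, 11) and r == pytest.approx(0.9)

    def test_values_outside_region_ignored(self):
        vals = np.full((10, 10), 0.2)
        vals[0, 0] = 0.99
        region = np.zeros_like(vals, dtype=bool)
        region[5:9, 5:9] = True
        r, loc = corr.max_symmetric_region_correlation(self._cmap(vals), region)
        assert r == pytest.approx(0.2) and region[loc]


class TestRegionProps:
    def _map_from_mask(self, supra, seed):
        vals = np.where(supra, 0.99, 0.0)
        return corr.CorrelationMap(vals, seed=seed)

    def _masks(self, shape, hemi_area):
        labels = np.zeros(shape, dtype=int)
        labels[..., :] = 0
        rows, cols = np.nonzero(np.ones(shape))
        labels[rows[:hemi_area], cols[:hemi_area]] = LEFT
        return RoiMaskSet(labels)

    def test_disc_is_nearly_circular(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        labels = np.where(disc, LEFT, 0)
        props = corr.correlation_region_properties(
            self._map_from_mask(disc, (20, 20)), RoiMaskSet(labels))
        assert 1.0 <= props.eccentricity <= 1.1

    def test_planted_ellipse_aspect_ratio(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ell = ((yy - 30) / 20.0) ** 2 + ((xx - 30) / 5.0) ** 2 <= 1
        labels = np.where(np.ones_like(ell), LEFT, 0)
        props = corr.correlation_region_properties(
            self._map_from_mask(ell, (30, 30)), RoiMaskSet(labels))
        assert props.eccentricity == pytest.approx(4.0, rel=0.10)

    def test_proportion_is_area_ratio(self):
        supra = np.zeros((40, 40), dtype=bool)
        supra[10:20, 10:20] = True            # 100 px component
        labels = np.zeros((40, 40), dtype=int)
        labels[:25, :40] = LEFT               # 1000 px hemisphere
        props = corr.correlation_region_properties(
            self._map_from_mask(supra, (15, 15)), RoiMaskSet(labels))
        assert props.proportion == pytest.approx(0.1)


@pytest.fixture(scope="module")
def session():
    cfg = synthetic.SyntheticSpontConfig(duration=240.0, coupling=1.0, seed=23)
    movie, masks, _ = synthetic.generate_spontaneous_movie(cfg)
    return movie, masks


class TestRepresentativeSeeds:

    def test_low_single_band_mid_high_dual(self, session):
        movie, masks = session
        seeds = corr.select_representative_seeds(movie, masks)
        assert seeds["low"] is not None and seeds["mid"] is not None
        coord, _ = synthetic._tonotopic_coord(masks, "left")
        p_low = coord[seeds["low"][1]]
        p_mid = coord[seeds["mid"][1]]
        assert p_low < p_mid           # mid is more lateral
        cmap_low = corr.seed_correlation_map(movie, seeds["low"], masks)
        assert corr._band_count(cmap_low, masks.left, 0.6) == 1
        cmap_mid = corr.seed_correlation_map(movie, seeds["mid"], masks)
        assert corr._band_count(cmap_mid, masks.left, 0.6) == 2

    def test_deterministic_selection(self, session):
        movie, masks = session
        a = corr.select_representative_seeds(movie, masks)
        b = corr.select_representative_seeds(movie, masks)
        assert a == b
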