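"""Concentric region partitions, per-region histograms and concentration
profiles against brute-force per-pixel enumeration."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from haquant import (
    ConcentrationMap,
    TissueMask,
    concentric_regions,
    line_profile,
    manual_regions,
    radial_profile,
    region_histogram,
)


def disk_mask(size=48, radius=18):
    yy, xx = np.indices((size, size))
    c = (size - 1) / 2
    mask = np.hypot(yy - c, xx - c) <= radius
    return TissueMask(mask=mask, threshold=0.0, pixel_size_um=1.0)


def brute_force_boundary_distance(mask):
    """Per-pixel distance to the nearest background pixel, by enumeration."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    d = cdist(fg, bg).min(axis=1)
    out = np.zeros(mask.shape)
    out[tuple(fg.T)] = d
    return out


def make_map(values, mask, pixel_size_um=1.0):
    return ConcentrationMap(
        values=np.where(mask, values, 0.0),
        mask=mask,
        pixel_size_um=pixel_size_um,
        thickness_um=5.0,
        mode="curve",
    )


class TestConcentricRegions:
    def test_disk_two_depth_bands(self):
        tm = disk_mask()
        regions = concentric_regions(tm, k=2)
        assert regions.names == ["R1", "R2"]
        # every boundary pixel (touching background) is in region 1
        from scipy import ndimage

        eroded = ndimage.binary_erosion(tm.mask)
        boundary = tm.mask & ~eroded
        assert np.all(regions.labels[boundary] == 1)
        # regions cover the mask exactly
        assert np.array_equal(regions.labels > 0, tm.mask)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            concentric_regions(disk_mask(), k=1)

    def test_k_exceeding_distinct_distances_rejected(self):
        tiny = TissueMask(
            mask=np.pad(np.ones((1, 2), bool), 1), threshold=0.0, pixel_size_um=1.0
        )
        with pytest.raises(ValueError, match="distinct distance"):
            concentric_regions(tiny, k=4)

    def test_counts_match_brute_force_distance_oracle(self):
        tm = disk_mask(size=64, radius=25)
        regions = concentric_regions(tm, k=4)
        d = brute_force_boundary_distance(tm.mask)
        dm = d[tm.mask]
        edges = np.linspace(dm.min(), dm.max(), 5)
        for j in range(1, 5):
            lo, hi = edges[j - 1], edges[j]
            # band j = (lo, hi], closed below only for band 1
            sel = (dm > lo) & (dm <= hi) if j > 1 else (dm >= lo) & (dm <= hi)
            assert int(sel.sum()) == int((regions.labels == j).sum())

    def test_counts_sum_to_mask_area(self):
        tm = disk_mask()
        for scheme in ("concentric_depth", "concentric_centroid"):
            regions = concentric_regions(tm, k=4, scheme=scheme)
            assert (regions.labels > 0).sum() == tm.area_px

    def test_centroid_scheme_outermost_is_region_one(self):
        tm = disk_mask()
        regions = concentric_regions(tm, k=3, scheme="concentric_centroid")
        yy, xx = np.indices(tm.mask.shape)
        c = (tm.mask.shape[0] - 1) / 2
        r = np.hypot(yy - c, xx - c)
        assert r[regions.labels == 1].min() > r[regions.labels == 3].max()


class TestRegionHistogram:
    def test_constant_map_single_occupied_bin(self):
        tm = disk_mask()
        regions = concentric_regions(tm, k=2)
        cmap = make_map(0.5, tm.mask)
        bins = np.linspace(0, 1, 11)
        table = region_histogram(cmap, regions, bins)
        for name in ("R1", "R2"):
            sub = table[table.region == name]
            occupied = sub[sub["count"] > 0]
            assert len(occupied) == 1
            width = occupied.bin_right.iloc[0] - occupied.bin_left.iloc[0]
            assert np.isclose(occupied.density.iloc[0] * width, 1.0)

    def test_disjoint_constants_do_not_overlap(self):
        tm = disk_mask()
        regions = concentric_regions(tm, k=2)
        values = np.where(regions.labels == 1, 0.2, 0.8)
        cmap = make_map(values, tm.mask)
        table = region_histogram(cmap, regions, np.linspace(0, 1, 21))
        r1 = table[(table.region == "R1") & (table["count"] > 0)]
        r2 = table[(table.region == "R2") & (table["count"] > 0)]
        assert r1.bin_right.max() <= r2.bin_left.min()

    def test_counts_match_enumeration(self, rng):
        tm = disk_mask()
        regions = concentric_regions(tm, k=3)
        cmap = make_map(rng.random(tm.mask.shape), tm.mask)
        bins = np.linspace(0, 1, 9)
        table = region_histogram(cmap, regions, bins)
        for j, name in enumerate(regions.names, start=1):
            vals = cmap.values[regions.labels == j]
            expected, _ = np.histogram(vals, bins=bins)
            got = table[table.region == name]["count"].to_numpy()
            np.testing.assert_array_equal(got, expected)

    def test_densities_integrate_to_one(self, rng):
        tm = disk_mask()
        regions = concentric_regions(tm, k=2)
        cmap = make_map(rng.random(tm.mask.shape), tm.mask)
        bins = np.linspace(0, 1, 9)
        table = region_histogram(cmap, regions, bins)
        widths = table.bin_right - table.bin_left
        for name in regions.names:
            sub = table[table.region == name]
            assert np.isclose((sub.density * widths[sub.index]).sum(), 1.0)

    def test_empty_region_flagged(self):
        tm = disk_mask()
        labels = np.where(tm.mask, 1, 0)
        regions = manual_regions(labels, ["A", "B"])
        cmap = make_map(0.3, tm.mask)
        table = region_histogram(cmap, regions, np.linspace(0, 1, 5))
        sub = table[table.region == "B"]
        assert sub["empty"].all()
        assert (sub["n_pixels"] == 0).all()


class TestLineProfile:
    def test_constant_map_is_flat_with_zero_sd(self):
        mask = np.ones((20, 20), bool)
        cmap = make_map(0.3, mask)
        prof = line_profile(cmap, origin=(1.0, 10.0), direction=(1.0, 0.0), band_width_px=3)
        np.testing.assert_allclose(prof.means, 0.3, rtol=1e-12)
        np.testing.assert_allclose(prof.sds, 0.0, atol=1e-12)
        assert np.all(np.diff(prof.positions) > 0)

    def test_coordinate_ramp_increases_linearly(self):
        mask = np.ones((10, 30), bool)
        xx = np.indices(mask.shape)[1].astype(float)
        cmap = make_map(xx, mask)
        prof = line_profile(cmap, origin=(0.0, 5.0), direction=(1.0, 0.0), band_width_px=1)
        assert np.all(np.diff(prof.means) > 0)
        np.testing.assert_allclose(np.diff(prof.means), 1.0, atol=1e-9)

    def test_positions_in_micrometres(self):
        mask = np.ones((10, 10), bool)
        cmap = make_map(1.0, mask, pixel_size_um=2.5)
        prof = line_profile(cmap, origin=(0.0, 5.0), direction=(1.0, 0.0))
        np.testing.assert_allclose(np.diff(prof.positions), 2.5)

    def test_origin_outside_mask_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[5:, :] = True
        cmap = make_map(1.0, mask)
        with pytest.raises(ValueError, match="outside"):
            line_profile(cmap, origin=(1.0, 1.0), direction=(1.0, 0.0))


class TestRadialProfile:
    def test_constant_map_flat(self):
        tm = disk_mask()
        regions = concentric_regions(tm, k=3)
        prof = radial_profile(make_map(0.4, tm.mask), regions)
        np.testing.assert_allclose(prof.means, 0.4, rtol=1e-12)
        np.testing.assert_allclose(prof.sds, 0.0, atol=1e-12)

    def test_depth_decreasing_map_gives_monotone_profile(self):
        from scipy import ndimage

        tm = disk_mask()
        depth = ndimage.distance_transform_edt(tm.mask)
        values = np.where(tm.mask, 2.0 * np.exp(-depth / 10.0), 0.0)
        regions = concentric_regions(tm, k=4)
        prof = radial_profile(make_map(values, tm.mask), regions)
        assert np.all(np.diff(prof.means) < 0)

    def test_band_means_match_enumeration(self, rng):
        tm = disk_mask(size=64, radius=25)
        regions = concentric_regions(tm, k=4)
        cmap = make_map(rng.random(tm.mask.shape), tm.mask)
        prof = radial_profile(cmap, regions)
        for j in range(1, 5):
            vals = [
                cmap.values[r, c]
                for r, c in np.argwhere(regions.labels == j)
            ]
            assert np.isclose(prof.means[j - 1], np.mean(vals), rtol=1e-12)
            assert prof.n_pixels[j - 1] == len(vals)

    def test_manual_scheme_rejected(self):
        tm = disk_mask()
        labels = np.where(tm.mask, 1, 0)
        regions = manual_regions(labels, ["A"])
        with pytest.raises(ValueError, match="concentric"):
            radial_profile(make_map(1.0, tm.mask), regions)
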