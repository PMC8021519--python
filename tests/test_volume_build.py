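"""z-interpolation and channel-specific grayscale morphology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from splenvas.volume_build import (
    CHANNEL_RECIPES,
    ChannelVolume,
    ellipsoid_footprint,
    filter_channel_volume,
    flow_interpolate_z,
    grey_close_ellipsoid,
    grey_dilate_ellipsoid,
    nn_resize_z,
)


def disk_slice(cx, cy, shape=(96, 96), r=10):
    X, Y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (255.0 * ((X - cx)**2 + (Y - cy)**2 <= r * r)).astype(np.uint8)


class TestFlowInterpolate:
    def test_factor_one_identity(self):
        vol = ChannelVolume(np.random.default_rng(0).integers(
            0, 255, (16, 16, 4)).astype(np.uint8), (0.5, 0.5, 7.0), "CD34")
        out = flow_interpolate_z(vol, 1)
        assert np.array_equal(out.values, vol.values)

    def test_factor_below_one_rejected(self):
        vol = ChannelVolume(np.zeros((8, 8, 2), np.uint8), (0.5, 0.5, 7.0), "CD34")
        with pytest.raises(ValueError):
            flow_interpolate_z(vol, 0)

    def test_identical_slices_zero_flow(self):
        sl = disk_slice(48, 48)
        vol = ChannelVolume(np.stack([sl, sl], axis=2), (0.5, 0.5, 7.0), "CD34")
        out = flow_interpolate_z(vol, 7)
        assert out.values.shape[2] == 8
        for k in range(8):
            assert np.array_equal(out.values[:, :, k], sl)

    def test_translating_disk_linear_centroid(self):
        """Disk moving 14 px between slices: interpolated centroid follows
        the linear path within 1 px."""
        vol = ChannelVolume(
            np.stack([disk_slice(30, 48), disk_slice(44, 48)], axis=2),
            (0.5, 0.5, 7.0), "CD34",
        )
        out = flow_interpolate_z(vol, 7)
        assert out.values.shape[2] == 8
        assert out.spacing_um[2] == pytest.approx(1.0)
        for s in range(8):
            sl = out.values[:, :, s].astype(float)
            cx = (sl.sum(axis=1) * np.arange(sl.shape[0])).sum() / sl.sum()
            assert abs(cx - (30 + 2 * s)) <= 1.0

    def test_original_slices_bit_exact(self):
        rng = np.random.default_rng(1)
        raw = np.zeros((48, 48, 5), np.uint8)
        for k in range(5):
            raw[:, :, k] = disk_slice(14 + 4 * k, 20 + 2 * k, (48, 48), r=6)
        vol = ChannelVolume(raw, (0.5, 0.5, 7.0), "CD34")
        out = flow_interpolate_z(vol, 3)
        assert out.values.shape[2] == (5 - 1) * 3 + 1
        for k in range(5):
            assert np.array_equal(out.values[:, :, 3 * k], raw[:, :, k])

    def test_origin_keeps_slice_positions(self):
        vol = ChannelVolume(np.zeros((8, 8, 3), np.uint8), (0.5, 0.5, 14.0),
                            "CD271", origin_um=(0.0, 0.0, -3.5))
        out = flow_interpolate_z(vol, 7)
        # first original slice center must stay at z = -3.5 + 0.5*14 = 3.5
        z0 = out.origin_um[2] + 0.5 * out.spacing_um[2]
        assert z0 == pytest.approx(3.5)


class TestNnResize:
    def test_repetition_rule(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 255, (6, 6, 3)).astype(np.uint8)
        out = nn_resize_z(ChannelVolume(raw, (0.5, 0.5, 14.0), "CD20"), 2)
        assert out.values.shape[2] == 6
        for k in range(3):
            assert np.array_equal(out.values[:, :, 2 * k], raw[:, :, k])
            assert np.array_equal(out.values[:, :, 2 * k + 1], raw[:, :, k])

    def test_histogram_scales_by_factor(self):
        rng = np.random.default_rng(1)
        raw = rng.integers(0, 255, (10, 10, 4)).astype(np.uint8)
        out = nn_resize_z(ChannelVolume(raw, (0.5, 0.5, 14.0), "CD20"), 3)
        h_in = np.bincount(raw.ravel(), minlength=256)
        h_out = np.bincount(out.values.ravel(), minlength=256)
        assert np.array_equal(h_out, 3 * h_in)
        # no new values introduced
        assert set(np.unique(out.values)) <= set(np.unique(raw))


class TestMorphology:
    def test_constant_volume_unchanged(self):
        vol = ChannelVolume(np.full((24, 24, 24), 77, np.uint8),
                            (0.5, 0.5, 1.0), "SMA")
        out = filter_channel_volume(vol)
        assert np.array_equal(out.values, vol.values)

    def test_single_voxel_dilation_support(self):
        """CD271 recipe: support after dilation contains the 8-8-2 ellipsoid
        (checked against brute-force morphology on a small grid)."""
        v = np.zeros((33, 33, 33), np.float32)
        v[16, 16, 16] = 255.0
        mine = grey_dilate_ellipsoid(v, 8, 8, 2)
        fp = ellipsoid_footprint(8, 8, 2)
        ref = ndimage.maximum_filter(v, footprint=fp, mode="nearest")
        assert np.array_equal(mine, ref)
        # closing adds nothing to the (convex) dilated blob
        closed = grey_close_ellipsoid(mine, 5, 5, 5)
        ref2 = ndimage.minimum_filter(
            ndimage.maximum_filter(mine, footprint=ellipsoid_footprint(5, 5, 5),
                                   mode="nearest"),
            footprint=ellipsoid_footprint(5, 5, 5), mode="nearest")
        assert np.array_equal(closed, ref2)

    def test_cd20_untouched(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 255, (16, 16, 8)).astype(np.uint8)
        out = filter_channel_volume(
            ChannelVolume(raw, (0.5, 0.5, 14.0), "CD20"))
        assert np.array_equal(out.values, raw)

    def test_unknown_channel_fails(self):
        vol = ChannelVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1), "CD999")
        with pytest.raises(ValueError):
            filter_channel_volume(vol)

    @given(
        vol=arrays(np.uint8, (9, 8, 7), elements=st.integers(0, 255)),
        rx=st.integers(1, 3), ry=st.integers(1, 3), rz=st.integers(1, 2),
    )
    @settings(max_examples=25, deadline=None)
    def test_dilation_matches_brute_force(self, vol, rx, ry, rz):
        v = vol.astype(np.float32)
        mine = grey_dilate_ellipsoid(v, rx, ry, rz)
        ref = ndimage.maximum_filter(
            v, footprint=ellipsoid_footprint(rx, ry, rz), mode="nearest")
        assert np.array_equal(mine, ref)
        # extensive: output >= input; monotone w.r.t. a brighter volume
        assert np.all(mine >= v)
        brighter = np.minimum(v + 17.0, 255.0)
        assert np.all(grey_dilate_ellipsoid(brighter, rx, ry, rz) >= mine)

    @given(
        vol=arrays(np.uint8, (8, 8, 6), elements=st.integers(0, 255)),
        rx=st.integers(1, 3), rz=st.integers(1, 2),
    )
    @settings(max_examples=20, deadline=None)
    def test_closing_matches_brute_force(self, vol, rx, rz):
        v = vol.astype(np.float32)
        fp = ellipsoid_footprint(rx, rx, rz)
        mine = grey_close_ellipsoid(v, rx, rx, rz)
        ref = ndimage.minimum_filter(
            ndimage.maximum_filter(v, footprint=fp, mode="nearest"),
            footprint=fp, mode="nearest")
        assert np.array_equal(mine, ref)

    def test_recipes_match_stated_operators(self):
        assert CHANNEL_RECIPES["CD34"] == [("close", (7, 7, 7)), ("gauss", (1.0,))]
        assert CHANNEL_RECIPES["SMA"][0] == ("dilate", (7, 7, 4))
        assert CHANNEL_RECIPES["SMA"][1] == ("close", (8, 8, 4))
        assert CHANNEL_RECIPES["CD271"][0] == ("dilate", (8, 8, 2))
        assert CHANNEL_RECIPES["CD20"] == []
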