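"""Color normalization and stack registration on controlled fixtures."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import EuclideanTransform, warp

from splenvas.phantom import PhantomSpec, SectionImage, build_phantom, render_sections
from splenvas.stack_prep import (
    RegistrationError,
    apply_alignment,
    extract_registration_channel,
    lab_stats,
    register_stack,
    reinhard_normalize,
)


def blob_image(centers, shape=(160, 160), amp=200.0, sigma=3.0):
    img = np.zeros(shape)
    for cx, cy in centers:
        img[int(cy), int(cx)] = amp
    img = ndimage.gaussian_filter(img, sigma)
    return img


class TestReinhard:
    def test_fixed_point(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(40, 220, (32, 32, 3))
        stats = lab_stats(img)
        out = reinhard_normalize(img, stats)
        assert np.abs(out - img).max() <= 1.0

    def test_constant_image_maps_to_reference_mean(self):
        # mild reference spread keeps the lab-mean color inside the RGB
        # gamut, so the forced-by-formula identity is observable exactly
        ref = np.clip(np.random.default_rng(1).normal(150, 5, (16, 16, 3)),
                      0, 255)
        ref_stats = lab_stats(ref)
        const = np.full((8, 8, 3), 90.0)
        out = reinhard_normalize(const, ref_stats)
        # constant in, constant out; lab means equal the reference means
        assert np.ptp(out.reshape(-1, 3), axis=0).max() <= 1e-6
        mu_out, _ = lab_stats(out)
        assert np.allclose(mu_out, ref_stats[0], atol=1e-5)

    def test_stats_transferred(self):
        rng = np.random.default_rng(2)
        ref = np.clip(rng.normal(140, 40, (64, 64, 3)), 1, 254)
        img = np.clip(rng.normal(90, 15, (64, 64, 3)), 1, 254)
        ref_stats = lab_stats(ref)
        out = reinhard_normalize(img, ref_stats)
        mu, sd = lab_stats(out)
        # agreement limited only by gamut clipping on the way back to RGB
        assert np.allclose(mu, ref_stats[0], atol=0.02)
        assert np.allclose(sd, ref_stats[1], rtol=0.08)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ref = np.clip(rng.normal(150, 35, (32, 32, 3)), 1, 254)
        img = np.clip(rng.normal(100, 20, (32, 32, 3)), 1, 254).astype(np.uint8)
        stats = lab_stats(ref)
        once = reinhard_normalize(img, stats)
        twice = reinhard_normalize(once, stats)
        assert np.abs(once.astype(int) - twice.astype(int)).max() <= 1

    def test_invalid_reference_stats(self):
        with pytest.raises(ValueError):
            reinhard_normalize(np.zeros((4, 4, 3)),
                               (np.zeros(3), np.zeros(3)))


class TestExtractRegistrationChannel:
    def test_background_near_zero(self, stain_model):
        img = np.full((32, 32, 3), 255.0)
        out = extract_registration_channel(img, stain_model)
        assert out.max() <= 1e-2

    def test_blue_dominates_brown(self, stain_model):
        dens = np.zeros((64, 64, 3))
        dens[16, 16, 1] = 0.9  # blue structure
        dens[48, 48, 0] = 0.9  # brown structure
        img = np.clip(stain_model.transmit(dens), 0, 255)
        out = extract_registration_channel(img, stain_model, sigma=2.0)
        assert out[16, 16] > 10 * out[48, 48]

    def test_sigma_zero_is_raw_density(self, stain_model):
        rng = np.random.default_rng(0)
        img = rng.uniform(60, 255, (16, 16, 3))
        from splenvas.unmixing import color_deconvolve

        raw = color_deconvolve(img, stain_model)[..., 1]
        out = extract_registration_channel(img, stain_model, sigma=0.0)
        assert np.array_equal(out, raw)


class TestRegisterStack:
    def test_identical_stack_identity(self):
        rng = np.random.default_rng(0)
        centers = rng.uniform(20, 140, (25, 2))
        img = blob_image(centers)
        al = register_stack([img] * 6, seed=0)
        assert np.abs(al.thetas).max() <= 1e-3
        assert np.abs(al.translations).max() <= 1e-3

    def test_known_translations_recovered(self):
        rng = np.random.default_rng(1)
        centers = rng.uniform(25, 135, (30, 2))
        shifts = [(0, 0), (4, -3), (-2, 5), (6, 1), (-5, -4)]
        stack = [blob_image(centers + np.array(s)) for s in shifts]
        al = register_stack(stack, reference_index=0, seed=0)
        for k, (sx, sy) in enumerate(shifts):
            # recovered transform maps section k into section 0 frame
            pt = al.apply_points(k, np.array([[80.0 + sx, 80.0 + sy]]))
            assert np.linalg.norm(pt - np.array([80.0, 80.0])) <= 0.3

    def test_relative_transform_composition(self):
        """The relative transform between sections 0 and 2 equals the
        composition of 0->1 and 1->2 (all true rigid shifts recovered)."""
        rng = np.random.default_rng(2)
        centers = rng.uniform(25, 135, (30, 2))
        shifts = [(0, 0), (3, 2), (7, -1)]
        stack = [blob_image(centers + np.array(s)) for s in shifts]
        al = register_stack(stack, reference_index=0, seed=0)
        p = np.array([[60.0, 90.0], [110.0, 40.0]])
        # raw section-2 coords -> common frame, two ways
        direct = al.transform(2)(p)
        # via section 1: map 2 -> common -> raw 1, then 1 -> common
        via = al.transform(1)(al.transform(1).inverse(al.transform(2)(p)))
        assert np.allclose(direct, via, atol=1e-9)
        # and both agree with the known ground-truth shift chain
        truth = p - np.array([7.0, -1.0])
        assert np.abs(direct - truth).max() <= 0.3

    def test_featureless_section_fails(self):
        flat = np.zeros((64, 64))
        with pytest.raises(RegistrationError):
            register_stack([flat, flat, flat], seed=0)

    def test_phantom_jitter_recovery(self, stain_model):
        """Desk-scale phantom with jitter <=10 px / 2 deg: ground-truth
        transforms recovered with RMS structure-pixel error <= 0.5 px."""
        from splenvas.phantom import _jitter_transform, voxelize_ground_truth

        spec = PhantomSpec(seed=2)
        gt = build_phantom(spec)
        secs = render_sections(gt, stain_model, spec)
        chans = [extract_registration_channel(s, stain_model) for s in secs]
        al = register_stack(chans, seed=0)
        ny, nx = spec.image_shape
        ref = al.reference_index
        Js = [_jitter_transform(*s.jitter, (ny, nx)) for s in secs]
        occ = voxelize_ground_truth(
            gt, (spec.pixel_size_um, spec.pixel_size_um,
                 spec.section_thickness_um),
            domain_size_um=spec.domain_size_um, stains=("CD34",),
        )["CD34"]
        errs = []
        for k in range(len(secs)):
            xs, ys = np.nonzero(occ[:, :, k] > 0)
            if len(xs) == 0:
                continue
            pts = np.stack([xs, ys], axis=1).astype(float)
            errs.append(np.sum(
                (Js[ref](pts) - al.transform(k)(Js[k](pts)))**2, axis=1))
        rms = float(np.sqrt(np.mean(np.concatenate(errs))))
        assert rms <= 0.5


class TestApplyAlignment:
    def _sections(self, imgs):
        return [
            SectionImage(pixels=im, pixel_size_um=0.5, section_index=i,
                         z_um=7.0 * i, stain_set=frozenset({"SMA", "CD34"}))
            for i, im in enumerate(imgs)
        ]

    def test_identity_alignment_crop_only(self):
        from splenvas.stack_prep import StackAlignment

        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (100, 100, 3))
        al = StackAlignment(thetas=np.zeros(2), translations=np.zeros((2, 2)),
                            reference_index=0)
        out = apply_alignment(self._sections([img, img]), al, crop_px=60)
        assert out[0].pixels.shape[:2] == (60, 60)
        assert np.allclose(out[0].pixels, img[20:80, 20:80], atol=1e-9)

    def test_known_translation_moves_centroid(self):
        from splenvas.stack_prep import StackAlignment

        img = np.full((120, 120, 3), 255.0)
        img[50:60, 70:80] = 0.0  # dark blob
        al = StackAlignment(
            thetas=np.zeros(1),
            translations=np.array([[-5.0, 0.0]]),  # shift left 5 px
            reference_index=0,
        )
        out = apply_alignment(self._sections([img]), al)
        dark = 255.0 - out[0].pixels[..., 0]
        ys, xs = np.nonzero(dark > 10)
        cx = (dark[ys, xs] * xs).sum() / dark[ys, xs].sum()
        assert abs(cx - (74.5 - 5.0)) <= 0.2

    def test_crop_larger_than_image_fails(self):
        from splenvas.stack_prep import StackAlignment

        img = np.zeros((50, 50, 3))
        al = StackAlignment(thetas=np.zeros(1), translations=np.zeros((1, 2)),
                            reference_index=0)
        with pytest.raises(ValueError):
            apply_alignment(self._sections([img]), al, crop_px=80)
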