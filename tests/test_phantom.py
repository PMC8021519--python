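"""Phantom generation: graph structure, voxelization geometry, rendering
physics, section artifacts."""

import dataclasses

import numpy as np
import pytest

from splenvas.phantom import (
    PhantomError,
    PhantomSpec,
    apply_section_artifacts,
    build_phantom,
    render_sections,
    voxelize_ground_truth,
)
from splenvas.unmixing import color_deconvolve, subtract_background


def graph_walk_counts(gt):
    """Independent tally of structure classes by walking the edge list."""
    counts = {}
    for e in gt.edges:
        counts[e.structure_class] = counts.get(e.structure_class, 0) + 1
    return counts


class TestBuildPhantom:
    def test_empty_spec_gives_empty_graph(self):
        gt = build_phantom(PhantomSpec(
            n_arterioles=0, bcell_density=0, n_venule_contacts=0,
            n_bypass_capillaries=0, seed=0,
        ))
        assert len(gt.nodes) == 0
        assert len(gt.edges) == 0
        assert len(gt.sheaths) == 0

    def test_forced_single_tube(self):
        gt = build_phantom(PhantomSpec(
            n_arterioles=1, stem_segments=(1, 1), stem_segment_um=(200.0, 200.0),
            branches_per_arteriole=(0, 0), long_sheath=False,
            n_bypass_capillaries=0, n_venule_contacts=0, bcell_density=0,
            n_network_trees=0, domain_size_um=(160.0, 160.0, 280.0), seed=3,
        ))
        assert len(gt.nodes) == 2
        assert len(gt.edges) == 1
        assert gt.path_length([0]) == pytest.approx(200.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_class_counts_match_graph_walk(self, seed):
        gt = build_phantom(PhantomSpec(seed=seed))
        assert gt.class_counts() == graph_walk_counts(gt)

    def test_deterministic_per_seed(self):
        a = build_phantom(PhantomSpec(seed=11))
        b = build_phantom(PhantomSpec(seed=11))
        assert np.array_equal(a.nodes, b.nodes)
        assert [(e.u, e.v, e.structure_class) for e in a.edges] == \
               [(e.u, e.v, e.structure_class) for e in b.edges]

    def test_requested_counts_present(self, default_gt):
        counts = default_gt.class_counts()
        assert counts.get("bypass_capillary", 0) == 3
        assert len(default_gt.venule_contact_nodes) == 2
        assert len(default_gt.sheaths) >= 2
        assert default_gt.long_path is not None
        assert default_gt.long_path["length_um"] > 300.0

    def test_side_branch_invariant(self, default_gt):
        """Every open side branch ends at a degree-1 node within its parent
        sheath's outer radius plus one capillary radius."""
        gt = default_gt
        deg = np.zeros(len(gt.nodes), int)
        for e in gt.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        side_ids = gt.edges_of_class("side_branch_open")
        assert side_ids
        for eid in side_ids:
            e = gt.edges[eid]
            free_ends = [n for n in (e.u, e.v) if deg[n] == 1]
            assert len(free_ends) == 1
            end = gt.nodes[free_ends[0]]
            # distance to the nearest covered sheath edge
            dmin, best_sheath = np.inf, None
            for s in gt.sheaths:
                for sid in s.edge_ids:
                    se = gt.edges[sid]
                    a, b = gt.nodes[se.u], gt.nodes[se.v]
                    ab = b - a
                    t = np.clip(np.dot(end - a, ab) / np.dot(ab, ab), 0, 1)
                    d = np.linalg.norm(end - (a + t * ab))
                    if d < dmin:
                        dmin, best_sheath = d, s
            assert dmin <= best_sheath.outer_radius_um + 3.0 + 1e-6

    def test_sheath_bifurcation_bound(self, default_gt):
        for s in default_gt.sheaths:
            assert 1 <= s.n_bifurcations <= 4

    def test_infeasible_spec_raises(self):
        with pytest.raises(PhantomError):
            build_phantom(PhantomSpec(domain_size_um=(30.0, 30.0, 40.0), seed=0),
                          max_retries=3)

    def test_invalid_spec_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(sheath_bifurcation_depth=(1, 5))
        with pytest.raises(PhantomError):
            PhantomSpec(pixel_size_um=0.0)


class TestVoxelize:
    def test_empty_gt_all_zero(self):
        gt = build_phantom(PhantomSpec(
            n_arterioles=0, bcell_density=0, n_venule_contacts=0,
            n_bypass_capillaries=0, seed=0,
        ))
        vols = voxelize_ground_truth(gt, (1.0, 1.0, 1.0),
                                     domain_size_um=(20.0, 20.0, 20.0))
        for v in vols.values():
            assert not v.any()

    def test_sphere_volume_analytic(self):
        from splenvas.phantom import PhantomGroundTruth
        r = 6.0
        gt = PhantomGroundTruth(
            nodes=np.zeros((0, 3)), edges=[], sheaths=[],
            bcells=[(np.array([20.0, 20.0, 20.0]), r)],
        )
        occ = voxelize_ground_truth(gt, (0.5, 0.5, 0.5),
                                    domain_size_um=(40.0, 40.0, 40.0),
                                    stains=("CD20",))["CD20"]
        measured = occ.sum() * 0.5**3
        assert measured == pytest.approx(4 / 3 * np.pi * r**3, rel=0.10)

    def test_capsule_volume_analytic(self):
        from splenvas.phantom import Edge, PhantomGroundTruth
        r, L = 4.0, 30.0
        gt = PhantomGroundTruth(
            nodes=np.array([[10.0, 20.0, 20.0], [10.0 + L, 20.0, 20.0]]),
            edges=[Edge(0, 1, r, "network_capillary")],
            sheaths=[], bcells=[],
        )
        occ = voxelize_ground_truth(gt, (0.5, 0.5, 0.5),
                                    domain_size_um=(60.0, 40.0, 40.0),
                                    stains=("CD34",))["CD34"]
        measured = occ.sum() * 0.5**3
        expect = np.pi * r**2 * L + 4 / 3 * np.pi * r**3
        assert measured == pytest.approx(expect, rel=0.10)

    def test_coarse_spacing_warns(self, default_gt):
        with pytest.warns(UserWarning):
            voxelize_ground_truth(default_gt, (8.0, 8.0, 8.0),
                                  domain_size_um=(160.0, 160.0, 280.0))


class TestRenderSections:
    def test_empty_gt_renders_background(self, stain_model):
        spec = PhantomSpec(
            n_arterioles=0, bcell_density=0, n_venule_contacts=0,
            n_bypass_capillaries=0, noise_sd=0.0,
            jitter_translation_px=(0, 0), jitter_rotation_deg=(0, 0), seed=0,
        )
        gt = build_phantom(spec)
        secs = render_sections(gt, stain_model, spec)
        assert len(secs) == spec.n_sections
        for s in secs[:3]:
            assert (s.pixels == 255).all()

    def test_alternating_red_stain(self, stain_model, quiet_spec):
        gt = build_phantom(quiet_spec)
        secs = render_sections(gt, stain_model, quiet_spec)
        assert "CD271" in secs[0].stain_set and "CD20" not in secs[0].stain_set
        assert "CD20" in secs[1].stain_set and "CD271" not in secs[1].stain_set

    def test_beer_lambert_column(self, stain_model, quiet_spec):
        """A rendered float pixel equals the closed-form transmitted intensity
        of its integrated stain column."""
        gt = build_phantom(quiet_spec)
        secs = render_sections(gt, stain_model, quiet_spec, quantize=False)
        k = 10
        occ = voxelize_ground_truth(
            gt, (0.5, 0.5, 1.0), origin=(0.0, 0.0, k * 7.0),
            shape=(320, 320, 7), stains=("SMA", "CD34", "CD271"),
        )
        from splenvas.phantom import STAIN_AMPLITUDES
        dens = np.zeros((320, 320, 3))
        dens[..., 0] = occ["SMA"].sum(axis=2).T * 1.0 * STAIN_AMPLITUDES["SMA"]
        dens[..., 1] = occ["CD34"].sum(axis=2).T * 1.0 * STAIN_AMPLITUDES["CD34"]
        dens[..., 2] = occ["CD271"].sum(axis=2).T * 1.0 * STAIN_AMPLITUDES["CD271"]
        expect = np.clip(stain_model.transmit(dens), 0, 255)
        assert np.abs(expect - secs[k].pixels).max() <= 1e-9

    def test_render_unmix_round_trip(self, stain_model, quiet_spec):
        """Rendering then exact unmixing recovers per-stain column densities
        to 1e-6 of full scale (zero noise, zero jitter, float pixels)."""
        gt = build_phantom(quiet_spec)
        secs = render_sections(gt, stain_model, quiet_spec, quantize=False)
        k = 12
        bg = subtract_background(secs[k].pixels, percentile=100)
        rec = color_deconvolve(bg, stain_model)
        occ = voxelize_ground_truth(
            gt, (0.5, 0.5, 1.0), origin=(0.0, 0.0, k * 7.0),
            shape=(320, 320, 7), stains=("SMA", "CD34", "CD271"),
        )
        from splenvas.phantom import STAIN_AMPLITUDES
        truth = np.zeros((320, 320, 3))
        truth[..., 0] = occ["SMA"].sum(axis=2).T * STAIN_AMPLITUDES["SMA"]
        truth[..., 1] = occ["CD34"].sum(axis=2).T * STAIN_AMPLITUDES["CD34"]
        truth[..., 2] = occ["CD271"].sum(axis=2).T * STAIN_AMPLITUDES["CD271"]
        scale = max(truth.max(), 1.0)
        assert np.abs(rec - truth).max() / scale <= 1e-6

    def test_deterministic_under_seed(self, stain_model):
        spec = PhantomSpec(seed=5)
        gt = build_phantom(spec)
        a = render_sections(gt, stain_model, spec)
        b = render_sections(gt, stain_model, spec)
        assert np.array_equal(a[7].pixels, b[7].pixels)
        assert a[7].jitter == b[7].jitter


class TestSectionArtifacts:
    def test_empty_lists_identity(self, stain_model, quiet_spec):
        gt = build_phantom(quiet_spec)
        secs = render_sections(gt, stain_model, quiet_spec)
        out = apply_section_artifacts(secs)
        assert len(out) == len(secs)
        assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(out, secs))

    def test_lost_sections_removed_with_gap(self, stain_model, quiet_spec):
        gt = build_phantom(quiet_spec)
        secs = render_sections(gt, stain_model, quiet_spec)
        out = apply_section_artifacts(secs, lost_section_indices=(3, 17))
        assert len(out) == len(secs) - 2
        kept = [s.section_index for s in out]
        assert 3 not in kept and 17 not in kept
        # original indices (and hence z positions) preserved across the gap
        assert kept == sorted(kept)
        assert out[3].section_index == 4

    def test_defocus_reduces_high_frequency_energy(self, stain_model, quiet_spec):
        gt = build_phantom(quiet_spec)
        secs = render_sections(gt, stain_model, quiet_spec)
        out = apply_section_artifacts(secs, defocus_indices=(10,), defocus_sigma=3.0)

        def hf_energy(img):
            f = np.fft.fftshift(np.fft.fft2(img.astype(float).mean(axis=2)))
            h, w = f.shape
            r = min(h, w) // 4
            mask = np.ones_like(f, bool)
            mask[h // 2 - r:h // 2 + r, w // 2 - r:w // 2 + r] = False
            return float(np.abs(f[mask]).sum())

        assert not out[10].focus_ok
        assert hf_energy(out[10].pixels) < hf_energy(out[9].pixels)
        assert hf_energy(out[10].pixels) < hf_energy(out[11].pixels)

    def test_out_of_range_index_fails(self, stain_model, quiet_spec):
        gt = build_phantom(quiet_spec)
        secs = render_sections(gt, stain_model, quiet_spec)
        with pytest.raises(IndexError):
            apply_section_artifacts(secs, lost_section_indices=(999,))
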