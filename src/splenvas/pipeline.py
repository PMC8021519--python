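"""End-to-end orchestration: phantom -> prep -> unmix -> volumes -> meshes ->
mesh post-processing -> recovery scoring, with a run manifest.

Each stage writes its outputs under the run directory and records them in
the manifest with checksums; a re-run with the same configuration hash
reuses cached stage outputs, so the pipeline is resumable.  One global seed
fans out to per-stage seeds by fixed derivation.

Also home to the volume/crop bookkeeping that reproduces the acquisition's
printed geometry numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import EuclideanTransform

from . import io as svio
from .config import PipelineConfig
from .mesh_ops import (
    paint_by_proximity,
    prune_cell_components,
    quadric_decimate,
    recover_topology,
    remove_small_components,
    taubin_smooth,
)
from .meshing import isosurface, repair_watertight
from .phantom import (
    PhantomSpec,
    _jitter_transform,
    apply_section_artifacts,
    build_phantom,
    render_sections,
)
from .stack_prep import (
    apply_alignment,
    extract_registration_channel,
    lab_stats,
    register_stack,
    reinhard_normalize,
)
from .unmixing import (
    channel_to_intensity,
    color_deconvolve,
    stack_stretch_range,
    subtract_background,
    single_stain_response,
)
from .volume_build import ChannelVolume, filter_channel_volume, flow_interpolate_z, nn_resize_z

__all__ = [
    "RunManifest",
    "run_pipeline",
    "compute_roi_volume",
    "crop_accounting",
    "derive_stage_seed",
]

STAGES = ("phantom", "prep", "unmix", "volumes", "mesh", "ops", "score")


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Fixed fan-out of one global seed to per-stage seeds (below 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def compute_roi_volume(n_sections: int, thickness_um: float, crop_px: int,
                       pixel_size_um: float) -> float:
    """ROI volume in mm³: (crop · pixel size)² · sections · thickness.

    Rounded to two decimals, the convention used for reporting ROI sizes.
    """
    if thickness_um <= 0 or crop_px <= 0 or pixel_size_um <= 0 or n_sections < 0:
        raise ValueError("all geometry parameters must be positive")
    side_mm = crop_px * pixel_size_um / 1000.0
    depth_mm = n_sections * thickness_um / 1000.0
    return round(side_mm * side_mm * depth_mm, 2)


def crop_accounting(total_sections: int, used_sections: int) -> int:
    """Percent of cut sections not used, rounded to the nearest integer."""
    if total_sections == 0:
        raise ValueError("total_sections must be positive")
    if used_sections > total_sections:
        raise ValueError("used cannot exceed total")
    return int(round(100.0 * (total_sections - used_sections) / total_sections))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    recovery: dict | None = None

    def record(self, stage: str, paths: dict, seconds: float) -> None:
        self.outputs[stage] = {
            name: {"path": str(p), "sha256": _file_hash(p)}
            for name, p in paths.items()
        }
        self.stage_seconds[stage] = round(seconds, 2)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    def verify(self) -> bool:
        for stage in self.outputs.values():
            for rec in stage.values():
                p = Path(rec["path"])
                if not p.exists() or _file_hash(p) != rec["sha256"]:
                    return False
        return True


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, err: BaseException):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stack_to_volume(slices: list[np.ndarray], spacing, channel, origin_z=0.0
                     ) -> ChannelVolume:
    # slices are (row=y, col=x); volume is (x, y, z)
    vals = np.stack([s.T for s in slices], axis=2)
    return ChannelVolume(vals, spacing, channel, origin_um=(0.0, 0.0, origin_z))


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int = 0,
                 resume: bool = True, keep_arrays: bool = True,
                 stop_after: str | None = None) -> RunManifest:
    """Execute the stages in order; deterministic for fixed seeds.

    ``stop_after`` truncates the run after the named stage (one of
    ``phantom, prep, unmix, volumes, mesh, ops, score``).  Returns the
    manifest; with ``keep_arrays`` the in-memory products (sections,
    volumes, meshes, recovery report) are attached to it under
    ``manifest.arrays`` for programmatic use.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=seed)
    arrays: dict = {}
    manifest.arrays = arrays  # type: ignore[attr-defined]

    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        cached = _try_resume(config, outdir, seed)
        if cached is not None:
            return cached

    stain_model = config.stain_model()

    # ---- phantom ----------------------------------------------------------
    t0 = time.time()
    stage = "phantom"
    try:
        spec = config.phantom_spec()
        spec = dataclasses.replace(spec, seed=derive_stage_seed(seed, "phantom"))
        gt = build_phantom(spec)
        sections = render_sections(gt, stain_model, spec)
        sections = apply_section_artifacts(
            sections, lost_section_indices=spec.lost_section_indices
        )
        sec_dir = outdir / "sections"
        svio.write_section_stack(sections, sec_dir,
                                 lost_section_indices=spec.lost_section_indices)
        gt_path = svio.write_ground_truth(gt, outdir / "ground_truth.json")
        manifest.record(stage, {"ground_truth": gt_path,
                                "stack_metadata": sec_dir / "stack_metadata.json"},
                        time.time() - t0)
        arrays.update(gt=gt, sections=sections, spec=spec)
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    if stop_after == "phantom":
        manifest.save(outdir / "manifest_partial.json")
        return manifest

    # ---- prep: normalize, register, resample ------------------------------
    t0 = time.time()
    stage = "prep"
    try:
        ref_idx = min(config.reinhard_reference_index, len(sections) - 1)
        ref_stats = lab_stats(sections[ref_idx].pixels)
        normalized = [reinhard_normalize(s, ref_stats) for s in sections]
        channels = [
            extract_registration_channel(s, stain_model,
                                         sigma=config.registration_sigma)
            for s in normalized
        ]
        alignment = register_stack(
            channels, seed=derive_stage_seed(seed, "registration")
        )
        crop = min(config.crop_px, normalized[0].pixels.shape[0])
        registered = apply_alignment(normalized, alignment, crop_px=crop)
        al_path = svio.write_alignment(alignment, outdir / "alignment.json")
        manifest.record(stage, {"alignment": al_path}, time.time() - t0)
        arrays.update(alignment=alignment, registered=registered, crop_px=crop)
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    if stop_after == "prep":
        manifest.save(outdir / "manifest_partial.json")
        return manifest

    # ---- unmix ------------------------------------------------------------
    t0 = time.time()
    stage = "unmix"
    try:
        densities = []
        for s in registered:
            bg = subtract_background(
                np.asarray(s.pixels, dtype=float),
                percentile=config.background_percentile,
            )
            densities.append(color_deconvolve(bg, stain_model))
        # channel -> list of (section, raw response) then stack-wide stretch
        chan_sections: dict[str, list[tuple[int, np.ndarray]]] = {
            "SMA": [], "CD34": [], "CD271": [], "CD20": [],
        }
        row_of = {"SMA": 0, "CD34": 1}
        for s, dens in zip(registered, densities):
            for marker, row in row_of.items():
                chan_sections[marker].append((s.section_index, dens[..., row]))
            red_marker = "CD271" if "CD271" in s.stain_set else "CD20"
            chan_sections[red_marker].append((s.section_index, dens[..., 2]))
        channel_stacks: dict[str, list[tuple[int, np.ndarray]]] = {}
        for marker, items in chan_sections.items():
            chan = {"SMA": "brown", "CD34": "blue"}.get(marker, "red")
            raws = [single_stain_response(d, chan, stain_model)
                    for _idx, d in items]
            rng_ = stack_stretch_range(raws) if raws else (0.0, 0.0)
            imgs = [
                (idx, channel_to_intensity(d, chan, stain_model,
                                           stretch_range=rng_).values)
                for (idx, d) in items
            ]
            channel_stacks[marker] = imgs
        manifest.record(stage, {}, time.time() - t0)
        arrays.update(channel_stacks=channel_stacks)
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    if stop_after == "unmix":
        manifest.save(outdir / "manifest_partial.json")
        return manifest

    # ---- volumes ----------------------------------------------------------
    t0 = time.time()
    stage = "volumes"
    try:
        px = config.pixel_size_um
        th = config.thickness_um
        volumes: dict[str, ChannelVolume] = {}
        for marker, items in channel_stacks.items():
            if not items:
                continue
            items = sorted(items, key=lambda t: t[0])
            ccfg = config.channel(marker)
            idxs = [i for i, _ in items]
            dz = th * (idxs[1] - idxs[0]) if len(idxs) > 1 else th
            # slab center of the first section carrying this marker
            origin_z = idxs[0] * th + th / 2 - dz / 2
            vol = _stack_to_volume([im for _, im in items], (px, px, dz),
                                   marker, origin_z=origin_z)
            if ccfg.interp_mode == "flow" and ccfg.interp_factor > 1:
                vol = flow_interpolate_z(vol, ccfg.interp_factor)
            elif ccfg.interp_mode == "nearest" and ccfg.interp_factor > 1:
                vol = nn_resize_z(vol, ccfg.interp_factor)
            vol = filter_channel_volume(vol, marker)
            volumes[marker] = vol
        vol_paths = {
            m: svio.write_channel_volume(v, outdir / "volumes" / f"{m}.tif")
            for m, v in volumes.items()
        }
        manifest.record(stage, vol_paths, time.time() - t0)
        arrays.update(volumes=volumes)
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    if stop_after == "volumes":
        manifest.save(outdir / "manifest_partial.json")
        return manifest

    # ---- mesh -------------------------------------------------------------
    t0 = time.time()
    stage = "mesh"
    try:
        raw_meshes = {}
        for marker, vol in volumes.items():
            ccfg = config.channel(marker)
            m = isosurface(vol, ccfg.iso)
            if len(m.faces) > 0:
                m = repair_watertight(m, ccfg.octree_depth)
            raw_meshes[marker] = m
        mesh_paths = {
            m: svio.write_mesh(mm, outdir / "meshes" / f"{m}_raw.ply")
            for m, mm in raw_meshes.items() if len(mm.faces) > 0
        }
        manifest.record(stage, mesh_paths, time.time() - t0)
        arrays.update(raw_meshes=raw_meshes)
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    if stop_after == "mesh":
        manifest.save(outdir / "manifest_partial.json")
        return manifest

    # ---- ops --------------------------------------------------------------
    t0 = time.time()
    stage = "ops"
    try:
        meshes = {}
        for marker, m in raw_meshes.items():
            ccfg = config.channel(marker)
            if len(m.faces) == 0:
                meshes[marker] = m
                continue
            if ccfg.smooth:
                m = taubin_smooth(m, iterations=config.taubin_iterations)
            if ccfg.component_fraction is not None:
                m = remove_small_components(m, ccfg.component_fraction)
            if ccfg.decimate_fraction is not None:
                m = quadric_decimate(m, ccfg.decimate_fraction)
            meshes[marker] = m
        paint = None
        if ("CD34" in meshes and len(meshes["CD34"].faces) > 0
                and "SMA" in meshes and len(meshes["SMA"].faces) > 0):
            paint = paint_by_proximity(meshes["CD34"], meshes["SMA"],
                                       threshold_um=config.paint_threshold_um)
        if "CD20" in meshes and len(meshes["CD20"].faces) > 0:
            refs = [meshes[m] for m in ("CD271", "CD34") if m in meshes]
            meshes["CD20"] = prune_cell_components(
                meshes["CD20"], refs,
                max_distance_um=config.prune_max_distance_um,
                min_diameter_um=config.prune_min_diameter_um,
            )
        out_paths = {}
        for marker, m in meshes.items():
            if len(m.faces) == 0:
                continue
            out_paths[marker] = svio.write_mesh(
                m, outdir / "meshes" / f"{marker}.ply"
            )
        if paint is not None:
            out_paths["CD34_painted"] = svio.write_mesh(
                paint.colored_mesh(), outdir / "meshes" / "CD34_painted.ply"
            )
        manifest.record(stage, out_paths, time.time() - t0)
        arrays.update(meshes=meshes, paint=paint)
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    if stop_after == "ops":
        manifest.save(outdir / "manifest_partial.json")
        return manifest

    # ---- score ------------------------------------------------------------
    t0 = time.time()
    stage = "score"
    try:
        gt_tf = make_gt_transform(arrays["sections"], alignment,
                                  arrays["spec"], crop)
        report = recover_topology(
            meshes, gt, tolerance_um=config.recovery_tolerance_um,
            gt_transform=gt_tf,
        )
        rep_path = outdir / "recovery_report.json"
        with open(rep_path, "w") as fh:
            json.dump(report.as_dict(), fh, indent=1)
        manifest.record(stage, {"recovery_report": rep_path}, time.time() - t0)
        manifest.recovery = report.as_dict()
        arrays.update(recovery=report)
    except Exception as err:  # noqa: BLE001
        raise StageFailure(stage, err) from err

    manifest.save(outdir / "manifest.json")
    return manifest


def _try_resume(config: PipelineConfig, outdir: Path, seed: int
                ) -> RunManifest | None:
    """Reload a completed run with matching config hash and seed, if intact."""
    try:
        with open(outdir / "manifest.json") as fh:
            doc = json.load(fh)
        if doc["config_hash"] != config.config_hash() or doc["seed"] != seed:
            return None
        manifest = RunManifest(
            config_hash=doc["config_hash"], seed=doc["seed"],
            stage_seconds=doc.get("stage_seconds", {}),
            outputs=doc.get("outputs", {}),
            warnings=doc.get("warnings", []),
            recovery=doc.get("recovery"),
        )
        if not manifest.verify():
            return None
        arrays: dict = {}
        arrays["gt"] = svio.read_ground_truth(outdir / "ground_truth.json")
        arrays["sections"] = svio.read_section_stack(outdir / "sections")
        arrays["alignment"] = svio.read_alignment(outdir / "alignment.json")
        arrays["volumes"] = {
            m: svio.read_channel_volume(outdir / "volumes" / f"{m}.tif")
            for m in config.channels
            if (outdir / "volumes" / f"{m}.tif").exists()
        }
        arrays["meshes"] = {
            m: svio.read_mesh(outdir / "meshes" / f"{m}.ply")
            for m in config.channels
            if (outdir / "meshes" / f"{m}.ply").exists()
        }
        manifest.arrays = arrays  # type: ignore[attr-defined]
        return manifest
    except Exception:  # noqa: BLE001 - any corruption falls back to re-run
        return None


def make_gt_transform(sections, alignment, spec: PhantomSpec, crop_px: int):
    """Map phantom world coordinates into the reconstructed mesh frame.

    The registered stack lives in the raw pixel frame of the reference
    section; ground truth lives in the jitter-free phantom frame.  The
    transform applies the reference section's true jitter, then the central
    crop offset, in pixel units, and returns micrometre coordinates.
    """
    ref = alignment.reference_index
    ny, nx = sections[0].pixels.shape[:2] if hasattr(sections[0], "pixels") \
        else spec.image_shape
    # note: sections passed here are pre-crop renders
    J_ref = _jitter_transform(*sections[ref].jitter, (ny, nx))
    s = spec.pixel_size_um
    c0 = (nx - crop_px) // 2
    r0 = (ny - crop_px) // 2

    def transform(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        cols = pts[:, 0] / s - 0.5
        rows = pts[:, 1] / s - 0.5
        raw = J_ref(np.stack([cols, rows], axis=1))
        out = np.empty_like(pts)
        out[:, 0] = (raw[:, 0] - c0 + 0.5) * s
        out[:, 1] = (raw[:, 1] - r0 + 0.5) * s
        out[:, 2] = pts[:, 2]
        return out

    return transform
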