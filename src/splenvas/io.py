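"""Plain-format I/O: section stacks, channel volumes, alignments, ground truth.

Sections are numbered 8-bit RGB TIFFs (``section_0000.tif``) with one JSON
sidecar per stack carrying physical geometry, per-section stain sets, jitter
ground truth and lost-section bookkeeping.  Channel volumes are multi-page
grayscale TIFFs plus a JSON sidecar with spacing/origin.  Meshes go through
trimesh (PLY with vertex colors, OBJ, STL).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from .phantom import Edge, PhantomGroundTruth, SectionImage, Sheath
from .stack_prep import StackAlignment
from .volume_build import ChannelVolume

__all__ = [
    "write_section_stack",
    "read_section_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_alignment",
    "read_alignment",
    "write_channel_volume",
    "read_channel_volume",
    "write_mesh",
    "read_mesh",
]


def write_section_stack(sections: list[SectionImage], directory: str | Path,
                        lost_section_indices=()) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_size_um": sections[0].pixel_size_um if sections else None,
        "lost_section_indices": sorted(int(i) for i in lost_section_indices),
        "sections": [],
    }
    for s in sections:
        name = f"section_{s.section_index:04d}.tif"
        tifffile.imwrite(directory / name, np.asarray(s.pixels, dtype=np.uint8))
        meta["sections"].append({
            "file": name,
            "section_index": int(s.section_index),
            "z_um": float(s.z_um),
            "stain_set": sorted(s.stain_set),
            "focus_ok": bool(s.focus_ok),
            "jitter": [float(v) for v in s.jitter],
        })
    with open(directory / "stack_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def read_section_stack(directory: str | Path) -> list[SectionImage]:
    directory = Path(directory)
    with open(directory / "stack_metadata.json") as fh:
        meta = json.load(fh)
    out = []
    for rec in meta["sections"]:
        px = tifffile.imread(directory / rec["file"])
        out.append(SectionImage(
            pixels=px,
            pixel_size_um=meta["pixel_size_um"],
            section_index=rec["section_index"],
            z_um=rec["z_um"],
            stain_set=frozenset(rec["stain_set"]),
            focus_ok=rec["focus_ok"],
            jitter=tuple(rec["jitter"]),
        ))
    return out


def write_ground_truth(gt: PhantomGroundTruth, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "nodes": np.asarray(gt.nodes).tolist(),
        "edges": [
            {"u": e.u, "v": e.v, "radius_um": e.radius_um,
             "structure_class": e.structure_class}
            for e in gt.edges
        ],
        "sheaths": [
            {"edge_ids": s.edge_ids, "outer_radius_um": s.outer_radius_um,
             "entry_node": s.entry_node, "exit_node": s.exit_node,
             "n_bifurcations": s.n_bifurcations,
             "main_path_edge_ids": s.main_path_edge_ids}
            for s in gt.sheaths
        ],
        "bcells": [[np.asarray(c).tolist(), float(r)] for c, r in gt.bcells],
        "stain_map": {k: sorted(v) for k, v in gt.stain_map.items()},
        "venule_contact_nodes": list(gt.venule_contact_nodes),
        "long_path": gt.long_path,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def read_ground_truth(path: str | Path) -> PhantomGroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return PhantomGroundTruth(
        nodes=np.asarray(doc["nodes"], dtype=float).reshape(-1, 3),
        edges=[Edge(e["u"], e["v"], e["radius_um"], e["structure_class"])
               for e in doc["edges"]],
        sheaths=[Sheath(s["edge_ids"], s["outer_radius_um"], s["entry_node"],
                        s["exit_node"], s["n_bifurcations"],
                        s["main_path_edge_ids"])
                 for s in doc["sheaths"]],
        bcells=[(np.asarray(c, dtype=float), r) for c, r in doc["bcells"]],
        stain_map={k: frozenset(v) for k, v in doc["stain_map"].items()},
        venule_contact_nodes=list(doc["venule_contact_nodes"]),
        long_path=doc["long_path"],
    )


def write_alignment(alignment: StackAlignment, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "reference_index": int(alignment.reference_index),
        "theta_rad": np.asarray(alignment.thetas).tolist(),
        "translation_px": np.asarray(alignment.translations).tolist(),
        "residual_stats": {
            "mean_rms_px": alignment.residual_stats.get("mean_rms_px"),
            "pair_rms_px": {
                f"{i}-{j}": v
                for (i, j), v in alignment.residual_stats.get(
                    "pair_rms_px", {}
                ).items()
            },
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


def read_alignment(path: str | Path) -> StackAlignment:
    with open(path) as fh:
        doc = json.load(fh)
    stats = doc.get("residual_stats", {})
    pair = {
        tuple(int(x) for x in k.split("-")): v
        for k, v in stats.get("pair_rms_px", {}).items()
    }
    return StackAlignment(
        thetas=np.asarray(doc["theta_rad"], dtype=float),
        translations=np.asarray(doc["translation_px"], dtype=float),
        reference_index=doc["reference_index"],
        residual_stats={"mean_rms_px": stats.get("mean_rms_px"),
                        "pair_rms_px": pair},
    )


def write_channel_volume(volume: ChannelVolume, path: str | Path) -> Path:
    """Multi-page TIFF (page = z slice, row = y, col = x) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.transpose(volume.values, (2, 1, 0))  # z, y, x
    tifffile.imwrite(path, pages)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({
            "spacing_um": list(volume.spacing_um),
            "origin_um": list(volume.origin_um),
            "channel": volume.channel,
            "provenance": volume.provenance,
            "axis_order": "zyx pages",
        }, fh, indent=1)
    return path


def read_channel_volume(path: str | Path) -> ChannelVolume:
    path = Path(path)
    pages = tifffile.imread(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    return ChannelVolume(
        values=np.transpose(pages, (2, 1, 0)),
        spacing_um=tuple(meta["spacing_um"]),
        channel=meta["channel"],
        provenance=meta["provenance"],
        origin_um=tuple(meta["origin_um"]),
    )


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), force="mesh", process=False)
    return m
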