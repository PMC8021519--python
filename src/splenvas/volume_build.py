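"""Per-channel 3D volume assembly, z-interpolation, and grayscale filtering.

Serial sections give strongly anisotropic voxels (0.5 × 0.5 × 7 µm for the
channels stained on every section, 14 µm for the alternating ones).  Dense
optical flow between consecutive slices drives shape-aware interpolation
that brings the z spacing down to 1 µm (SMA, CD34) or 2 µm (CD271); the
B-cell channel (CD20), being made of small round cells, is only replicated
by nearest-neighbour resizing when an isotropic grid is wanted.

After interpolation each channel receives its own grayscale morphology
(dilation/closing with anisotropic digital-ellipsoid structuring elements,
then a Gaussian blur) that bridges the residual z gaps before iso-surfacing:

* CD34 — closing radius 7 (uniform), Gaussian sigma 1;
* SMA — dilation 7-7-4, closing 8-8-4, Gaussian sigma 2;
* CD271 — dilation 8-8-2, closing 5 (uniform), Gaussian sigma 1;
* CD20 — untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_ilk

__all__ = [
    "ChannelVolume",
    "flow_interpolate_z",
    "nn_resize_z",
    "filter_channel_volume",
    "ellipsoid_footprint",
    "grey_dilate_ellipsoid",
    "grey_erode_ellipsoid",
    "grey_close_ellipsoid",
    "CHANNEL_RECIPES",
]


@dataclass
class ChannelVolume:
    """One stain channel as an 8-bit scalar grid with physical spacing.

    ``values`` is indexed (x, y, z); ``spacing_um`` and ``origin_um`` place
    voxel centers in world micrometres: ``world = origin + (index + 1/2) *
    spacing``.
    """

    values: np.ndarray
    spacing_um: tuple[float, float, float]
    channel: str
    provenance: str = "raw"
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")


def flow_interpolate_z(
    volume: ChannelVolume,
    factor: int,
    radius: int = 12,
    num_warp: int = 3,
) -> ChannelVolume:
    """Optical-flow slice interpolation reducing z anisotropy by ``factor``.

    Between each consecutive slice pair (A, B) dense flow is estimated in
    both directions (iterative Lucas-Kanade, coarse-to-fine); the slice at
    fraction alpha is the blend ``(1-alpha) * warp(A, alpha * flow_AB) +
    alpha * warp(B, (1-alpha) * flow_BA)``.  Original slices are copied
    through bit-exactly; the output has ``(Z-1) * factor + 1`` slices and
    z-spacing divided by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vals = volume.values
    if vals.shape[2] < 2:
        raise ValueError("need at least two slices")
    if factor == 1:
        return dataclasses.replace(volume, provenance="interpolated")
    nx, ny, nz = vals.shape
    out = np.empty((nx, ny, (nz - 1) * factor + 1), dtype=vals.dtype)
    rows, cols = np.mgrid[0:ny, 0:nx]
    for k in range(nz - 1):
        a = vals[:, :, k].T.astype(np.float32)  # row=y, col=x
        b = vals[:, :, k + 1].T.astype(np.float32)
        out[:, :, k * factor] = vals[:, :, k]
        if np.array_equal(a, b):
            for s in range(1, factor):
                out[:, :, k * factor + s] = vals[:, :, k]
            continue
        flow_ab = optical_flow_ilk(a, b, radius=radius, num_warp=num_warp)
        flow_ba = optical_flow_ilk(b, a, radius=radius, num_warp=num_warp)
        for s in range(1, factor):
            alpha = s / factor
            # forward-warp A by alpha of the A->B flow (backward sampling:
            # the feature seen at r in A sits at r + flow_ab(r) in B)
            wa = ndimage.map_coordinates(
                a,
                [rows - alpha * flow_ab[0], cols - alpha * flow_ab[1]],
                order=1, mode="nearest",
            )
            wb = ndimage.map_coordinates(
                b,
                [rows - (1 - alpha) * flow_ba[0], cols - (1 - alpha) * flow_ba[1]],
                order=1, mode="nearest",
            )
            blend = (1 - alpha) * wa + alpha * wb
            if np.issubdtype(vals.dtype, np.integer):
                blend = np.rint(np.clip(blend, 0, 255))
            out[:, :, k * factor + s] = blend.T.astype(vals.dtype)
    out[:, :, -1] = vals[:, :, -1]
    sx, sy, sz = volume.spacing_um
    ox, oy, oz = volume.origin_um
    # keep original slice centers at their world positions: with the
    # voxel-center convention, halving the spacing shifts the origin
    return dataclasses.replace(
        volume,
        values=out,
        spacing_um=(sx, sy, sz / factor),
        origin_um=(ox, oy, oz + 0.5 * sz - 0.5 * sz / factor),
        provenance="interpolated",
    )


def nn_resize_z(volume: ChannelVolume, factor: int) -> ChannelVolume:
    """Repeat each slice ``factor`` times (nearest-neighbour z resize).

    Introduces no new gray values; appropriate for channels made of small
    isolated round objects where shape-connecting interpolation would
    invent structure.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return dataclasses.replace(volume, provenance="interpolated")
    out = np.repeat(volume.values, factor, axis=2)
    sx, sy, sz = volume.spacing_um
    ox, oy, oz = volume.origin_um
    return dataclasses.replace(
        volume, values=out, spacing_um=(sx, sy, sz / factor),
        origin_um=(ox, oy, oz + 0.5 * sz - 0.5 * sz / factor),
        provenance="interpolated",
    )


# ---------------------------------------------------------------------------
# grayscale morphology with digital-ellipsoid structuring elements


def ellipsoid_footprint(rx: int, ry: int, rz: int) -> np.ndarray:
    """Digital ellipsoid: voxel centers within the ellipse of radii (rx, ry, rz)."""
    x = np.arange(-rx, rx + 1)[:, None, None] / max(rx, 1e-9)
    y = np.arange(-ry, ry + 1)[None, :, None] / max(ry, 1e-9)
    z = np.arange(-rz, rz + 1)[None, None, :] / max(rz, 1e-9)
    if rx == 0:
        x = np.zeros((1, 1, 1))
    if ry == 0:
        y = np.zeros((1, 1, 1))
    if rz == 0:
        z = np.zeros((1, 1, 1))
    return (x**2 + y**2 + z**2) <= 1.0 + 1e-12


def _box_decomposition(rx: int, ry: int, rz: int) -> list[tuple[int, int, int]]:
    """Maximal symmetric boxes whose union equals the digital ellipsoid.

    A flat dilation by a union of sets is the voxelwise max of the dilations
    by each set, and a symmetric box dilation separates into three 1-D
    running maxima, so this decomposition turns the O(|SE|)-per-voxel
    ellipsoid filter into a handful of O(1)-per-voxel passes.
    """
    fp = ellipsoid_footprint(rx, ry, rz)
    boxes: set[tuple[int, int, int]] = set()
    for dz in range(rz + 1):
        for dy in range(ry + 1):
            xs = np.nonzero(fp[:, ry + dy, rz + dz])[0]
            if len(xs) == 0:
                continue
            dx = int(xs.max() - rx)
            if dx >= 0:
                boxes.add((dx, dy, dz))
    # prune dominated boxes
    pruned = [
        b for b in boxes
        if not any(o != b and all(oc >= bc for oc, bc in zip(o, b)) for o in boxes)
    ]
    return sorted(pruned)


def _box_filter(vol: np.ndarray, half: tuple[int, int, int], op) -> np.ndarray:
    out = vol
    for axis, h in enumerate(half):
        if h > 0:
            out = op(out, size=2 * h + 1, axis=axis, mode="nearest")
    return out


def grey_dilate_ellipsoid(vol: np.ndarray, rx: int, ry: int, rz: int) -> np.ndarray:
    """Grayscale dilation by a digital ellipsoid (edge-replicated border)."""
    out = None
    for box in _box_decomposition(rx, ry, rz):
        cand = _box_filter(vol, box, ndimage.maximum_filter1d)
        out = cand if out is None else np.maximum(out, cand)
    return vol.copy() if out is None else out


def grey_erode_ellipsoid(vol: np.ndarray, rx: int, ry: int, rz: int) -> np.ndarray:
    """Grayscale erosion by a digital ellipsoid (edge-replicated border)."""
    out = None
    for box in _box_decomposition(rx, ry, rz):
        cand = _box_filter(vol, box, ndimage.minimum_filter1d)
        out = cand if out is None else np.minimum(out, cand)
    return vol.copy() if out is None else out


def grey_close_ellipsoid(vol: np.ndarray, rx: int, ry: int, rz: int) -> np.ndarray:
    """Grayscale closing (dilation then erosion) by a digital ellipsoid."""
    return grey_erode_ellipsoid(grey_dilate_ellipsoid(vol, rx, ry, rz), rx, ry, rz)


#: channel -> ordered operator list; radii are (x, y, z) voxel radii
CHANNEL_RECIPES: dict[str, list[tuple[str, tuple]]] = {
    "CD34": [("close", (7, 7, 7)), ("gauss", (1.0,))],
    "SMA": [("dilate", (7, 7, 4)), ("close", (8, 8, 4)), ("gauss", (2.0,))],
    "CD271": [("dilate", (8, 8, 2)), ("close", (5, 5, 5)), ("gauss", (1.0,))],
    "CD20": [],
}


def filter_channel_volume(volume: ChannelVolume, channel: str | None = None
                          ) -> ChannelVolume:
    """Apply the channel's grayscale morphology recipe (see module docstring)."""
    channel = channel or volume.channel
    if channel not in CHANNEL_RECIPES:
        raise ValueError(f"unknown channel {channel!r}")
    vals = volume.values.astype(np.float32)
    for op, args in CHANNEL_RECIPES[channel]:
        if op == "dilate":
            vals = grey_dilate_ellipsoid(vals, *args)
        elif op == "close":
            vals = grey_close_ellipsoid(vals, *args)
        elif op == "gauss":
            vals = ndimage.gaussian_filter(vals, sigma=args[0])
    if np.issubdtype(volume.values.dtype, np.integer):
        vals = np.rint(np.clip(vals, 0, 255)).astype(volume.values.dtype)
    else:
        vals = vals.astype(volume.values.dtype)
    return dataclasses.replace(volume, values=vals, provenance="filtered")
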