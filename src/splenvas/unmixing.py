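"""Separate registered RGB sections into per-stain 8-bit intensity channels.

The stage mirrors a classic brightfield workflow: estimate and subtract the
background (white point), color-deconvolve into brown/blue/red stain
densities, then convert each single-stain density to the 8-bit intensity
representation used for iso-surfacing.  The per-channel conversions are
deliberately idiosyncratic — they re-render the single stain to RGB and pick
one colorspace component — because that is what makes iso-value selection on
the resulting grayscale stacks behave well:

* blue (CD34):  re-render, negate, keep the green component;
* brown (SMA):  re-render, negate, keep the blue component;
* red (CD271/CD20): re-render, take the CMYK magenta component.

Each channel is finally stretched linearly over the stack-wide min/max so
that 0 means "no stain" and 255 means "maximal stain".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stain import STAIN_ORDER, StainModel

__all__ = [
    "StainChannelImage",
    "subtract_background",
    "color_deconvolve",
    "single_stain_response",
    "stack_stretch_range",
    "channel_to_intensity",
]


@dataclass
class StainChannelImage:
    """One unmixed stain channel of one section, 8-bit intensity."""

    values: np.ndarray  # H x W uint8
    channel: str  # 'blue' | 'brown' | 'red'
    section_index: int = 0
    pixel_size_um: float = 0.5


def subtract_background(image: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Rescale so the estimated white point maps to pure white (255).

    The white point is estimated per RGB channel as a high percentile of the
    pixel intensities (default 99th; 100 uses the channel maximum).  A
    saturated-black image has no estimable background and raises.
    """
    image = np.asarray(image, dtype=float)
    wp = np.percentile(image.reshape(-1, image.shape[-1]), percentile, axis=0)
    if np.any(wp <= 0):
        raise ValueError("background not estimable: channel white point is zero")
    out = image * (255.0 / wp)
    return np.clip(out, 0.0, 255.0)


def color_deconvolve(image: np.ndarray, model: StainModel) -> np.ndarray:
    """RGB image -> per-stain density maps, shape ``(..., 3)``.

    OD is computed as ``-log10((I + 1) / 256)`` per channel, then projected
    through the inverse stain matrix.  Negative densities (noise pushing a
    pixel outside the stain simplex) are clipped to zero.
    """
    image = np.asarray(image, dtype=float)
    od = -np.log10((image + 1.0) / 256.0)
    densities = od @ model.inverse
    return np.clip(densities, 0.0, None)


def single_stain_response(density: np.ndarray, channel: str, model: StainModel) -> np.ndarray:
    """Raw (pre-stretch) grayscale response of a single-stain density map.

    Re-renders the stain alone through Beer–Lambert and extracts the channel's
    colorspace component (see module docstring).  Monotone in density.
    """
    if channel not in STAIN_ORDER:
        raise ValueError(f"unknown channel {channel!r}")
    density = np.asarray(density, dtype=float)
    s = STAIN_ORDER.index(channel)
    dens3 = np.zeros(density.shape + (3,))
    dens3[..., s] = density
    rgb = np.clip(model.transmit(dens3), 0.0, 255.0)
    if channel == "blue":
        return 255.0 - rgb[..., 1]  # negated green
    if channel == "brown":
        return 255.0 - rgb[..., 2]  # negated blue
    # red -> CMYK magenta, naive conversion, scaled to 8-bit
    r, g, b = rgb[..., 0] / 255.0, rgb[..., 1] / 255.0, rgb[..., 2] / 255.0
    k = 1.0 - np.maximum(np.maximum(r, g), b)
    denom = 1.0 - k
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(denom > 0, (1.0 - g - k) / np.where(denom > 0, denom, 1.0), 0.0)
    return 255.0 * m


def stack_stretch_range(responses: list[np.ndarray]) -> tuple[float, float]:
    """Stack-wide (min, max) of raw responses, for the final linear stretch.

    Computed over the whole stack rather than per section so z-profiles stay
    comparable between sections.
    """
    lo = min(float(np.min(r)) for r in responses)
    hi = max(float(np.max(r)) for r in responses)
    return lo, hi


def channel_to_intensity(
    density: np.ndarray,
    channel: str,
    model: StainModel,
    stretch_range: tuple[float, float] | None = None,
    section_index: int = 0,
    pixel_size_um: float = 0.5,
) -> StainChannelImage:
    """Single-stain density map -> stretched 8-bit intensity image.

    ``stretch_range`` is the stack-wide (min, max) raw response from
    :func:`stack_stretch_range`; when omitted it is computed from this image
    alone.  A degenerate range (all-zero channel) maps to all-zero output.
    """
    raw = single_stain_response(density, channel, model)
    if stretch_range is None:
        stretch_range = (float(raw.min()), float(raw.max()))
    lo, hi = stretch_range
    if hi - lo <= 0:
        stretched = np.zeros_like(raw)
    else:
        stretched = (np.clip(raw, lo, hi) - lo) * (255.0 / (hi - lo))
    values = np.clip(np.rint(stretched), 0, 255).astype(np.uint8)
    return StainChannelImage(values, channel, section_index, pixel_size_um)
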