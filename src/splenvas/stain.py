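"""Optical-density stain model shared by the phantom renderer and the unmixer.

Brightfield immunohistochemistry obeys the Beer–Lambert law: each stain *s*
attenuates transmitted light in RGB channel *c* by a factor
``10**(-A_s * M[s, c])`` where ``A_s`` is the column density of the stain
along the optical path and ``M`` is a matrix whose rows are unit
optical-density vectors.  Separating mixed stains ("color deconvolution")
amounts to inverting ``M`` in OD space.

The forward/inverse pair used throughout the package is

    transmitted  I_c = 256 * 10**(-sum_s A_s M[s, c]) - 1
    OD_c         = -log10((I_c + 1) / 256)

so that unstained pixels map exactly to the 255 white point and the round
trip is exact in floating point.  The ``+1`` offset is the conventional
guard against ``log(0)`` for saturated 8-bit pixels and is part of the
package contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Stain order used by every 3-vector / 3x3 matrix in the package.
STAIN_ORDER = ("brown", "blue", "red")

# Unit OD vectors (rows: brown DAB, alkaline-phosphatase blue, AP red).
# The DAB vector is the standard published one; the blue and red vectors are
# representative AP chromogen directions chosen for a well-conditioned matrix.
_DEFAULT_OD = np.array(
    [
        [0.26814753, 0.57031375, 0.77642715],  # DAB brown
        [0.82900000, 0.52500000, 0.19200000],  # AP blue (absorbs red/green)
        [0.21393921, 0.85112669, 0.47794022],  # AP red (absorbs green/blue)
    ]
)


def _unit_rows(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("stain OD vector with zero norm")
    return m / norms


@dataclass
class StainModel:
    """Beer–Lambert color model for a triple-stained brightfield section.

    Parameters
    ----------
    od_matrix:
        3x3 matrix, rows = unit OD vectors in the order ``(brown, blue, red)``.
    background_rgb:
        Transmitted intensity with no stain (white point), default pure white.
    concentration_scale:
        Per-structure-class OD amplitude per micrometre of optical path,
        used by the phantom renderer.
    """

    od_matrix: np.ndarray = field(default_factory=lambda: _DEFAULT_OD.copy())
    background_rgb: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )
    concentration_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.od_matrix = _unit_rows(self.od_matrix)
        self.background_rgb = np.asarray(self.background_rgb, dtype=float)
        cond = np.linalg.cond(self.od_matrix)
        if not np.isfinite(cond):
            raise ValueError("stain OD matrix is singular")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.od_matrix)

    def transmit(self, densities: np.ndarray) -> np.ndarray:
        """Forward Beer–Lambert: stain column densities -> float RGB.

        ``densities`` has shape ``(..., 3)`` in :data:`STAIN_ORDER`; the
        result has shape ``(..., 3)`` in RGB, in ``[0, background]``.
        """
        densities = np.asarray(densities, dtype=float)
        od = densities @ self.od_matrix
        bg = self.background_rgb
        return (bg + 1.0) * np.power(10.0, -od) - 1.0

    def optical_density(self, rgb: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`transmit` up to the OD stage (per-channel OD)."""
        rgb = np.asarray(rgb, dtype=float)
        bg = self.background_rgb
        return -np.log10((rgb + 1.0) / (bg + 1.0))


def default_stain_model() -> StainModel:
    """The package-wide default stain model (DAB brown / AP blue / AP red)."""
    return StainModel()
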