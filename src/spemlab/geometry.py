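"""Screen geometry and physical-unit conversions.

The pursuit task is defined in pixel coordinates on a known display, but the
colocality ball radii are specified in millimetres.  :class:`ScreenGeometry`
owns the mm <-> px conversion, assuming square pixels, so that metric radii
can be mapped onto the pixel lattice.

Coordinate convention (documentation only -- all trajectory math is
orientation-agnostic): origin at the top-left corner, x rightward,
y downward, 0-based pixel indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScreenGeometry", "STUDY_GEOMETRY", "mm_to_px", "px_to_mm"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of the stimulus display.

    Parameters
    ----------
    width_px, height_px
        Display resolution in pixels.
    diagonal_mm
        Physical diagonal of the panel in millimetres (a 14-inch panel is
        355.6 mm).
    viewing_distance_mm
        Eye-to-screen distance in millimetres; kept for completeness (visual
        angle computations), not used by the trajectory indices.
    """

    width_px: int = 1366
    height_px: int = 768
    diagonal_mm: float = 355.6
    viewing_distance_mm: float = 500.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen resolution must be positive")
        if self.diagonal_mm <= 0:
            raise ValueError("diagonal_mm must be positive")
        if self.viewing_distance_mm <= 0:
            raise ValueError("viewing_distance_mm must be positive")

    @property
    def mm_per_px(self) -> float:
        """Pixel pitch in mm, assuming square pixels."""
        return self.diagonal_mm / math.hypot(self.width_px, self.height_px)

    def mm_to_px(self, length_mm: float) -> float:
        if length_mm < 0:
            raise ValueError(f"length_mm must be >= 0, got {length_mm}")
        return length_mm / self.mm_per_px

    def px_to_mm(self, length_px: float) -> float:
        if length_px < 0:
            raise ValueError(f"length_px must be >= 0, got {length_px}")
        return length_px * self.mm_per_px

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width_px - 1 and 0 <= y <= self.height_px - 1


#: Geometry of the study display: 14" panel, 1366x768, viewed at 50 cm.
STUDY_GEOMETRY = ScreenGeometry()


def mm_to_px(length_mm: float, geometry: ScreenGeometry) -> float:
    """Convert a physical length to pixels on ``geometry``."""
    return geometry.mm_to_px(length_mm)


def px_to_mm(length_px: float, geometry: ScreenGeometry) -> float:
    """Convert a pixel length to millimetres on ``geometry``."""
    return geometry.px_to_mm(length_px)
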