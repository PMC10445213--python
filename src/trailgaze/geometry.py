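"""Screen geometry and pixel/degree coordinate conversion.

Two coordinate systems are used throughout:

* **pixel space** — 0-based, origin at the top-left screen corner, y grows
  downward.  This is how gaze samples and clicks are stored at rest.
* **degree space** — origin at the screen center, y grows upward, units are
  degrees of visual angle.  Each axis is converted independently via
  ``angle = arctan(offset_cm / viewing_distance_cm)``, so the mapping is
  exact (not small-angle) and invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "DEFAULT_GEOMETRY",
    "pixels_to_degrees",
    "degrees_to_pixels",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display setup: resolution, physical size, viewing distance.

    Defaults mirror a 1024x768 px CRT of 36x27 cm viewed at 71 cm from a
    chin rest, the setup the scoring thresholds in this package assume.
    """

    width_px: int = 1024
    height_px: int = 768
    width_cm: float = 36.0
    height_cm: float = 27.0
    viewing_distance_cm: float = 71.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    # -- scalar/array axis conversions ------------------------------------

    def x_px_to_deg(self, x_px):
        off_cm = (np.asarray(x_px, dtype=float) - self.width_px / 2) * (self.width_cm / self.width_px)
        return np.degrees(np.arctan(off_cm / self.viewing_distance_cm))

    def y_px_to_deg(self, y_px):
        # pixel y grows downward; degree y grows upward
        off_cm = (self.height_px / 2 - np.asarray(y_px, dtype=float)) * (self.height_cm / self.height_px)
        return np.degrees(np.arctan(off_cm / self.viewing_distance_cm))

    def x_deg_to_px(self, x_deg):
        off_cm = self.viewing_distance_cm * np.tan(np.radians(np.asarray(x_deg, dtype=float)))
        return off_cm * (self.width_px / self.width_cm) + self.width_px / 2

    def y_deg_to_px(self, y_deg):
        off_cm = self.viewing_distance_cm * np.tan(np.radians(np.asarray(y_deg, dtype=float)))
        return self.height_px / 2 - off_cm * (self.height_px / self.height_cm)

    # -- linear (small-angle) extents, used for layout feasibility ---------

    @property
    def width_deg_linear(self) -> float:
        return float(np.degrees(self.width_cm / self.viewing_distance_cm))

    @property
    def height_deg_linear(self) -> float:
        return float(np.degrees(self.height_cm / self.viewing_distance_cm))


DEFAULT_GEOMETRY = ScreenGeometry()


def _convert_frame(samples: pd.DataFrame, fx, fy, unit: str) -> pd.DataFrame:
    out = samples.copy()
    out["x"] = fx(samples["x"].to_numpy())
    out["y"] = fy(samples["y"].to_numpy())
    out.attrs["unit"] = unit
    return out


def pixels_to_degrees(samples: pd.DataFrame, geometry: ScreenGeometry = DEFAULT_GEOMETRY) -> pd.DataFrame:
    """Convert a sample frame (columns ``x``, ``y`` in pixels) to degrees.

    The returned frame carries ``attrs['unit'] == 'deg'``.
    """
    if samples.attrs.get("unit", "px") == "deg":
        raise ValueError("samples already in degrees")
    return _convert_frame(samples, geometry.x_px_to_deg, geometry.y_px_to_deg, "deg")


def degrees_to_pixels(samples: pd.DataFrame, geometry: ScreenGeometry = DEFAULT_GEOMETRY) -> pd.DataFrame:
    """Inverse of :func:`pixels_to_degrees`."""
    if samples.attrs.get("unit", "deg") == "px":
        raise ValueError("samples already in pixels")
    return _convert_frame(samples, geometry.x_deg_to_px, geometry.y_deg_to_px, "px")
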