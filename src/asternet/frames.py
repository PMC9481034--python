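"""Calibrated 2D intensity frames.

The analysis treats the bundle network as two-dimensional: axial extent of
the imaged structures is one to two vertex spacings, so a single focal plane
captures the topology. All geometry downstream is expressed in micrometres;
the frame carries the μm-per-pixel calibration that converts.

Coordinate convention: x increases to the right (columns), y increases
downward (rows), with the origin at the centre of the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["ImageFrame"]


@dataclass
class ImageFrame:
    """A single-channel fluorescence image with physical calibration.

    Parameters
    ----------
    intensities
        2D array of non-negative pixel values (arbitrary counts).
    pixel_size_um
        Physical side length of one pixel in micrometres; must be > 0.
    """

    intensities: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ConfigurationError(
                f"expected a 2D intensity grid, got ndim={self.intensities.ndim}"
            )
        if not self.pixel_size_um > 0:
            raise ConfigurationError(
                f"pixel_size_um must be positive, got {self.pixel_size_um}"
            )
        if self.intensities.size and float(self.intensities.min()) < 0:
            raise ConfigurationError("intensities must be non-negative")

    @property
    def height_px(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.intensities.shape[1])

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um * 1e-6

    def crop_um(self, x0: float, y0: float, x1: float, y1: float) -> "ImageFrame":
        """Return the sub-frame covering [x0, x1] × [y0, y1] (μm)."""
        p = self.pixel_size_um
        c0, c1 = max(0, int(round(x0 / p))), min(self.width_px, int(round(x1 / p)))
        r0, r1 = max(0, int(round(y0 / p))), min(self.height_px, int(round(y1 / p)))
        if c1 <= c0 or r1 <= r0:
            raise ConfigurationError("empty crop window")
        return ImageFrame(self.intensities[r0:r1, c0:c1].copy(), p)

    def central_crop_um(self, width_um: float, height_um: float) -> "ImageFrame":
        """Return a centred crop of the given physical size (μm)."""
        cx, cy = self.width_um / 2, self.height_um / 2
        return self.crop_um(
            cx - width_um / 2, cy - height_um / 2, cx + width_um / 2, cy + height_um / 2
        )
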