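"""In-memory container for MSI datacubes.

A dataset is a grid of per-pixel TOF profile spectra sharing one m/z axis
(continuous-mode storage). Pixel coordinates follow the imzML convention:
1-based integer (x, y) indices; micron-space geometry uses pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MSIDataset"]


@dataclass
class MSIDataset:
    """Grid of per-pixel spectra.

    Parameters
    ----------
    mz : strictly increasing shared m/z axis (Da).
    intensities : (n_pixels, n_mz) array of raw counts, >= 0.
    coords : (n_pixels, 2) integer array of 1-based (x, y) pixel indices.
    pixel_size_um : edge length of one pixel in microns.
    """

    mz: np.ndarray
    intensities: np.ndarray
    coords: np.ndarray
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.intensities.shape != (len(self.coords), len(self.mz)):
            raise ValueError("intensities shape inconsistent with coords/mz")
        if self.coords.min() < 1:
            raise ValueError("pixel coordinates are 1-based")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx) extent of the pixel grid."""
        return int(self.coords[:, 1].max()), int(self.coords[:, 0].max())

    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2

    def to_image(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter one value per pixel into a (ny, nx) image."""
        values = np.asarray(values)
        ny, nx = self.grid_shape
        img = np.full((ny, nx), fill, dtype=values.dtype if values.dtype.kind == "f" else float)
        img[self.coords[:, 1] - 1, self.coords[:, 0] - 1] = values
        return img
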