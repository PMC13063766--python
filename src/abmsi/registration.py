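"""Landmark registration of fluorescence deposit masks to the MSI grid,
and deposit morphometry (areas, tissue densities).

Fluorescence microscopy localises amyloid deposits (LCO-stained plaques and
neurofibrillary tangles) at higher optical resolution than the 20 um MSI
raster. An affine transform fitted to matched landmark pairs maps the binary
deposit masks onto the MSI grid (nearest-neighbour resampling preserves
binarity); connected-component labelling then yields per-deposit areas, and
counts are normalised per 1,000,000 um^2 of tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import FOUR_CONNECTED

__all__ = [
    "LandmarkSet",
    "AffineTransform",
    "DepositMask",
    "DepositObject",
    "UnderdeterminedError",
    "fit_affine",
    "apply_transform",
    "label_deposits",
    "deposit_density",
]


class UnderdeterminedError(ValueError):
    """Fewer than three non-collinear landmark pairs."""


@dataclass
class LandmarkSet:
    """Matched (fluorescence, MSI) coordinate pairs in microns."""

    src: np.ndarray  # (n, 2) fluorescence-space points
    dst: np.ndarray  # (n, 2) MSI-space points

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.float64)
        self.dst = np.asarray(self.dst, dtype=np.float64)
        if self.src.shape != self.dst.shape or self.src.ndim != 2 or self.src.shape[1] != 2:
            raise ValueError("landmarks must be matched (n, 2) arrays")
        if len(np.unique(self.src, axis=0)) != len(self.src):
            raise ValueError("duplicate source landmarks")

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls(
            src=df[["src_x_um", "src_y_um"]].to_numpy(),
            dst=df[["dst_x_um", "dst_y_um"]].to_numpy(),
        )

    def __len__(self) -> int:
        return len(self.src)


@dataclass(frozen=True)
class AffineTransform:
    """x_msi = A @ x_fluor + t (microns)."""

    A: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", np.asarray(self.A, dtype=np.float64))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=np.float64))
        if self.A.shape != (2, 2) or self.t.shape != (2,):
            raise ValueError("affine transform needs a 2x2 matrix and 2-vector")
        if abs(np.linalg.det(self.A)) < 1e-12:
            raise ValueError("linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.A.T + self.t

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform(A=Ainv, t=-Ainv @ self.t)


@dataclass
class DepositMask:
    """Binary single-channel deposit raster (one kind per mask)."""

    mask: np.ndarray
    pixel_size_um: float
    kind: str = "plaque"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class DepositObject:
    object_id: int
    kind: str
    area_um2: float
    centroid_um: tuple[float, float]


def fit_affine(landmarks: LandmarkSet) -> tuple[AffineTransform, float]:
    """Least-squares affine fit; returns the transform and the RMS residual
    (microns, root of the mean squared target-space distance)."""
    n = len(landmarks)
    if n < 3:
        raise UnderdeterminedError("affine fit needs at least 3 landmark pairs")
    src = landmarks.src
    # collinearity check: rank of centred source cloud
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
        raise UnderdeterminedError("landmarks are collinear")
    design = np.column_stack([src, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, landmarks.dst, rcond=None)
    A = coef[:2].T
    t = coef[2]
    transform = AffineTransform(A=A, t=t)
    resid = landmarks.dst - transform.apply(src)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return transform, rms


def apply_transform(
    transform: AffineTransform,
    mask: DepositMask,
    target_shape: tuple[int, int],
    target_pixel_size_um: float,
) -> DepositMask:
    """Resample a fluorescence mask onto the MSI grid.

    Every target (MSI) pixel center is mapped back through the inverse
    transform and sampled nearest-neighbour from the source raster, which
    preserves binarity. A mask that lands fully outside the target grid
    yields an empty mask with a warning.
    """
    ny, nx = target_shape
    inv = transform.inverse()
    xs = (np.arange(nx) + 0.5) * target_pixel_size_um
    ys = (np.arange(ny) + 0.5) * target_pixel_size_um
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    src_pts = inv.apply(pts)
    col = np.floor(src_pts[:, 0] / mask.pixel_size_um).astype(int)
    row = np.floor(src_pts[:, 1] / mask.pixel_size_um).astype(int)
    inside = (
        (row >= 0) & (row < mask.mask.shape[0]) & (col >= 0) & (col < mask.mask.shape[1])
    )
    out = np.zeros(ny * nx, dtype=bool)
    out[inside] = mask.mask[row[inside], col[inside]]
    out = out.reshape(ny, nx)
    if mask.mask.any() and not out.any():
        warnings.warn("transformed mask falls outside the target grid; empty result")
    return DepositMask(mask=out, pixel_size_um=target_pixel_size_um, kind=mask.kind)


def label_deposits(
    mask: DepositMask, kind: str | None = None, min_pixels: int = 1
) -> list[DepositObject]:
    """4-connected components of a binary mask as deposit objects."""
    labeled, n_obj = ndimage.label(mask.mask, structure=FOUR_CONNECTED)
    kind = kind or mask.kind
    objects = []
    next_id = 1
    px_area = mask.pixel_size_um**2
    for obj in range(1, n_obj + 1):
        ys, xs = np.nonzero(labeled == obj)
        if len(ys) < min_pixels:
            continue
        objects.append(
            DepositObject(
                object_id=next_id,
                kind=kind,
                area_um2=len(ys) * px_area,
                centroid_um=(
                    float((xs + 0.5).mean() * mask.pixel_size_um),
                    float((ys + 0.5).mean() * mask.pixel_size_um),
                ),
            )
        )
        next_id += 1
    return objects


def deposit_density(objects: list[DepositObject], tissue_area_um2: float) -> float:
    """Deposit count per 1,000,000 um^2 of tissue."""
    if tissue_area_um2 <= 0:
        raise ValueError("tissue area must be positive")
    return len(objects) / tissue_area_um2 * 1e6


def objects_to_frame(objects: list[DepositObject]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": o.object_id,
                "kind": o.kind,
                "area_um2": o.area_um2,
                "centroid_x_um": o.centroid_um[0],
                "centroid_y_um": o.centroid_um[1],
            }
            for o in objects
        ],
        columns=["id", "kind", "area_um2", "centroid_x_um", "centroid_y_um"],
    )
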