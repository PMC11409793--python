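"""Reference-plane geometry and the through-plane parallel-slice scheme.

A finite slice thickness is discretized into ``num`` parallel slices on
each side of the reference plane, spaced ``dist`` millimetres apart along
the plane normal:

    num  = round(slice_thickness / (2 * z_res))
    dist = slice_thickness / (2 * num)          (num > 0)

where ``z_res`` is the 3D volume's inter-slice spacing. The resulting
signed offsets ``k * dist`` for k = -num..num span exactly
[-thickness/2, +thickness/2]. A thickness of 0 mm collapses the scheme to
the single central slice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dicom_io import SliceHeader

__all__ = [
    "ReferencePlane",
    "ParallelSliceStack",
    "plane_from_header",
    "pixel_centers",
    "build_parallel_stack",
    "round_half_away",
]

MAX_THICKNESS_MM = 99.99


def round_half_away(x):
    """Round to nearest integer, ties away from zero (everyday rounding)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ReferencePlane:
    """An oriented, pixelated plane in patient space (mm, LPS).

    ``origin`` is the center of pixel (0, 0); ``normal_cosine`` is
    ``row_cosine x col_cosine``.
    """

    origin: np.ndarray
    row_cosine: np.ndarray
    col_cosine: np.ndarray
    normal_cosine: np.ndarray
    pixel_spacing: tuple[float, float]
    rows: int
    cols: int

    def __post_init__(self) -> None:
        n = self.normal_cosine
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("normal_cosine is not a unit vector")
        if abs(float(np.dot(n, self.row_cosine))) > 1e-6 or abs(
            float(np.dot(n, self.col_cosine))
        ) > 1e-6:
            raise ValueError("normal_cosine is not orthogonal to the in-plane cosines")


@dataclass(frozen=True)
class ParallelSliceStack:
    """Through-plane sampling scheme: signed offsets along the plane normal."""

    slice_thickness: float
    num: int
    dist: float  # 0.0 when num == 0
    offsets: np.ndarray

    def __post_init__(self) -> None:
        if self.num < 0:
            raise ValueError("num must be non-negative")


def plane_from_header(header: SliceHeader) -> ReferencePlane:
    """Build the patient-space plane of a 2D reference slice."""
    normal = np.cross(header.row_cosine, header.col_cosine)
    normal = normal / np.linalg.norm(normal)
    return ReferencePlane(
        origin=np.asarray(header.position, float),
        row_cosine=np.asarray(header.row_cosine, float),
        col_cosine=np.asarray(header.col_cosine, float),
        normal_cosine=normal,
        pixel_spacing=(header.pixel_spacing_row, header.pixel_spacing_col),
        rows=header.rows,
        cols=header.cols,
    )


def pixel_centers(plane: ReferencePlane) -> np.ndarray:
    """Patient-space centers of all pixels, shape (rows, cols, 3).

    center(i, j) = origin + i*spacing_row*row_cosine + j*spacing_col*col_cosine
    """
    i = np.arange(plane.rows)[:, None, None]
    j = np.arange(plane.cols)[None, :, None]
    return (
        plane.origin[None, None, :]
        + i * plane.pixel_spacing[0] * plane.row_cosine[None, None, :]
        + j * plane.pixel_spacing[1] * plane.col_cosine[None, None, :]
    )


def build_parallel_stack(slice_thickness: float, z_res: float) -> ParallelSliceStack:
    """Discretize a slice thickness into symmetric parallel-slice offsets.

    ``slice_thickness`` must lie in [0, 99.99] mm. A positive thickness
    smaller than the volume's slice spacing rounds to ``num == 0`` and is
    treated like 0 mm (single central slice); a warning is emitted since
    the requested thickness is then not actually integrated over.
    """
    if not (0.0 <= slice_thickness <= MAX_THICKNESS_MM):
        raise ValueError(
            f"slice thickness must be between 0 mm and {MAX_THICKNESS_MM} mm, "
            f"got {slice_thickness}"
        )
    if z_res <= 0:
        raise ValueError("z_res must be positive")
    num = int(math.floor(slice_thickness / (2.0 * z_res) + 0.5))
    if num == 0:
        if slice_thickness > 0:
            warnings.warn(
                f"slice thickness {slice_thickness} mm is below the volume's "
                f"slice spacing {z_res} mm; falling back to a single central "
                "slice (0 mm behaviour)",
                stacklevel=2,
            )
        return ParallelSliceStack(slice_thickness, 0, 0.0, np.array([0.0]))
    dist = slice_thickness / (2.0 * num)
    offsets = np.arange(-num, num + 1, dtype=float) * dist
    return ParallelSliceStack(slice_thickness, num, dist, offsets)
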