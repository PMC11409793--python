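"""Synthetic validation and test phantoms.

``generate_validation_dataset`` builds the artificial validation cube: an
11x11x11 volume at 1 mm isotropic resolution with the iso-center at the
volume midpoint. The value is constant along x and y and decreases
linearly along z from 100 at the center by 20 per mm to 0 at both
borders. Three 11x11 reference slices probe it:

* ``parplane`` — parallel to the x-y plane at z = 0 (1 mm in-plane);
* ``perplane`` — parallel to the x-z plane at y = 0 (1 mm in-plane);
* ``diagplane`` — tilted 45 degrees in the y-z plane through the
  iso-center (1 mm x sqrt(2) mm in-plane).

All three carry a 2 mm slice-thickness tag. Because the value law is
piecewise linear with breakpoints only on grid planes, reformatted values
under a rectangular profile can be computed in closed form by hand;
``expected_values_oracle`` does exactly that, sharing no interpolation
code with the reslicing pipeline.

``generate_edge_phantom`` is a synthetic stand-in for clinical 3D LGE
acquisitions: a two-compartment volume separated by a sharp oblique
planar boundary on an isotropic 1.25 mm grid, used to study how slice
thickness and profile blur an edge.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
from pydicom.uid import generate_uid

from . import dicom_io
from .dicom_io import SliceHeader, VolumeGrid
from .geometry import round_half_away

__all__ = [
    "ValidationDataset",
    "generate_validation_dataset",
    "expected_values_oracle",
    "generate_edge_phantom",
    "edge_reference_header",
    "VALIDATION_PLANES",
    "VALIDATION_THICKNESSES",
]

VALIDATION_PLANES = ("parplane", "perplane", "diagplane")
VALIDATION_THICKNESSES = (0.0, 2.0, 2.82, 4.23)

_N = 11  # positions per axis
_HALF = (_N - 1) // 2  # iso-center index offset: grid spans -5..5 mm


def _value_law(z: np.ndarray) -> np.ndarray:
    """Phantom intensity at height z (mm): 100 at z=0, -20 per mm, 0 at |z|=5."""
    return np.maximum(0.0, 100.0 - 20.0 * np.abs(z))


@dataclass
class ValidationDataset:
    volume: VolumeGrid
    parplane: SliceHeader
    perplane: SliceHeader
    diagplane: SliceHeader

    def plane(self, name: str) -> SliceHeader:
        if name not in VALIDATION_PLANES:
            raise ValueError(f"unknown plane {name!r}; valid: {VALIDATION_PLANES}")
        return getattr(self, name)


def _plane_readout(name: str) -> np.ndarray:
    """Direct 11x11 volume readout at a validation plane (0 mm behaviour)."""
    j = np.arange(_N)
    if name == "parplane":
        return np.full((_N, _N), 100.0)
    # perplane: column index j walks z; diagplane: j walks the y-z diagonal
    return np.tile(_value_law(j - _HALF), (_N, 1))


def generate_validation_dataset(out_dir: str | os.PathLike | None = None) -> ValidationDataset:
    """Build the artificial validation cube and its three reference slices.

    When ``out_dir`` is given, the volume is additionally written as a
    DICOM series (``volume/slice_###.dcm``) and each reference slice as a
    single DICOM file (``<plane>.dcm``), all readable through
    :mod:`reslice3d2d.dicom_io`. The reference files carry the 0 mm
    readout as pixel data.
    """
    z = np.arange(_N) - _HALF
    values = np.broadcast_to(_value_law(z)[None, None, :], (_N, _N, _N)).copy()
    study_uid = generate_uid()
    vol_series_uid = generate_uid()
    volume = VolumeGrid(
        values=values,
        origin=np.array([-5.0, -5.0, -5.0]),
        row_cosine=np.array([1.0, 0.0, 0.0]),
        col_cosine=np.array([0.0, 1.0, 0.0]),
        normal_cosine=np.array([0.0, 0.0, 1.0]),
        spacing=(1.0, 1.0, 1.0),
        series_uid=vol_series_uid,
        series_number=101,
        study_uid=study_uid,
    )

    s2 = 1.0 / math.sqrt(2.0)
    headers = {}
    plane_defs = {
        # name: (origin, row_cosine, col_cosine, (spacing_row, spacing_col), series number)
        "parplane": ([-5.0, -5.0, 0.0], [1, 0, 0], [0, 1, 0], (1.0, 1.0), 201),
        "perplane": ([-5.0, 0.0, -5.0], [1, 0, 0], [0, 0, 1], (1.0, 1.0), 202),
        "diagplane": ([-5.0, -5.0, -5.0], [1, 0, 0], [0, s2, s2], (1.0, math.sqrt(2.0)), 203),
    }
    for name, (origin, row, col, spacing, number) in plane_defs.items():
        headers[name] = SliceHeader(
            position=np.array(origin, float),
            row_cosine=np.array(row, float),
            col_cosine=np.array(col, float),
            pixel_spacing_row=spacing[0],
            pixel_spacing_col=spacing[1],
            rows=_N,
            cols=_N,
            slice_thickness=2.0,
            series_uid=generate_uid(),
            sop_uid=generate_uid(),
            study_uid=study_uid,
            series_number=number,
        )

    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        vol_dir = os.path.join(out_dir, "volume")
        os.makedirs(vol_dir, exist_ok=True)
        for k in range(_N):
            dicom_io.write_slice(
                os.path.join(vol_dir, f"slice_{k:03d}.dcm"),
                values[:, :, k],
                position=volume.origin + k * volume.normal_cosine,
                row_cosine=volume.row_cosine,
                col_cosine=volume.col_cosine,
                pixel_spacing=(1.0, 1.0),
                series_uid=vol_series_uid,
                study_uid=study_uid,
                series_number=101,
                instance_number=k + 1,
                slice_thickness=1.0,
                series_description="validation cube",
            )
        for name, h in headers.items():
            dicom_io.write_slice(
                os.path.join(out_dir, f"{name}.dcm"),
                _plane_readout(name),
                position=h.position,
                row_cosine=h.row_cosine,
                col_cosine=h.col_cosine,
                pixel_spacing=(h.pixel_spacing_row, h.pixel_spacing_col),
                series_uid=h.series_uid,
                study_uid=study_uid,
                sop_uid=h.sop_uid,
                series_number=h.series_number,
                instance_number=1,
                slice_thickness=h.slice_thickness,
                series_description=f"validation {name}",
            )

    return ValidationDataset(volume=volume, **headers)


def _oracle_stack(thickness: float) -> np.ndarray:
    """num/dist discretization evaluated by hand for the 1 mm phantom grid."""
    num = int(math.floor(thickness / 2.0 + 0.5))
    if num == 0:
        return np.array([0.0])
    dist = thickness / (2.0 * num)
    return np.arange(-num, num + 1, dtype=float) * dist


def expected_values_oracle(plane: str, thickness: float) -> np.ndarray:
    """Hand-calculated rectangular-profile expectation for a validation slice.

    Evaluates the closed-form value law 100 - 20*|z| at every sample
    location of the parallel-slice scheme and averages the samples that
    fall inside the cube (|x|, |y|, |z| <= 5 mm), rounding half away from
    zero — entirely independent of the reslicing pipeline.
    """
    if plane not in VALIDATION_PLANES:
        raise ValueError(f"unsupported plane {plane!r}; valid: {VALIDATION_PLANES}")
    if not any(abs(thickness - t) < 1e-12 for t in VALIDATION_THICKNESSES):
        raise ValueError(
            f"unsupported thickness {thickness}; valid: {VALIDATION_THICKNESSES}"
        )
    offsets = _oracle_stack(thickness)
    s2 = 1.0 / math.sqrt(2.0)
    out = np.zeros((_N, _N))
    eps = 1e-9
    for i in range(_N):
        for j in range(_N):
            acc = 0.0
            n_valid = 0
            for off in offsets:
                if plane == "parplane":
                    x, y, z = i - 5.0, j - 5.0, off
                elif plane == "perplane":
                    x, y, z = i - 5.0, -off, j - 5.0
                else:  # diagplane: in-plane (1, sqrt2), normal (0,-1,1)/sqrt2
                    x = i - 5.0
                    y = (j - 5.0) - off * s2
                    z = (j - 5.0) + off * s2
                if abs(x) <= 5 + eps and abs(y) <= 5 + eps and abs(z) <= 5 + eps:
                    acc += 100.0 - 20.0 * abs(z)
                    n_valid += 1
            out[i, j] = float(round_half_away(acc / n_valid)) if n_valid else 0.0
    return out


def generate_edge_phantom(
    size: int = 48,
    edge_axis: int = 0,
    n_slices: int | None = None,
    seed: int = 0,
    noise_sigma: float = 25.0,
    tilt: float = 0.4,
) -> VolumeGrid:
    """Two-compartment edge phantom on an isotropic 1.25 mm grid.

    A sharp planar boundary separates a bright compartment (600) from a
    dark one (100); the boundary normal points mainly along ``edge_axis``
    but is tilted obliquely against all three grid axes — in particular
    by ``tilt`` into the slice direction — so that reslicing with
    increasing thickness smears the edge across several pixels. Gaussian
    noise (``noise_sigma``, default SNR about 24 for the bright
    compartment) adds the broadband texture of a real acquisition.
    Deterministic for a fixed ``seed``.
    """
    if size < 8 or (n_slices is not None and n_slices < 8):
        raise ValueError("edge phantom requires at least 8 positions per axis")
    if edge_axis not in (0, 1, 2):
        raise ValueError("edge_axis must be 0, 1 or 2")
    n_slices = size if n_slices is None else n_slices
    shape = (size, size, n_slices)
    spacing = 1.25
    origin = -np.array([(n - 1) * spacing / 2.0 for n in shape])

    boundary_normal = np.zeros(3)
    boundary_normal[edge_axis] = 1.0
    boundary_normal[(edge_axis + 1) % 3] += 0.25
    boundary_normal[(edge_axis + 2) % 3] += tilt
    boundary_normal /= np.linalg.norm(boundary_normal)

    coords = np.stack(
        np.meshgrid(
            origin[0] + spacing * np.arange(shape[0]),
            origin[1] + spacing * np.arange(shape[1]),
            origin[2] + spacing * np.arange(shape[2]),
            indexing="ij",
        ),
        axis=-1,
    )
    signed = np.tensordot(coords, boundary_normal, axes=([-1], [0]))
    values = np.where(signed < 0, 600.0, 100.0)
    rng = np.random.default_rng(seed)
    values = values + rng.normal(0.0, noise_sigma, size=shape)

    return VolumeGrid(
        values=values,
        origin=origin,
        row_cosine=np.array([1.0, 0.0, 0.0]),
        col_cosine=np.array([0.0, 1.0, 0.0]),
        normal_cosine=np.array([0.0, 0.0, 1.0]),
        spacing=(spacing, spacing, spacing),
        series_uid=f"2.25.777.{seed % 2**31}.1",
        series_number=301,
        study_uid=f"2.25.777.{seed % 2**31}.0",
    )


def edge_reference_header(
    volume: VolumeGrid, rows: int = 40, cols: int = 40, thickness_tag: float = 7.0
) -> SliceHeader:
    """An axial reference slice through the center of the edge phantom.

    Mimics a midventricular 2D acquisition: same in-plane spacing as the
    volume, a nominal slice-thickness tag (default 7 mm), positioned so
    the slice center coincides with the volume center.
    """
    sp = volume.spacing[0]
    center = volume.origin + volume.normal_cosine * (
        (volume.values.shape[2] - 1) * volume.spacing[2] / 2.0
    ) + volume.row_cosine * ((volume.values.shape[0] - 1) * volume.spacing[0] / 2.0) + (
        volume.col_cosine * ((volume.values.shape[1] - 1) * volume.spacing[1] / 2.0)
    )
    origin = (
        center
        - volume.row_cosine * sp * (rows - 1) / 2.0
        - volume.col_cosine * sp * (cols - 1) / 2.0
    )
    return SliceHeader(
        position=origin,
        row_cosine=volume.row_cosine,
        col_cosine=volume.col_cosine,
        pixel_spacing_row=sp,
        pixel_spacing_col=sp,
        rows=rows,
        cols=cols,
        slice_thickness=thickness_tag,
        series_uid=generate_uid(),
        sop_uid=generate_uid(),
        study_uid=volume.study_uid or generate_uid(),
        series_number=401,
    )
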