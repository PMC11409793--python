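"""The two-step reformatting interpolation.

Step 1 (in-plane / through-plane sampling): the 3D volume is sampled by
trilinear interpolation at every reference pixel center, repeated at the
parallel-slice offsets along the plane normal, giving a stack of values
``value[i, j, k]`` for k = -num..num.

Step 2 (totalization): the stack is collapsed with slice-profile weights
w_k = w(k/num),

    value[i, j] = round( sum_k w_k * value[i, j, k] / sum_k w_k )

Samples falling outside the volume's bounding box (voxel-center
convention) are excluded from both sums, i.e. the weights are
renormalized over the valid samples; pixels with no weighted in-volume
sample at all are set to 0 and counted in ``ResliceResult.n_outside``.

Six symmetric slice profiles are available as weight functions of the
normalized offset u = k/num in [-1, 1]:

    rectangular    w(u) = 1
    triangular     w(u) = 1 - |u|
    cosine_plus_1  w(u) = cos(pi*u) + 1
    sinc           w(u) = sin(pi*u)/(pi*u),  w(0) = 1
    std_normal_2   w(u) = exp(-(2u)^2 / 2)   (Gaussian, border at 2 sigma)
    std_normal_5   w(u) = exp(-(5u)^2 / 2)   (Gaussian, border at 5 sigma)

The rectangular profile is an idealized slice; the Gaussian profiles
emulate scanner excitation profiles whose sensitivity tapers toward the
slice borders — rapidly so for ``std_normal_5``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dicom_io import SliceHeader, VolumeGrid
from .geometry import (
    ParallelSliceStack,
    ReferencePlane,
    build_parallel_stack,
    pixel_centers,
    plane_from_header,
    round_half_away,
)

__all__ = [
    "SliceProfile",
    "SampledStack",
    "ResliceResult",
    "PROFILE_NAMES",
    "get_profile",
    "profile_weights",
    "sample_stack",
    "totalize",
    "reslice",
]

#: Index-space tolerance for the inside-the-volume test; absorbs the
#: precision loss of decimal-string DICOM geometry tags.
_BOUNDS_EPS = 1e-6


@dataclass(frozen=True)
class SliceProfile:
    """A named symmetric through-plane weight function on u in [-1, 1]."""

    name: str
    weight: Callable[[np.ndarray], np.ndarray]


def _sinc(u: np.ndarray) -> np.ndarray:
    return np.sinc(u)  # np.sinc is sin(pi u)/(pi u) with value 1 at 0


_PROFILES: dict[str, SliceProfile] = {
    p.name: p
    for p in (
        SliceProfile("rectangular", lambda u: np.ones_like(u, dtype=float)),
        SliceProfile("triangular", lambda u: 1.0 - np.abs(u)),
        SliceProfile("cosine_plus_1", lambda u: np.cos(np.pi * u) + 1.0),
        SliceProfile("sinc", _sinc),
        SliceProfile("std_normal_2", lambda u: np.exp(-0.5 * (2.0 * u) ** 2)),
        SliceProfile("std_normal_5", lambda u: np.exp(-0.5 * (5.0 * u) ** 2)),
    )
}

PROFILE_NAMES: tuple[str, ...] = tuple(_PROFILES)


def get_profile(name: str | SliceProfile) -> SliceProfile:
    if isinstance(name, SliceProfile):
        return name
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown slice profile {name!r}; valid names: {', '.join(PROFILE_NAMES)}"
        ) from None


@dataclass
class SampledStack:
    """Trilinear samples over the parallel-slice stack.

    ``values`` has shape (rows, cols, 2*num+1); ``valid_mask`` marks
    samples whose patient-space location lies inside the volume.
    """

    values: np.ndarray
    valid_mask: np.ndarray


@dataclass
class ResliceResult:
    """A reformatted 2D image with its provenance.

    ``values`` holds the rounded integers clipped to the unsigned 16-bit
    export range; ``float_values`` keeps the weighted means before
    rounding (NaN where no sample fell inside the volume).
    """

    values: np.ndarray
    float_values: np.ndarray
    thickness_used: float
    profile_name: str
    source_series: str = ""
    source_series_number: int | None = None
    reference_sop: str = ""
    n_outside: int = 0


def profile_weights(profile: str | SliceProfile, num: int) -> np.ndarray:
    """Profile weights w_k = w(k/num) for k = -num..num; [1] when num == 0.

    The weights are not normalized here — normalization happens in the
    totalization denominator.
    """
    prof = get_profile(profile)
    if num < 0:
        raise ValueError("num must be non-negative")
    if num == 0:
        return np.array([1.0])
    u = np.arange(-num, num + 1, dtype=float) / num
    w = np.asarray(prof.weight(u), dtype=float)
    if np.any(w < -1e-12) or w[num] <= 0:
        raise ValueError(f"profile {prof.name!r} produced invalid weights")
    return np.clip(w, 0.0, None)


def sample_stack(
    volume: VolumeGrid, plane: ReferencePlane, stack: ParallelSliceStack
) -> SampledStack:
    """Trilinearly sample the volume at every pixel center and stack offset."""
    centers = pixel_centers(plane)  # (R, C, 3)
    pts = (
        centers[:, :, None, :]
        + stack.offsets[None, None, :, None] * plane.normal_cosine[None, None, None, :]
    )  # (R, C, K, 3)
    rel = pts - volume.origin
    # orthonormal frame: index coordinates are scaled projections
    idx = np.stack(
        [
            np.tensordot(rel, volume.row_cosine, axes=([-1], [0])) / volume.spacing[0],
            np.tensordot(rel, volume.col_cosine, axes=([-1], [0])) / volume.spacing[1],
            np.tensordot(rel, volume.normal_cosine, axes=([-1], [0])) / volume.spacing[2],
        ],
        axis=-1,
    )
    shape = np.array(volume.values.shape, dtype=float)
    valid = np.all((idx >= -_BOUNDS_EPS) & (idx <= shape - 1 + _BOUNDS_EPS), axis=-1)
    if not valid.any():
        raise ValueError("no overlap: the reference plane lies entirely outside the volume")
    interp = RegularGridInterpolator(
        tuple(np.arange(n, dtype=float) for n in volume.values.shape),
        volume.values,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    clipped = np.clip(idx, 0.0, shape - 1)
    values = interp(clipped.reshape(-1, 3)).reshape(idx.shape[:-1])
    values = np.where(valid, values, np.nan)
    return SampledStack(values=values, valid_mask=valid)


def totalize(
    samples: SampledStack,
    weights: np.ndarray,
    *,
    thickness_used: float = 0.0,
    profile_name: str = "",
    source_series: str = "",
    source_series_number: int | None = None,
    reference_sop: str = "",
) -> ResliceResult:
    """Collapse the sampled stack into one slice by the weighted mean."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (samples.values.shape[2],):
        raise ValueError(
            f"weight list length {weights.shape} does not match stack depth "
            f"{samples.values.shape[2]}"
        )
    if not np.any(weights > 0):
        raise ValueError("profile weights are identically zero")
    w = weights[None, None, :] * samples.valid_mask
    wsum = w.sum(axis=2)
    vsum = np.nansum(w * np.where(samples.valid_mask, samples.values, 0.0), axis=2)
    # A pixel contributes only where its in-volume samples carry weight.
    # Border-zero profiles (triangular, sinc) can leave a boundary pixel
    # with valid samples but zero total weight; such pixels join the
    # out-of-volume tally instead of aborting the reslice.
    usable = wsum > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        float_values = np.where(usable, vsum / np.where(usable, wsum, 1.0), np.nan)
    ints = round_half_away(np.where(usable, float_values, 0.0))
    values = np.clip(ints, 0, 65535).astype(np.int64)
    return ResliceResult(
        values=values,
        float_values=float_values,
        thickness_used=thickness_used,
        profile_name=profile_name,
        source_series=source_series,
        source_series_number=source_series_number,
        reference_sop=reference_sop,
        n_outside=int(np.count_nonzero(~usable)),
    )


def resolve_thickness(thickness: float | str, volume: VolumeGrid,
                      reference: SliceHeader) -> float:
    """Resolve a numeric thickness or one of the presets to millimetres.

    ``"reference_2d"`` uses the reference slice's own thickness tag (an
    error if the tag is absent); ``"volume_z"`` uses the volume's slice
    spacing.
    """
    if isinstance(thickness, str):
        if thickness == "reference_2d":
            if reference.slice_thickness is None:
                raise ValueError(
                    "thickness preset 'reference_2d' requires the reference "
                    "slice to carry a SliceThickness tag"
                )
            return float(reference.slice_thickness)
        if thickness == "volume_z":
            return float(volume.spacing[2])
        raise ValueError(
            f"unknown thickness preset {thickness!r}; "
            "use a number in mm, 'reference_2d' or 'volume_z'"
        )
    return float(thickness)


def reslice(
    volume: VolumeGrid,
    reference: SliceHeader,
    thickness: float | str,
    profile: str | SliceProfile = "rectangular",
) -> ResliceResult:
    """Reformat the 3D volume at the patient-space location of a 2D slice.

    ``thickness`` is the through-plane integration width in mm (0 samples
    the plane itself), or one of the presets ``"reference_2d"`` /
    ``"volume_z"``. Deterministic for fixed inputs.
    """
    thickness_mm = resolve_thickness(thickness, volume, reference)
    prof = get_profile(profile)
    plane = plane_from_header(reference)
    stack = build_parallel_stack(thickness_mm, volume.spacing[2])
    samples = sample_stack(volume, plane, stack)
    weights = profile_weights(prof, stack.num)
    return totalize(
        samples,
        weights,
        thickness_used=thickness_mm,
        profile_name=prof.name,
        source_series=volume.series_uid,
        source_series_number=volume.series_number,
        reference_sop=reference.sop_uid,
    )
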