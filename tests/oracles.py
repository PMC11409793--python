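"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately written with explicit per-point loops and
shares no interpolation or weighting code with the package.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

_EPS = 1e-6


def trilinear_point(volume, point):
    """(value, valid) of hand-rolled trilinear interpolation at one point."""
    axes = (volume.row_cosine, volume.col_cosine, volume.normal_cosine)
    frac = []
    for axis, sp, n in zip(axes, volume.spacing, volume.values.shape):
        f = float(np.dot(point - volume.origin, axis)) / sp
        if f < -_EPS or f > n - 1 + _EPS:
            return math.nan, False
        frac.append(min(max(f, 0.0), n - 1))
    base = []
    t = []
    for f, n in zip(frac, volume.values.shape):
        i0 = min(int(math.floor(f)), n - 2) if n > 1 else 0
        base.append(i0)
        t.append(f - i0)
    acc = 0.0
    for di, dj, dk in product((0, 1), repeat=3):
        w = (
            (t[0] if di else 1.0 - t[0])
            * (t[1] if dj else 1.0 - t[1])
            * (t[2] if dk else 1.0 - t[2])
        )
        acc += w * volume.values[base[0] + di, base[1] + dj, base[2] + dk]
    return acc, True


def _profile_weight(name: str, u: float) -> float:
    if name == "rectangular":
        return 1.0
    if name == "triangular":
        return 1.0 - abs(u)
    if name == "cosine_plus_1":
        return math.cos(math.pi * u) + 1.0
    if name == "sinc":
        return 1.0 if u == 0 else math.sin(math.pi * u) / (math.pi * u)
    if name == "std_normal_2":
        return math.exp(-0.5 * (2.0 * u) ** 2)
    if name == "std_normal_5":
        return math.exp(-0.5 * (5.0 * u) ** 2)
    raise ValueError(name)


def brute_force_reslice(volume, header, thickness: float, profile: str = "rectangular"):
    """Pre-rounding reformatted image by exhaustive per-pixel evaluation.

    Returns (float image with NaN where no sample is inside, out-of-volume
    pixel count).
    """
    z_res = volume.spacing[2]
    num = int(math.floor(thickness / (2.0 * z_res) + 0.5))
    offsets = (
        [0.0]
        if num == 0
        else [k * thickness / (2.0 * num) for k in range(-num, num + 1)]
    )
    weights = [1.0] if num == 0 else [_profile_weight(profile, k / num) for k in range(-num, num + 1)]
    normal = np.cross(header.row_cosine, header.col_cosine)
    normal = normal / np.linalg.norm(normal)
    out = np.full((header.rows, header.cols), np.nan)
    n_outside = 0
    for i in range(header.rows):
        for j in range(header.cols):
            center = (
                header.position
                + i * header.pixel_spacing_row * header.row_cosine
                + j * header.pixel_spacing_col * header.col_cosine
            )
            wsum = 0.0
            vsum = 0.0
            for off, w in zip(offsets, weights):
                value, ok = trilinear_point(volume, center + off * normal)
                if ok:
                    wsum += w
                    vsum += w * value
            if wsum > 0:
                out[i, j] = vsum / wsum
            else:
                n_outside += 1
    return out, n_outside


def random_volume_and_header(rng: np.random.Generator):
    """A random small volume and an overlapping oblique reference header."""
    from reslice3d2d import SliceHeader, VolumeGrid

    shape = tuple(int(n) for n in rng.integers(5, 13, size=3))
    spacing = tuple(float(s) for s in rng.uniform(0.6, 2.0, size=3))
    frame = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(frame) < 0:
        frame[:, 2] *= -1
    origin = rng.uniform(-20, 20, size=3)
    volume = VolumeGrid(
        values=rng.uniform(0, 1000, size=shape),
        origin=origin,
        row_cosine=frame[:, 0],
        col_cosine=frame[:, 1],
        normal_cosine=frame[:, 2],
        spacing=spacing,
        series_uid="2.25.900.1",
        series_number=1,
        study_uid="2.25.900.0",
    )
    center = origin + sum(
        (n - 1) / 2.0 * s * ax
        for n, s, ax in zip(shape, spacing, (frame[:, 0], frame[:, 1], frame[:, 2]))
    )
    pframe = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    rows, cols = (int(n) for n in rng.integers(4, 8, size=2))
    ps = tuple(float(s) for s in rng.uniform(0.5, 1.5, size=2))
    header = SliceHeader(
        position=center
        - (rows - 1) / 2.0 * ps[0] * pframe[:, 0]
        - (cols - 1) / 2.0 * ps[1] * pframe[:, 1],
        row_cosine=pframe[:, 0],
        col_cosine=pframe[:, 1],
        pixel_spacing_row=ps[0],
        pixel_spacing_col=ps[1],
        rows=rows,
        cols=cols,
        slice_thickness=None,
        series_uid="2.25.900.2",
        sop_uid="2.25.900.3",
        study_uid="2.25.900.0",
    )
    return volume, header
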