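"""Frequency Domain Image Blur Measure (FM).

FM scores the sharpness of an image as the fraction of its Fourier
spectrum that carries non-negligible energy. Blurring suppresses high
spatial frequencies, so fewer coefficients stay above the threshold and
FM drops. The measure is computed in six steps:

1. 2D discrete Fourier transform of the image;
2. shift the zero-frequency component to the spectrum center;
3. take the magnitudes;
4. M = maximum magnitude;
5. count the coefficients with magnitude strictly greater than M/1000;
6. FM = count / (rows * cols).

FM lies in (0, 1]: a constant image scores 1/(rows*cols) (only the DC
term survives) and a single-pixel impulse scores 1 (flat spectrum). The
measure is invariant to multiplying the image by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FMResult", "compute_fm"]

#: Denominator of the spectral threshold M/1000.
THRESHOLD_DIVISOR = 1000.0


@dataclass(frozen=True)
class FMResult:
    fm: float
    threshold: float
    above_count: int


def compute_fm(image: np.ndarray) -> FMResult:
    """Compute the Frequency Domain Image Blur Measure of a 2D image."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("FM requires a 2D image with at least 2x2 pixels")
    if not np.all(np.isfinite(image)):
        raise ValueError("FM requires finite image values")
    spectrum = np.fft.fftshift(np.fft.fft2(image))
    magnitude = np.abs(spectrum)
    peak = float(magnitude.max())
    threshold = peak / THRESHOLD_DIVISOR
    above = int(np.count_nonzero(magnitude > threshold))
    return FMResult(fm=above / image.size, threshold=threshold, above_count=above)
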