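"""Frequency warping between Hertz and the Bark psycho-acoustical scale.

Hearing thresholds are modeled as smooth functions of *perceptual* frequency
distance, not of raw Hertz.  All Gaussian-process computation in this package
therefore happens on the Bark scale; physical frequencies in Hz appear only at
the I/O boundaries.  The warping used is the simple analytic form

    bark(f) = 6 * asinh(f / 600),

which is invertible in closed form as ``600 * sinh(x / 6)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STANDARD_FREQUENCIES_HZ",
    "bark",
    "bark_inverse",
    "standard_grid_bark",
    "BARK_CENTER",
]

#: The standard audiometric frequency grid (Hz) on which audiograms are tabulated.
STANDARD_FREQUENCIES_HZ = np.array(
    [125.0, 250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0, 6000.0, 8000.0]
)


def bark(f):
    """Map physical frequency (Hz) to the Bark scale.

    Parameters
    ----------
    f : float or array_like
        Frequency in Hz; must be non-negative.

    Returns
    -------
    float or ndarray
        Transformed frequency in Bark, ``6 * asinh(f / 600)``.  Strictly
        increasing and concave in ``f``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative (Hz)")
    out = 6.0 * np.arcsinh(f / 600.0)
    return out.item() if out.ndim == 0 else out


def bark_inverse(x):
    """Map a Bark-scale frequency back to Hz (exact inverse of :func:`bark`)."""
    x = np.asarray(x, dtype=float)
    out = 600.0 * np.sinh(x / 6.0)
    return out.item() if out.ndim == 0 else out


def standard_grid_bark() -> np.ndarray:
    """The standard audiometric grid in Bark units."""
    return bark(STANDARD_FREQUENCIES_HZ)


#: Midpoint of the standard grid in Bark; polynomial mean functions are
#: expressed in powers of (x - BARK_CENTER) to keep their coefficients
#: well-scaled during optimization.
BARK_CENTER = float((bark(125.0) + bark(8000.0)) / 2.0)
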