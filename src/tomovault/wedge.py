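"""Binary missing-wedge masks in Fourier space.

The tilt axis is the volume y axis: a tilt range of +/- ``halfangle`` about y
leaves Fourier space sampled wherever the in-plane direction of (fx, fz) lies
within ``halfangle`` of the fx axis, independent of fy.  ``halfangle = 90``
keeps everything (no wedge).
"""

from __future__ import annotations

import numpy as np


def missing_wedge_mask(shape: tuple[int, int, int],
                       halfangle_deg: float) -> np.ndarray:
    """Binary Fourier mask (1 = measured) for a ``[z, y, x]`` volume."""
    if not 0 < halfangle_deg <= 90:
        raise ValueError("wedge half-angle must be in (0, 90] degrees")
    if halfangle_deg == 90:
        return np.ones(shape)
    fz = np.fft.fftfreq(shape[0])[:, None, None]
    fx = np.fft.fftfreq(shape[2])[None, None, :]
    angle = np.degrees(np.arctan2(np.abs(fz), np.abs(fx)))
    mask = (angle <= halfangle_deg) | ((fz == 0) & (fx == 0))
    return np.broadcast_to(mask, shape).astype(float)


def apply_wedge(data: np.ndarray, halfangle_deg: float) -> np.ndarray:
    """Filter a real volume with the binary missing-wedge mask."""
    if halfangle_deg == 90:
        return data.copy()
    mask = missing_wedge_mask(data.shape, halfangle_deg)
    return np.fft.ifftn(np.fft.fftn(data) * mask).real
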