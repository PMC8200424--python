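"""Dose-matrix resampling — the resolution/interpolation intervention.

Changing the sampling resolution of a measured dose matrix (for example the
diode array's 5 mm export, or the panel's 0.255 mm image, to a common 1 mm
grid) is exactly the kind of processing clinical software applies before a
gamma comparison, and it systematically shifts gamma pass rates: linear
upsampling of a sparse grid manufactures plausible candidate doses between
nodes (raising pass rates), while downsampling a dense image discards real
structure (lowering them).  The resampler here is deliberately naive — plain
bilinear (or nearest-neighbour) with no anti-aliasing prefilter — to probe
that effect.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dose import DoseMatrix

__all__ = ["resample"]


def resample(
    dose: DoseMatrix, new_spacing: float, method: str = "BILINEAR"
) -> DoseMatrix:
    """Resample onto a grid of ``new_spacing`` covering the same extent.

    The new grid is cell-center aligned at the input origin and never
    extrapolates beyond the input extent.  ``method`` is ``BILINEAR``
    (default) or ``NEAREST``.  The input is untouched.
    """
    method = method.upper()
    if method not in ("BILINEAR", "NEAREST"):
        raise ValueError(f"unknown resampling method {method!r}")
    if not new_spacing > 0:
        raise ValueError("new_spacing must be > 0")
    x0, x1, y0, y1 = dose.extent
    if new_spacing > max(x1 - x0, y1 - y0):
        raise ValueError("new_spacing larger than the dose matrix extent")

    nx = int(np.floor((x1 - x0) / new_spacing + 1e-9)) + 1
    ny = int(np.floor((y1 - y0) / new_spacing + 1e-9)) + 1
    nxv = np.minimum(x0 + new_spacing * np.arange(nx), x1)
    nyv = np.minimum(y0 + new_spacing * np.arange(ny), y1)

    interp = RegularGridInterpolator(
        (dose.y, dose.x),
        dose.values,
        method="linear" if method == "BILINEAR" else "nearest",
    )
    xx, yy = np.meshgrid(nxv, nyv)
    vals = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(ny, nx)
    return DoseMatrix(vals, float(new_spacing), (float(nxv[0]), float(nyv[0])))
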