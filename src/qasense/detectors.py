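"""Virtual QA detectors: a sparse cylindrical diode array and a dense flat panel.

Both devices are modelled purely as *samplers* of a planar dose surrogate:

* ``ARRAY`` — a 1386-diode helical cylinder, unwrapped to a plane: 21 rows of
  66 diodes at 10 mm pitch, odd rows offset by half a pitch (the helix
  surrogate).  The vendor software exports measurements on a 5 mm grid, which
  is emulated by linear scattered interpolation of the diode readings.
* ``PANEL`` — a 1024x1024 amorphous-silicon imager with 0.4 mm pixels,
  exported at 0.255 mm after bilinear resampling.  Only a centered crop
  (default 120 mm) is sampled by default, which keeps desk-scale studies fast;
  the full 409.6 mm panel is available via ``crop_mm``.

Measurement reproducibility is a multiplicative Gaussian noise per sampled
point (default 0.1 % relative SD), calibrated so that two independent
measurements of the same delivery pass 1%/1 mm global gamma at 100 %.
Dose-to-signal calibration chains, angular corrections and phantom
attenuation are intentionally out of scope: the study design compares a
detector with itself, so those factors cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator, griddata

from .dose import DoseMatrix

__all__ = [
    "DetectorSpec",
    "NoiseModel",
    "DoseExtentError",
    "build_arccheck_lattice",
    "build_epid_panel",
    "measure",
]

ARRAY_N_DIODES = 1386
ARRAY_ROWS = 21
ARRAY_COLS = 66
ARRAY_PITCH_MM = 10.0
ARRAY_EXPORT_SPACING_MM = 5.0

PANEL_N_PIXELS = 1024
PANEL_PIXEL_PITCH_MM = 0.4
PANEL_EXPORT_SPACING_MM = 0.255
PANEL_DEFAULT_CROP_MM = 120.0


class DoseExtentError(ValueError):
    """A detector sample point falls outside the dose matrix extent."""


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise: value * (1 + N(0, sigma_rel))."""

    sigma_rel: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")


@dataclass
class DetectorSpec:
    """Geometry of a virtual measuring device plus its export grid.

    ``sample_points`` are the physical sampling locations (x, y) in mm;
    ``export_x``/``export_y`` the cell-center axes of the reported matrix.
    For PANEL, ``pixel_x``/``pixel_y`` give the regular pixel lattice that
    ``sample_points`` was flattened from.
    """

    kind: str  # "ARRAY" | "PANEL"
    sample_points: np.ndarray
    export_x: np.ndarray
    export_y: np.ndarray
    export_spacing: float
    pixel_x: np.ndarray | None = None
    pixel_y: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("ARRAY", "PANEL"):
            raise ValueError(f"unknown detector kind {self.kind!r}")
        if self.export_spacing <= 0:
            raise ValueError("export_spacing must be > 0")
        self.sample_points = np.asarray(self.sample_points, dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.sample_points)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}

    @staticmethod
    def from_dict(d: dict) -> "DetectorSpec":
        d = dict(d)
        kind = d.pop("kind")
        if kind == "ARRAY":
            return build_arccheck_lattice()
        return build_epid_panel(**d)


def build_arccheck_lattice() -> DetectorSpec:
    """The unwrapped-cylinder diode lattice: 21 x 66 = 1386 points.

    Rows run along the cylinder axis (y, 10 mm pitch, 200 mm span); columns
    along the unwrapped circumference (x, 10 mm pitch); odd rows are offset
    +5 mm to stand in for the helical winding.  Export grid: 5 mm.
    """
    rows_y = ARRAY_PITCH_MM * (np.arange(ARRAY_ROWS) - (ARRAY_ROWS - 1) / 2.0)
    cols_x = ARRAY_PITCH_MM * (np.arange(ARRAY_COLS) - (ARRAY_COLS - 1) / 2.0)
    pts = []
    for k, y in enumerate(rows_y):
        offset = ARRAY_PITCH_MM / 2.0 if k % 2 else 0.0
        for x in cols_x:
            pts.append((x + offset, y))
    pts = np.asarray(pts)
    s = ARRAY_EXPORT_SPACING_MM
    ex = np.arange(np.min(pts[:, 0]), np.max(pts[:, 0]) + s / 2, s)
    ey = np.arange(np.min(pts[:, 1]), np.max(pts[:, 1]) + s / 2, s)
    return DetectorSpec("ARRAY", pts, ex, ey, s, params={})


def build_epid_panel(crop_mm: float = PANEL_DEFAULT_CROP_MM) -> DetectorSpec:
    """The flat-panel imager: 1024x1024 pixels of 0.4 mm, 0.255 mm export.

    Only pixels inside the centered ``crop_mm`` window (plus one pixel of
    margin so the export grid stays interpolable) are sampled.
    """
    if crop_mm <= 0:
        raise ValueError("crop_mm must be > 0")
    centers = PANEL_PIXEL_PITCH_MM * (
        np.arange(PANEL_N_PIXELS) - (PANEL_N_PIXELS - 1) / 2.0
    )
    half = min(crop_mm / 2.0, centers[-1])
    keep = np.abs(centers) <= half + PANEL_PIXEL_PITCH_MM
    px = centers[keep]
    xx, yy = np.meshgrid(px, px)
    pts = np.column_stack([xx.ravel(), yy.ravel()])

    s = PANEL_EXPORT_SPACING_MM
    n_half = int(np.floor(half / s))
    ex = s * np.arange(-n_half, n_half + 1)
    return DetectorSpec(
        "PANEL",
        pts,
        ex,
        ex.copy(),
        s,
        pixel_x=px,
        pixel_y=px.copy(),
        params={"crop_mm": float(crop_mm)},
    )


def _sample(dose: DoseMatrix, pts: np.ndarray) -> np.ndarray:
    x0, x1, y0, y1 = dose.extent
    bad = (pts[:, 0] < x0) | (pts[:, 0] > x1) | (pts[:, 1] < y0) | (pts[:, 1] > y1)
    if np.any(bad):
        px, py = pts[np.argmax(bad)]
        raise DoseExtentError(
            f"sample point ({px:g}, {py:g}) mm outside dose grid extent "
            f"x[{x0:g}, {x1:g}] y[{y0:g}, {y1:g}]"
        )
    interp = RegularGridInterpolator(
        (dose.y, dose.x), dose.values, method="linear", bounds_error=False, fill_value=None
    )
    return interp(np.column_stack([pts[:, 1], pts[:, 0]]))


def measure(dose: DoseMatrix, spec: DetectorSpec, noise: NoiseModel) -> DoseMatrix:
    """Virtually measure a dose surrogate the way the device reports it.

    Bilinearly samples the input at every detector sampling location, applies
    multiplicative Gaussian noise, and interpolates to the device's export
    grid (linear scattered interpolation with nearest-neighbour fringe fill
    for the diode lattice; bilinear resampling for the panel).
    """
    vals = _sample(dose, spec.sample_points)
    if noise.sigma_rel > 0:
        rng = np.random.default_rng(noise.seed)
        vals = vals * (1.0 + rng.normal(0.0, noise.sigma_rel, size=vals.shape))

    if spec.kind == "ARRAY":
        xx, yy = np.meshgrid(spec.export_x, spec.export_y)
        grid = griddata(spec.sample_points, vals, (xx, yy), method="linear")
        nan = np.isnan(grid)
        if np.any(nan):  # convex-hull fringe
            near = griddata(spec.sample_points, vals, (xx, yy), method="nearest")
            grid[nan] = near[nan]
    else:
        pix = vals.reshape(len(spec.pixel_y), len(spec.pixel_x))
        interp = RegularGridInterpolator(
            (spec.pixel_y, spec.pixel_x), pix, method="linear"
        )
        xx, yy = np.meshgrid(spec.export_x, spec.export_y)
        grid = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(xx.shape)

    np.clip(grid, 0.0, None, out=grid)  # noise guard; dose is non-negative
    return DoseMatrix(
        grid, spec.export_spacing, (float(spec.export_x[0]), float(spec.export_y[0]))
    )
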