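"""Planar dose distributions on uniform grids.

The :class:`DoseMatrix` is the currency passed between every stage of the
pipeline: the rendered delivery surrogate, the virtually measured detector
export, the resampled matrix fed to the gamma comparison, and the per-point
gamma map itself all use it.

Coordinate conventions
----------------------
Isocenter-centered millimetres.  ``values[iy, ix]`` lives at
``x = origin[0] + ix * spacing`` and ``y = origin[1] + iy * spacing``
(cell-center convention, isotropic spacing).  X is the leaf-travel axis,
Y the leaf-index axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseMatrix"]


@dataclass
class DoseMatrix:
    """A 2D relative-dose distribution on a uniform, isotropic grid.

    Parameters
    ----------
    values
        2D array of non-negative relative dose values, shape ``(ny, nx)``.
    spacing
        Grid pitch in mm (isotropic, > 0).
    origin
        ``(x, y)`` position in mm of the *center* of cell ``[0, 0]``.
    all_zero_warning
        Set by the renderer when every aperture was empty and the matrix is
        identically zero (flagged rather than raised, so study runs survive
        degenerate plans).
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    all_zero_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2D, got ndim={self.values.ndim}")
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry -----------------------------------------------------------

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def x(self) -> np.ndarray:
        """Cell-center x coordinates, mm."""
        return self.origin[0] + self.spacing * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        """Cell-center y coordinates, mm."""
        return self.origin[1] + self.spacing * np.arange(self.ny)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of cell centers, mm."""
        x, y = self.x, self.y
        return float(x[0]), float(x[-1]), float(y[0]), float(y[-1])

    def same_grid(self, other: "DoseMatrix", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.spacing - other.spacing) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def copy(self) -> "DoseMatrix":
        return DoseMatrix(
            self.values.copy(), self.spacing, self.origin, self.all_zero_warning
        )

    # -- constructors -------------------------------------------------------

    @staticmethod
    def centered(nx: int, ny: int, spacing: float) -> "DoseMatrix":
        """All-zero matrix whose grid is symmetric about the isocenter."""
        origin = (-spacing * (nx - 1) / 2.0, -spacing * (ny - 1) / 2.0)
        return DoseMatrix(np.zeros((ny, nx)), spacing, origin)
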