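"""Synthetic SBRT-VMAT-like plans, delivery-error injection, and dose rendering.

The model world: a 40-leaf-pair MLC (5 mm projected leaf width at the
isocenter), two arcs per patient, each arc a sequence of control points with
its own aperture and monitor-unit weight, and a non-zero collimator angle per
arc.  A plan's delivered dose is approximated by a planar surrogate: every
control-point aperture is Gaussian-blurred (penumbra), rotated by its
collimator angle about the isocenter, and accumulated with its MU weight.

Delivery errors are injected directly into the control points:

* ``COLLIMATOR`` — add a signed angle (degrees) to every control point;
* ``MLCFS``     — open/close the field width by a signed total of m mm
  (each bank moves m/2; closing clamps at the pair midpoint);
* ``MLCSHIFT``  — translate both banks by a signed m mm along leaf travel.

Because the penumbra kernel is isotropic, blurring each aperture before
rotating it is mathematically identical to rotating the sharp aperture first;
the analytic (error-function) blur is used so that edge profiles are exact to
machine precision rather than limited by rasterization.
"""

from __future__ import annotations

import copy
import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .dose import DoseMatrix

__all__ = [
    "N_LEAF_PAIRS",
    "LEAF_WIDTH_MM",
    "MIN_GAP_MM",
    "ErrorType",
    "ErrorSpec",
    "ControlPoint",
    "ArcPlan",
    "PatientPlan",
    "generate_patient_plan",
    "apply_error",
    "render_arc_dose",
    "render_composite_dose",
]

N_LEAF_PAIRS = 40
LEAF_WIDTH_MM = 5.0  # projected at isocenter (Agility-like)
MIN_GAP_MM = 0.5
MAX_LEAF_POS_MM = 200.0
DEFAULT_ERROR_MAGNITUDES = (1.0, 2.0, 5.0)  # ± grid, degrees or mm


class ErrorType(str, enum.Enum):
    NONE = "NONE"
    COLLIMATOR = "COLLIMATOR"
    MLCFS = "MLCFS"
    MLCSHIFT = "MLCSHIFT"


@dataclass(frozen=True)
class ErrorSpec:
    """A single delivery-error variant: what to perturb and by how much.

    ``magnitude`` is signed: degrees for ``COLLIMATOR``, mm otherwise.
    """

    error_type: ErrorType
    magnitude: float

    def __post_init__(self) -> None:
        et = ErrorType(self.error_type)
        object.__setattr__(self, "error_type", et)
        m = float(self.magnitude)
        object.__setattr__(self, "magnitude", m)
        if not np.isfinite(m):
            raise ValueError("error magnitude must be finite")
        if et is ErrorType.NONE and m != 0.0:
            raise ValueError("NONE error requires magnitude 0")
        if et is not ErrorType.NONE and m == 0.0:
            raise ValueError(f"{et.value} error requires a nonzero magnitude")

    @property
    def label(self) -> str:
        if self.error_type is ErrorType.NONE:
            return "NE"
        unit = "deg" if self.error_type is ErrorType.COLLIMATOR else "mm"
        return f"{self.error_type.value}{self.magnitude:+g}{unit}"


@dataclass
class ControlPoint:
    """MLC bank positions (mm at isocenter), collimator angle and MU weight."""

    leaf_left: np.ndarray
    leaf_right: np.ndarray
    collimator_angle: float
    mu_weight: float

    def __post_init__(self) -> None:
        self.leaf_left = np.asarray(self.leaf_left, dtype=float)
        self.leaf_right = np.asarray(self.leaf_right, dtype=float)
        self.validate()

    def validate(self, min_gap: float = MIN_GAP_MM) -> None:
        if self.leaf_left.shape != (N_LEAF_PAIRS,) or self.leaf_right.shape != (
            N_LEAF_PAIRS,
        ):
            raise ValueError(f"leaf banks must have {N_LEAF_PAIRS} positions")
        gap = self.leaf_right - self.leaf_left
        if np.any(gap < min_gap - 1e-9):
            raise ValueError("leaf pair gap below minimum gap")
        if np.any(np.abs(self.leaf_left) > MAX_LEAF_POS_MM) or np.any(
            np.abs(self.leaf_right) > MAX_LEAF_POS_MM
        ):
            raise ValueError(f"leaf positions must be within ±{MAX_LEAF_POS_MM} mm")
        if not self.mu_weight >= 0:
            raise ValueError("mu_weight must be >= 0")


@dataclass
class ArcPlan:
    """One VMAT arc: ordered control points plus the arc's total MU weight."""

    arc_id: int
    control_points: list[ControlPoint]
    mu: float = 1.0

    def validate(self) -> None:
        if self.arc_id not in (1, 2):
            raise ValueError("arc_id must be 1 or 2")
        if len(self.control_points) < 2:
            raise ValueError("an arc needs at least 2 control points")
        total = float(sum(cp.mu_weight for cp in self.control_points))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"control point mu_weights must sum to 1, got {total}")
        if not self.mu >= 0:
            raise ValueError("arc MU must be >= 0")
        for cp in self.control_points:
            cp.validate()


@dataclass
class PatientPlan:
    """Two-arc plan for one synthetic patient."""

    patient_id: str
    arcs: list[ArcPlan]
    target_diameter: float
    rng_seed: int

    def validate(self) -> None:
        if len(self.arcs) != 2:
            raise ValueError("a patient plan has exactly 2 arcs")
        if not (20.0 <= self.target_diameter <= 60.0):
            raise ValueError("target_diameter must be in [20, 60] mm")
        for arc in self.arcs:
            arc.validate()


# ---------------------------------------------------------------------------
# Plan generation


def leaf_row_edges() -> np.ndarray:
    """Y edges of the 40 leaf rows: -100 .. +100 mm in 5 mm steps (41 values)."""
    return LEAF_WIDTH_MM * (np.arange(N_LEAF_PAIRS + 1) - N_LEAF_PAIRS / 2.0)


def _smooth_field(rng: np.random.Generator, n_cp: int, amplitude: float) -> np.ndarray:
    """A seeded, smoothly varying (n_cp, 40) perturbation bounded by amplitude."""
    coarse = rng.uniform(-1.0, 1.0, size=(4, 6))
    fine = ndimage.zoom(
        coarse, (n_cp / coarse.shape[0], N_LEAF_PAIRS / coarse.shape[1]), order=1
    )
    fine = fine[:n_cp, :N_LEAF_PAIRS]
    peak = np.max(np.abs(fine))
    if peak > 0:
        fine = fine / peak
    return amplitude * fine


def generate_patient_plan(
    seed: int,
    target_diameter: float = 35.0,
    n_control_points: int = 24,
    min_gap: float = MIN_GAP_MM,
) -> PatientPlan:
    """Generate a reproducible two-arc plan conforming to an elliptical target.

    Each control point's open leaf pairs track the elliptical projection of a
    target of the given diameter, with a seeded smooth modulation bounded by
    3 mm per leaf.  Leaf pairs outside the target rows are parked closed (gap
    = ``min_gap``) at the bank midline.  Collimator angles are non-zero, drawn
    from ±[10°, 45°] per arc.
    """
    if n_control_points < 2:
        raise ValueError("n_control_points must be >= 2")
    if not (20.0 <= target_diameter <= 60.0):
        raise ValueError("target_diameter must be in [20, 60] mm")
    rng = np.random.default_rng(int(seed))

    edges = leaf_row_edges()
    row_centers = 0.5 * (edges[:-1] + edges[1:])
    a = target_diameter / 2.0  # semi-axis along leaf travel (x)

    arcs: list[ArcPlan] = []
    for arc_id in (1, 2):
        b = a * rng.uniform(0.85, 1.15)  # semi-axis along leaf index (y)
        angle = float(rng.choice([-1.0, 1.0]) * rng.uniform(10.0, 45.0))
        # max |delta| 2.7 mm keeps the stated 3 mm bound with slack
        dl = _smooth_field(rng, n_control_points, 2.7)
        dr = _smooth_field(rng, n_control_points, 2.7)
        raw_w = 0.5 + rng.random(n_control_points)
        mu_w = raw_w / raw_w.sum()
        mu = float(rng.uniform(0.8, 1.2))

        open_row = np.abs(row_centers) < b
        half_width = np.zeros(N_LEAF_PAIRS)
        half_width[open_row] = a * np.sqrt(1.0 - (row_centers[open_row] / b) ** 2)

        cps: list[ControlPoint] = []
        for k in range(n_control_points):
            left = np.where(open_row, -half_width + dl[k], -min_gap / 2.0)
            right = np.where(open_row, half_width + dr[k], +min_gap / 2.0)
            narrow = right - left < min_gap
            mid = 0.5 * (left + right)
            left = np.where(narrow, mid - min_gap / 2.0, left)
            right = np.where(narrow, mid + min_gap / 2.0, right)
            cps.append(ControlPoint(left, right, angle, float(mu_w[k])))
        arcs.append(ArcPlan(arc_id, cps, mu))

    plan = PatientPlan(f"synthetic-{int(seed):06d}", arcs, float(target_diameter), int(seed))
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Error injection


def apply_error(
    plan: PatientPlan, spec: ErrorSpec, min_gap: float = MIN_GAP_MM
) -> PatientPlan:
    """Return a new plan with the delivery error injected; the input is untouched."""
    if not isinstance(spec, ErrorSpec):
        spec = ErrorSpec(*spec)
    out = copy.deepcopy(plan)
    et, m = spec.error_type, spec.magnitude
    if et is ErrorType.NONE:
        return out
    for arc in out.arcs:
        for cp in arc.control_points:
            if et is ErrorType.COLLIMATOR:
                cp.collimator_angle += m
            elif et is ErrorType.MLCSHIFT:
                cp.leaf_left += m
                cp.leaf_right += m
            elif et is ErrorType.MLCFS:
                cp.leaf_left -= m / 2.0
                cp.leaf_right += m / 2.0
                narrow = cp.leaf_right - cp.leaf_left < min_gap
                if np.any(narrow):
                    mid = 0.5 * (cp.leaf_left + cp.leaf_right)
                    cp.leaf_left = np.where(narrow, mid - min_gap / 2.0, cp.leaf_left)
                    cp.leaf_right = np.where(narrow, mid + min_gap / 2.0, cp.leaf_right)
            else:  # pragma: no cover - ErrorSpec already validates
                raise ValueError(f"unknown error type {et!r}")
    return out


# ---------------------------------------------------------------------------
# Rendering


def _grid_1d(extent: float, spacing: float) -> np.ndarray:
    """Symmetric cell-center axis covering ±extent/2, isocenter on a node."""
    half = int(round(extent / (2.0 * spacing)))
    return spacing * np.arange(-half, half + 1)


def _blurred_aperture(
    cp: ControlPoint, x: np.ndarray, y: np.ndarray, sigma: float, min_gap: float
) -> np.ndarray:
    """Gaussian-blurred aperture of one control point, before rotation.

    Leaf rows are disjoint in y, so the aperture is a disjoint union of
    axis-aligned rectangles; its Gaussian convolution is an exact sum of
    separable error-function products.  Pairs closed to the minimum gap sit
    behind the backup jaw and contribute nothing.
    """
    edges = leaf_row_edges()
    out = np.zeros((y.size, x.size))
    gap = cp.leaf_right - cp.leaf_left
    for i in np.nonzero(gap > min_gap + 1e-9)[0]:
        px = ndtr((x - cp.leaf_left[i]) / sigma) - ndtr((x - cp.leaf_right[i]) / sigma)
        py = ndtr((y - edges[i]) / sigma) - ndtr((y - edges[i + 1]) / sigma)
        out += np.outer(py, px)
    return out


def _rotate(field: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a field about the grid center (bilinear, no reshape)."""
    if angle_deg == 0.0:
        return field
    return ndimage.rotate(
        field, angle_deg, reshape=False, order=1, mode="constant", cval=0.0,
        prefilter=False,
    )


def render_arc_dose(
    arc: ArcPlan,
    spacing: float = 0.5,
    extent: float | tuple[float, float] = 240.0,
    penumbra_sigma: float = 2.5,
    normalize: bool = True,
) -> DoseMatrix:
    """Render one arc to a planar relative-dose surrogate.

    Every control point's aperture is blurred with an isotropic Gaussian of
    ``penumbra_sigma`` mm, rotated by its collimator angle about the
    isocenter, and accumulated with its MU weight.  The output grid is
    isocenter-centered with the given pitch, covering ``extent`` mm
    (scalar, or ``(extent_x, extent_y)``).  With ``normalize`` the matrix is
    scaled to max 1.
    """
    if spacing <= 0 or spacing > 1.0:
        raise ValueError("spacing must be in (0, 1] mm")
    if penumbra_sigma <= 0:
        raise ValueError("penumbra_sigma must be > 0")
    ex, ey = (extent, extent) if np.isscalar(extent) else extent
    x_full, y_full = _grid_1d(ex, spacing), _grid_1d(ey, spacing)

    # Active square subgrid: aperture reach * sqrt(2) (rotation) + blur margin.
    reach = MIN_GAP_MM
    for cp in arc.control_points:
        gap = cp.leaf_right - cp.leaf_left
        open_pairs = gap > MIN_GAP_MM + 1e-9
        if np.any(open_pairs):
            edges = leaf_row_edges()
            ymax = max(
                abs(edges[:-1][open_pairs]).max(), abs(edges[1:][open_pairs]).max()
            )
            xmax = max(
                abs(cp.leaf_left[open_pairs]).max(),
                abs(cp.leaf_right[open_pairs]).max(),
            )
            reach = max(reach, xmax, ymax)
    half_active = reach * np.sqrt(2.0) + 8.0 * penumbra_sigma + 2.0 * spacing
    half_active = min(half_active, max(abs(x_full[0]), abs(y_full[0])))
    n_half = int(np.ceil(half_active / spacing))
    xa = spacing * np.arange(-n_half, n_half + 1)

    acc = np.zeros((xa.size, xa.size))
    any_open = False
    for cp in arc.control_points:
        if np.any(cp.leaf_right - cp.leaf_left > MIN_GAP_MM + 1e-9):
            any_open = True
            ap = _blurred_aperture(cp, xa, xa, penumbra_sigma, MIN_GAP_MM)
            acc += cp.mu_weight * _rotate(ap, cp.collimator_angle)

    full = np.zeros((y_full.size, x_full.size))
    # embed the active subgrid (both grids share the isocenter node)
    cx, cy = x_full.size // 2, y_full.size // 2
    sx0, sx1 = max(0, cx - n_half), min(x_full.size, cx + n_half + 1)
    sy0, sy1 = max(0, cy - n_half), min(y_full.size, cy + n_half + 1)
    ax0, ay0 = sx0 - (cx - n_half), sy0 - (cy - n_half)
    full[sy0:sy1, sx0:sx1] = acc[
        ay0 : ay0 + (sy1 - sy0), ax0 : ax0 + (sx1 - sx0)
    ]
    np.clip(full, 0.0, None, out=full)  # guard bilinear round-off

    warn_zero = not any_open or full.max() <= 0.0
    if warn_zero:
        warnings.warn("rendered arc has no open aperture; dose is all zero")
        full[:] = 0.0
    elif normalize:
        full /= full.max()
    dm = DoseMatrix(full, spacing, (float(x_full[0]), float(y_full[0])))
    dm.all_zero_warning = warn_zero
    return dm


def render_composite_dose(
    plan: PatientPlan,
    spacing: float = 0.5,
    extent: float | tuple[float, float] = 240.0,
    penumbra_sigma: float = 2.5,
    normalize: bool = True,
) -> DoseMatrix:
    """MU-weighted sum of the plan's two arc renderings on an identical grid.

    Exactly linear before normalization: ``composite = mu1*arc1 + mu2*arc2``.
    """
    if sum(arc.mu for arc in plan.arcs) <= 0:
        raise ValueError("plan has zero total MU")
    parts = [
        render_arc_dose(arc, spacing, extent, penumbra_sigma, normalize=False)
        for arc in plan.arcs
    ]
    if not parts[0].same_grid(parts[1]):  # pragma: no cover - same inputs, must hold
        raise RuntimeError("internal error: arc renderings on mismatched grids")
    values = sum(arc.mu * p.values for arc, p in zip(plan.arcs, parts))
    warn_zero = all(p.all_zero_warning for p in parts) or values.max() <= 0
    if not warn_zero and normalize:
        values = values / values.max()
    dm = DoseMatrix(values, parts[0].spacing, parts[0].origin)
    dm.all_zero_warning = warn_zero
    return dm
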