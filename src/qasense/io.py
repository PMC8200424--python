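"""Plain-text file formats: dose matrices, plans, and study configuration.

Dose matrix ASCII format (``.dose``)::

    qasense-dose 1
    nx 5
    ny 4
    spacing_mm 0.5
    origin_x_mm -1
    origin_y_mm -0.75
    <ny rows of nx values, space separated, row-major (y rows)>

Values are written with 9 significant digits (``%.9g``), so a
write -> read -> write cycle is byte-identical.  Plans and study configs are
YAML documents with schema versions; see :func:`write_plan` /
:func:`read_plan`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .dose import DoseMatrix
from .plans import ArcPlan, ControlPoint, PatientPlan

__all__ = [
    "DoseParseError",
    "read_dose",
    "write_dose",
    "read_plan",
    "write_plan",
]

_DOSE_MAGIC = "qasense-dose 1"
_PLAN_SCHEMA = 1


class DoseParseError(ValueError):
    """Malformed dose file; the message names the offending line."""


def write_dose(dose: DoseMatrix, path: str | Path) -> None:
    """Write a dose matrix in the ASCII format (9 significant digits)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_DOSE_MAGIC}\n")
        fh.write(f"nx {dose.nx}\n")
        fh.write(f"ny {dose.ny}\n")
        fh.write(f"spacing_mm {dose.spacing:.9g}\n")
        fh.write(f"origin_x_mm {dose.origin[0]:.9g}\n")
        fh.write(f"origin_y_mm {dose.origin[1]:.9g}\n")
        for row in dose.values:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def _header_value(lines: list[str], idx: int, key: str) -> float:
    if idx >= len(lines):
        raise DoseParseError(f"line {idx + 1}: missing '{key}' header line")
    parts = lines[idx].split()
    if len(parts) != 2 or parts[0] != key:
        raise DoseParseError(
            f"line {idx + 1}: expected '{key} <value>', got {lines[idx]!r}"
        )
    try:
        return float(parts[1])
    except ValueError as exc:
        raise DoseParseError(f"line {idx + 1}: cannot parse {key} value") from exc


def read_dose(path: str | Path) -> DoseMatrix:
    """Read a dose matrix written by :func:`write_dose`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _DOSE_MAGIC:
        raise DoseParseError(f"line 1: not a qasense dose file (magic {_DOSE_MAGIC!r})")
    nx = int(_header_value(lines, 1, "nx"))
    ny = int(_header_value(lines, 2, "ny"))
    spacing = _header_value(lines, 3, "spacing_mm")
    ox = _header_value(lines, 4, "origin_x_mm")
    oy = _header_value(lines, 5, "origin_y_mm")
    if nx <= 0 or ny <= 0:
        raise DoseParseError("line 2: nx and ny must be positive")
    if spacing <= 0:
        raise DoseParseError("line 4: spacing_mm must be > 0")
    data_lines = lines[6:]
    if len(data_lines) < ny:
        raise DoseParseError(
            f"line {len(lines)}: expected {ny} data rows, found {len(data_lines)}"
        )
    rows = []
    for j in range(ny):
        vals = data_lines[j].split()
        if len(vals) != nx:
            raise DoseParseError(
                f"line {7 + j}: expected {nx} values in row, found {len(vals)}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise DoseParseError(f"line {7 + j}: non-numeric dose value") from exc
    for j in range(ny, len(data_lines)):
        if data_lines[j].strip():
            raise DoseParseError(f"line {7 + j}: trailing data beyond ny={ny} rows")
    return DoseMatrix(np.array(rows), spacing, (ox, oy))


# ---------------------------------------------------------------------------
# Plans


def write_plan(plan: PatientPlan, path: str | Path) -> None:
    doc = {
        "qasense_plan": _PLAN_SCHEMA,
        "patient_id": plan.patient_id,
        "target_diameter": float(plan.target_diameter),
        "rng_seed": int(plan.rng_seed),
        "arcs": [
            {
                "arc_id": arc.arc_id,
                "mu": float(arc.mu),
                "control_points": [
                    {
                        "collimator_angle": float(cp.collimator_angle),
                        "mu_weight": float(cp.mu_weight),
                        "leaf_left": [float(v) for v in cp.leaf_left],
                        "leaf_right": [float(v) for v in cp.leaf_right],
                    }
                    for cp in arc.control_points
                ],
            }
            for arc in plan.arcs
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_plan(path: str | Path) -> PatientPlan:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("qasense_plan") != _PLAN_SCHEMA:
        raise ValueError(f"{path}: not a qasense plan file (schema {_PLAN_SCHEMA})")
    arcs = [
        ArcPlan(
            int(a["arc_id"]),
            [
                ControlPoint(
                    np.asarray(cp["leaf_left"], dtype=float),
                    np.asarray(cp["leaf_right"], dtype=float),
                    float(cp["collimator_angle"]),
                    float(cp["mu_weight"]),
                )
                for cp in a["control_points"]
            ],
            float(a.get("mu", 1.0)),
        )
        for a in doc["arcs"]
    ]
    plan = PatientPlan(
        str(doc["patient_id"]),
        arcs,
        float(doc["target_diameter"]),
        int(doc["rng_seed"]),
    )
    plan.validate()
    return plan
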