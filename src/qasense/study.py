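"""The intrinsic-sensitivity study: cohort, error grid, measurement, gamma.

Orchestrates the full measured-vs-measured design: for every synthetic
patient, the baseline delivery is rendered and virtually measured twice with
independent noise (the second measurement gives the no-error self-comparison
that defines the detection standard); every error variant is rendered,
measured once, and gamma-compared against the first baseline measurement for
every detector x criteria x resolution x mode cell.  An error counts as
*detected* in a cell when its pass rate falls strictly below the no-error
standard for that cell.

Everything is deterministic given ``master_seed``: plan generation and every
measurement's noise stream are seeded through a ``SeedSequence`` hierarchy
(master -> patient -> measurement), and the seeds are reported per record.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .detectors import DetectorSpec, NoiseModel, build_arccheck_lattice, build_epid_panel, measure
from .dose import DoseMatrix
from .gamma import STUDY_CRITERIA, GammaCriteria, SearchOptions, gamma_index_many
from .plans import ErrorSpec, ErrorType, PatientPlan, apply_error, generate_patient_plan, render_arc_dose
from .resample import resample

__all__ = [
    "StudyConfig",
    "StudyResult",
    "DetectionRule",
    "physical_roster",
    "run_study",
    "classify_detection",
    "composite_vs_individual",
    "aggregate",
]

log = logging.getLogger("qasense.study")

NATIVE = "native"
RESAMPLED = "1mm"

#: Per-cell patient counts of the physical study's 88 clinically significant
#: variants.  The zero-SD table rows pin n=1 for collimator +1/-2 and the
#: +-2/+-5 MLC cells; the remaining 80 are spread over the six multi-patient
#: cells (the exact split is not recoverable and is configurable here).
PHYSICAL_ROSTER_COUNTS: tuple[tuple[str, float, int], ...] = (
    ("COLLIMATOR", +1.0, 1),
    ("COLLIMATOR", -2.0, 1),
    ("COLLIMATOR", +5.0, 14),
    ("COLLIMATOR", -5.0, 14),
    ("MLCFS", +1.0, 13),
    ("MLCFS", -1.0, 13),
    ("MLCFS", +2.0, 1),
    ("MLCFS", -2.0, 1),
    ("MLCFS", +5.0, 1),
    ("MLCSHIFT", +1.0, 13),
    ("MLCSHIFT", -1.0, 13),
    ("MLCSHIFT", +2.0, 1),
    ("MLCSHIFT", -2.0, 1),
    ("MLCSHIFT", +5.0, 1),
)


def physical_roster(n_patients: int = 15) -> list[tuple[int, ErrorSpec]]:
    """The 88-variant roster mirroring the physical study's bookkeeping."""
    roster: list[tuple[int, ErrorSpec]] = []
    for et, mag, count in PHYSICAL_ROSTER_COUNTS:
        for k in range(count):
            roster.append((k % n_patients, ErrorSpec(ErrorType(et), mag)))
    return roster


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run."""

    n_patients: int = 15
    error_types: tuple[str, ...] = ("COLLIMATOR", "MLCFS", "MLCSHIFT")
    error_magnitudes: tuple[float, ...] = (1.0, 2.0, 5.0)  # applied as +-
    roster: list[tuple[int, ErrorSpec]] | None = None
    detectors: tuple[str, ...] = ("ARRAY", "PANEL")
    criteria: tuple[GammaCriteria, ...] = STUDY_CRITERIA
    resolutions: tuple[str, ...] = (NATIVE, RESAMPLED)
    resample_spacing: float = 1.0
    mode: str = "COMPOSITE"  # COMPOSITE | PER_ARC | BOTH
    master_seed: int = 12345
    sigma_rel: float = 0.001
    target_diameter: float = 35.0
    n_control_points: int = 24
    panel_crop_mm: float = 120.0
    render_spacing: float = 0.5
    penumbra_sigma: float = 2.5

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.criteria:
            raise ValueError("criteria list must be non-empty")
        if any(m == 0 for m in self.error_magnitudes):
            raise ValueError("error-grid magnitudes must be nonzero")
        if self.mode not in ("COMPOSITE", "PER_ARC", "BOTH"):
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- enumeration --------------------------------------------------------

    def variants(self) -> list[tuple[int, ErrorSpec]]:
        """(patient index, error) cells; full factorial unless a roster is set."""
        if self.roster is not None:
            return list(self.roster)
        out = []
        for p in range(self.n_patients):
            for et in self.error_types:
                for m in self.error_magnitudes:
                    for sign in (+1.0, -1.0):
                        out.append((p, ErrorSpec(ErrorType(et), sign * m)))
        return out

    def mode_parts(self) -> tuple[int, ...]:
        """Arc labels per mode: 0 = composite, 1/2 = individual arcs."""
        return {"COMPOSITE": (0,), "PER_ARC": (1, 2), "BOTH": (0, 1, 2)}[self.mode]

    def primary_mode_part(self) -> int:
        return self.mode_parts()[0]

    def expected_manifest(self) -> dict:
        """Bookkeeping counts, computable without running anything.

        ``comparisons``/``analyses`` follow the physical study's counting:
        plans x detectors at native resolution in the primary mode, and
        comparisons x criteria.
        """
        n_variants = len(self.variants())
        n_plans = self.n_patients + n_variants
        comparisons = n_plans * len(self.detectors)
        parts = self.mode_parts()
        renders_per_plan = 2  # two arcs rendered once each; composite is their sum
        measurements = (
            (2 * self.n_patients + n_variants) * len(self.detectors) * len(parts)
        )
        records = (
            n_plans
            * len(self.detectors)
            * len(self.criteria)
            * len(self.resolutions)
            * len(parts)
        )
        return {
            "config_hash": self.config_hash(),
            "master_seed": self.master_seed,
            "patients": self.n_patients,
            "plans": n_plans,
            "variants": n_variants,
            "renders": n_plans * renders_per_plan,
            "measurements": measurements,
            "comparisons": comparisons,
            "analyses": comparisons * len(self.criteria),
            "records": records,
        }

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "error_types": list(self.error_types),
            "error_magnitudes": [float(m) for m in self.error_magnitudes],
            "roster": None
            if self.roster is None
            else [[p, e.error_type.value, float(e.magnitude)] for p, e in self.roster],
            "detectors": list(self.detectors),
            "criteria": [[c.dd_percent, c.dta_mm, c.threshold_fraction] for c in self.criteria],
            "resolutions": list(self.resolutions),
            "resample_spacing": self.resample_spacing,
            "mode": self.mode,
            "master_seed": self.master_seed,
            "sigma_rel": self.sigma_rel,
            "target_diameter": self.target_diameter,
            "n_control_points": self.n_control_points,
            "panel_crop_mm": self.panel_crop_mm,
            "render_spacing": self.render_spacing,
            "penumbra_sigma": self.penumbra_sigma,
        }

    @staticmethod
    def from_dict(d: dict) -> "StudyConfig":
        d = dict(d)
        if d.get("roster") is not None:
            d["roster"] = [
                (int(p), ErrorSpec(ErrorType(et), float(m))) for p, et, m in d["roster"]
            ]
        if "criteria" in d:
            d["criteria"] = tuple(
                GammaCriteria(c[0], c[1], c[2] if len(c) > 2 else 0.10)
                for c in d["criteria"]
            )
        for key in ("error_types", "detectors", "resolutions", "error_magnitudes"):
            if key in d:
                d[key] = tuple(d[key])
        return StudyConfig(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class DetectionRule:
    """The no-error standard per cell: detected means GPR strictly below it."""

    baseline_gpr: dict[tuple, float] = field(default_factory=dict)

    @staticmethod
    def from_records(records: pd.DataFrame) -> "DetectionRule":
        ne = records[records["is_baseline"] & records["gpr"].notna()]
        rule = DetectionRule()
        grouped = ne.groupby(["detector", "arc", "criteria", "resolution"])["gpr"].mean()
        for key, gpr in grouped.items():
            rule.baseline_gpr[key] = float(gpr)
        return rule


def classify_detection(record, rule: DetectionRule) -> bool:
    """Detected iff the record's GPR is strictly below the cell's NE standard."""
    key = (record["detector"], record["arc"], record["criteria"], record["resolution"])
    if key not in rule.baseline_gpr:
        raise KeyError(f"no no-error baseline for cell {key}")
    return bool(record["gpr"] < rule.baseline_gpr[key])


@dataclass
class StudyResult:
    records: pd.DataFrame
    manifest: dict
    config: StudyConfig


# ---------------------------------------------------------------------------
# Execution


_ROLE_CODES = {"plan": 0, "meas": 1}
_KIND_CODES = {"A": 0, "B": 1, "V": 2}


def _measurement_seed(master_seed: int, patient: int, role: tuple) -> int:
    """Deterministic per-(patient, role) seed from the master seed.

    Roles are tuples like ("plan",) or ("meas", detector, arc, kind[, index]);
    each element is coerced to a stable integer code for the spawn key.
    """
    codes = []
    for item in role:
        if isinstance(item, str):
            codes.append(_ROLE_CODES.get(item, _KIND_CODES.get(item, None)))
            if codes[-1] is None:
                # detector names and any other labels: stable small hash
                codes[-1] = int.from_bytes(item.encode()[:4].ljust(4, b"\0"), "big")
        else:
            codes.append(int(item))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(patient, *codes))
    return int(ss.generate_state(1)[0])


def _build_detectors(config: StudyConfig) -> dict[str, DetectorSpec]:
    out = {}
    for name in config.detectors:
        if name == "ARRAY":
            out[name] = build_arccheck_lattice()
        elif name == "PANEL":
            out[name] = build_epid_panel(config.panel_crop_mm)
        else:
            raise ValueError(f"unknown detector {name!r}")
    return out


def _render_extent(config: StudyConfig, specs: dict[str, DetectorSpec]):
    xmax = ymax = 0.0
    for spec in specs.values():
        pts = spec.sample_points
        xmax = max(xmax, float(np.abs(pts[:, 0]).max()))
        ymax = max(ymax, float(np.abs(pts[:, 1]).max()))
    margin = 4.0
    return (2 * (xmax + margin), 2 * (ymax + margin))


def _render_parts(plan: PatientPlan, config: StudyConfig, extent) -> dict[int, DoseMatrix]:
    """Doses per mode part: 0 = MU-weighted composite, 1/2 = individual arcs."""
    raw = [
        render_arc_dose(
            arc,
            spacing=config.render_spacing,
            extent=extent,
            penumbra_sigma=config.penumbra_sigma,
            normalize=False,
        )
        for arc in plan.arcs
    ]
    parts: dict[int, DoseMatrix] = {}
    need = set(config.mode_parts())
    if 0 in need:
        vals = sum(arc.mu * r.values for arc, r in zip(plan.arcs, raw))
        peak = vals.max()
        parts[0] = DoseMatrix(
            vals / peak if peak > 0 else vals, raw[0].spacing, raw[0].origin
        )
    for arc_label in (1, 2):
        if arc_label in need:
            r = raw[arc_label - 1]
            peak = r.values.max()
            parts[arc_label] = DoseMatrix(
                r.values / peak if peak > 0 else r.values, r.spacing, r.origin
            )
    return parts


def _search_options(detector: str, config: StudyConfig) -> SearchOptions:
    """Per-detector gamma search mode.

    The sparse array export is compared node-to-node (no interpolation),
    mirroring observed vendor behaviour on its native 5 mm grid; the dense
    panel uses interpolated DTA search.  A single interpolation step — a tenth
    of the *tightest* DTA in the criteria list — is shared by all criteria so
    that the candidate sets are nested and criteria-monotonicity holds
    pointwise.
    """
    if detector == "ARRAY":
        return SearchOptions(interpolate=False)
    step = min(c.dta_mm for c in config.criteria) / 10.0
    return SearchOptions(interpolate=True, interp_step=step)


def _compare_cell(
    ref: DoseMatrix,
    ev: DoseMatrix,
    config: StudyConfig,
    detector: str,
    resolution: str,
):
    """Gamma at every criterion for one (ref, eval, resolution) cell."""
    if resolution == RESAMPLED:
        ref = resample(ref, config.resample_spacing)
        ev = resample(ev, config.resample_spacing)
    opts = _search_options(detector, config)
    return gamma_index_many(ref, ev, config.criteria, opts)


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full study; deterministic given ``config.master_seed``."""
    specs = _build_detectors(config)
    extent = _render_extent(config, specs)
    variants = config.variants()
    by_patient: dict[int, list[ErrorSpec]] = {}
    for p, err in variants:
        by_patient.setdefault(p, []).append(err)

    rows: list[dict] = []

    def emit(patient, detector, arc, err: ErrorSpec | None, resolution, results, seed):
        is_baseline = err is None
        for crit, res in results.items():
            rows.append(
                {
                    "patient": patient,
                    "detector": detector,
                    "arc": arc,
                    "error_type": "NONE" if is_baseline else err.error_type.value,
                    "magnitude": 0.0 if is_baseline else err.magnitude,
                    "criteria": crit.label,
                    "dd_percent": crit.dd_percent,
                    "dta_mm": crit.dta_mm,
                    "resolution": resolution,
                    "gpr": res.gpr,
                    "gmv": res.gmv,
                    "n_assessed": res.n_assessed,
                    "is_baseline": is_baseline,
                    "noise_seed": seed,
                    "failure": "",
                }
            )

    def emit_failure(patient, detector, arc, err, resolution, exc):
        for crit in config.criteria:
            rows.append(
                {
                    "patient": patient,
                    "detector": detector,
                    "arc": arc,
                    "error_type": "NONE" if err is None else err.error_type.value,
                    "magnitude": 0.0 if err is None else err.magnitude,
                    "criteria": crit.label,
                    "dd_percent": crit.dd_percent,
                    "dta_mm": crit.dta_mm,
                    "resolution": resolution,
                    "gpr": np.nan,
                    "gmv": np.nan,
                    "n_assessed": 0,
                    "is_baseline": err is None,
                    "noise_seed": -1,
                    "failure": f"{type(exc).__name__}: {exc}",
                }
            )

    for p in range(config.n_patients):
        plan_seed = _measurement_seed(config.master_seed, p, ("plan",))
        plan = generate_patient_plan(
            plan_seed % 2**31, config.target_diameter, config.n_control_points
        )
        base_parts = _render_parts(plan, config, extent)
        variant_parts: dict[int, dict[int, DoseMatrix]] = {}
        for vi, err in enumerate(by_patient.get(p, [])):
            variant_parts[vi] = _render_parts(apply_error(plan, err), config, extent)

        for det_name, spec in specs.items():
            for arc_label, base_dose in base_parts.items():
                seed_a = _measurement_seed(config.master_seed, p, ("meas", det_name, arc_label, "A"))
                seed_b = _measurement_seed(config.master_seed, p, ("meas", det_name, arc_label, "B"))
                meas_ref = measure(base_dose, spec, NoiseModel(config.sigma_rel, seed_a))
                meas_ne = measure(base_dose, spec, NoiseModel(config.sigma_rel, seed_b))
                for resolution in config.resolutions:
                    try:
                        results = _compare_cell(
                            meas_ref, meas_ne, config, det_name, resolution
                        )
                        emit(p, det_name, arc_label, None, resolution, results, seed_b)
                    except Exception as exc:  # keep the study alive
                        log.exception(
                            "NE cell failed: patient=%s det=%s arc=%s res=%s",
                            p, det_name, arc_label, resolution,
                        )
                        emit_failure(p, det_name, arc_label, None, resolution, exc)

                for vi, err in enumerate(by_patient.get(p, [])):
                    seed_v = _measurement_seed(
                        config.master_seed, p, ("meas", det_name, arc_label, "V", vi)
                    )
                    try:
                        meas_v = measure(
                            variant_parts[vi][arc_label],
                            spec,
                            NoiseModel(config.sigma_rel, seed_v),
                        )
                    except Exception as exc:
                        log.exception(
                            "measurement failed: patient=%s det=%s arc=%s err=%s",
                            p, det_name, arc_label, err.label,
                        )
                        for resolution in config.resolutions:
                            emit_failure(p, det_name, arc_label, err, resolution, exc)
                        continue
                    for resolution in config.resolutions:
                        try:
                            results = _compare_cell(
                                meas_ref, meas_v, config, det_name, resolution
                            )
                            emit(p, det_name, arc_label, err, resolution, results, seed_v)
                        except Exception as exc:
                            log.exception(
                                "cell failed: patient=%s det=%s arc=%s err=%s res=%s",
                                p, det_name, arc_label, err.label, resolution,
                            )
                            emit_failure(p, det_name, arc_label, err, resolution, exc)

    records = pd.DataFrame(rows)
    rule = DetectionRule.from_records(records)
    records["detected"] = [
        (not r["is_baseline"])
        and not np.isnan(r["gpr"])
        and classify_detection(r, rule)
        for _, r in records.iterrows()
    ]
    manifest = config.expected_manifest()
    manifest["records_emitted"] = int(len(records))
    manifest["failures"] = int((records["failure"] != "").sum())
    return StudyResult(records, manifest, config)


# ---------------------------------------------------------------------------
# Composite vs individual arcs


def composite_vs_individual(config: StudyConfig) -> dict:
    """Run a BOTH-mode study and pair per-arc against composite records.

    Returns the full result plus a paired table of GPR deltas
    (arc minus composite) and the fraction of error cells where the per-arc
    detection call (either arc detects) agrees with the composite call.
    """
    if "ARRAY" not in config.detectors:
        raise ValueError("composite_vs_individual expects the ARRAY detector")
    cfg = replace(config, mode="BOTH")
    result = run_study(cfg)
    rec = result.records
    err = rec[~rec["is_baseline"] & (rec["failure"] == "")]
    keys = ["patient", "detector", "error_type", "magnitude", "criteria", "resolution"]
    comp = err[err["arc"] == 0].set_index(keys)
    paired_rows = []
    for arc in (1, 2):
        a = err[err["arc"] == arc].set_index(keys)
        joined = comp.join(a, lsuffix="_comp", rsuffix="_arc", how="inner")
        for key, row in joined.iterrows():
            paired_rows.append(
                dict(
                    zip(keys, key),
                    arc=arc,
                    gpr_composite=row["gpr_comp"],
                    gpr_arc=row["gpr_arc"],
                    delta_gpr=row["gpr_arc"] - row["gpr_comp"],
                    detected_composite=bool(row["detected_comp"]),
                    detected_arc=bool(row["detected_arc"]),
                )
            )
    paired = pd.DataFrame(paired_rows)
    per_cell = paired.groupby(keys).agg(
        detected_composite=("detected_composite", "any"),
        detected_any_arc=("detected_arc", "any"),
    )
    agreement = float(
        (per_cell["detected_composite"] == per_cell["detected_any_arc"]).mean()
    )
    return {"result": result, "paired": paired, "detection_agreement": agreement}


# ---------------------------------------------------------------------------
# Aggregation


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD of GPR and GMV per study cell (grouped over patients).

    SD is the sample SD (ddof=1); single-patient groups report SD = 0.
    Failed cells are dropped with a warning row count in the log.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    good = records[records["failure"] == ""]
    n_bad = len(records) - len(good)
    if n_bad:
        log.warning("aggregate: dropping %d failed records", n_bad)
    keys = ["detector", "arc", "error_type", "magnitude", "criteria", "resolution"]
    agg = (
        good.groupby(keys, sort=True)
        .agg(
            gpr_mean=("gpr", "mean"),
            gpr_sd=("gpr", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
            gmv_mean=("gmv", "mean"),
            gmv_sd=("gmv", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
            n=("gpr", "size"),
            n_detected=("detected", "sum"),
        )
        .reset_index()
    )
    return agg
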