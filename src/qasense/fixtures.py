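"""Seeded fixture generator: a small deterministic pack for offline testing.

Writes, into a target directory:

* ``plan_baseline.yaml`` / ``plan_mlcshift+5mm.yaml`` — one synthetic patient
  plan and its +5 mm MLC-shift variant;
* ``array_ne.dose`` / ``array_mlcshift+5mm.dose`` — virtual diode-array
  measurements of both deliveries;
* ``panel_ne.dose`` / ``panel_mlcshift+5mm.dose`` — virtual panel
  measurements (small crop, to stay quick);
* ``gamma_ref.dose`` / ``gamma_eval.dose`` — a 16x16 toy pair with
  hand-checkable gamma values.

Regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .detectors import NoiseModel, build_arccheck_lattice, build_epid_panel, measure
from .dose import DoseMatrix
from .io import write_dose, write_plan
from .plans import ErrorSpec, ErrorType, apply_error, generate_patient_plan, render_composite_dose

__all__ = ["make_fixtures"]


def _toy_pair(rng: np.random.Generator) -> tuple[DoseMatrix, DoseMatrix]:
    """A smooth 16x16 pair: a Gaussian blob plus small seeded perturbations."""
    n, s = 16, 2.0
    ax = s * (np.arange(n) - (n - 1) / 2.0)
    xx, yy = np.meshgrid(ax, ax)
    ref = np.exp(-(xx**2 + yy**2) / (2 * 8.0**2))
    ev = np.exp(-((xx - 1.0) ** 2 + yy**2) / (2 * 8.0**2))
    ev = ev * (1.0 + 0.01 * rng.standard_normal(ev.shape))
    origin = (float(ax[0]), float(ax[0]))
    return DoseMatrix(ref, s, origin), DoseMatrix(np.clip(ev, 0, None), s, origin)


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture pack; returns a name -> path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    plan = generate_patient_plan(int(seed), target_diameter=35.0, n_control_points=12)
    variant = apply_error(plan, ErrorSpec(ErrorType.MLCSHIFT, +5.0))
    paths["plan_baseline"] = outdir / "plan_baseline.yaml"
    paths["plan_variant"] = outdir / "plan_mlcshift+5mm.yaml"
    write_plan(plan, paths["plan_baseline"])
    write_plan(variant, paths["plan_variant"])

    array_spec = build_arccheck_lattice()
    panel_spec = build_epid_panel(crop_mm=60.0)
    extent = (2 * 332.0, 2 * 106.0)
    base_dose = render_composite_dose(plan, extent=extent)
    var_dose = render_composite_dose(variant, extent=extent)

    for name, dose, noise_seed in (
        ("array_ne", base_dose, seed + 1),
        ("array_mlcshift+5mm", var_dose, seed + 2),
    ):
        m = measure(dose, array_spec, NoiseModel(seed=noise_seed))
        paths[name] = outdir / f"{name}.dose"
        write_dose(m, paths[name])
    for name, dose, noise_seed in (
        ("panel_ne", base_dose, seed + 3),
        ("panel_mlcshift+5mm", var_dose, seed + 4),
    ):
        m = measure(dose, panel_spec, NoiseModel(seed=noise_seed))
        paths[name] = outdir / f"{name}.dose"
        write_dose(m, paths[name])

    rng = np.random.default_rng(int(seed) + 17)
    ref, ev = _toy_pair(rng)
    paths["gamma_ref"] = outdir / "gamma_ref.dose"
    paths["gamma_eval"] = outdir / "gamma_eval.dose"
    write_dose(ref, paths["gamma_ref"])
    write_dose(ev, paths["gamma_eval"])
    return paths
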