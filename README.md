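# qasense

**Virtual intrinsic-sensitivity analysis of radiotherapy QA detectors.**

Patient-specific QA of VMAT deliveries compares a measured dose distribution
against a prediction, usually with the gamma index.  What a given device can
detect, however, is limited first of all by its *intrinsic* properties —
spatial sampling, export interpolation, measurement reproducibility — before
any prediction model enters.  `qasense` isolates that intrinsic layer in a
fully synthetic pipeline aimed at medical physicists studying QA device
behaviour and gamma-criteria selection:

1. **Synthetic deliveries** — SBRT-VMAT-like two-arc plans from a 40-leaf-pair
   MLC (5 mm leaf width), rendered to a planar relative-dose surrogate
   (aperture ⨉ MU weight, Gaussian penumbra, per-control-point collimator
   rotation).
2. **Controlled delivery errors** — collimator-angle offsets (±1/±2/±5°), MLC
   field-size changes and MLC bank shifts (±1/±2/±5 mm) injected directly into
   the control points.
3. **Virtual measurement** — a sparse cylindrical diode array (1386 diodes,
   10 mm pitch, unwrapped; 5 mm export grid) and a dense flat panel
   (1024×1024 pixels of 0.4 mm; 0.255 mm export), each with a small
   multiplicative measurement noise (0.1 % relative SD).
4. **Measured-vs-measured gamma analysis** — every error variant is compared
   against the *baseline measurement of the same detector*, eliminating
   prediction-model confounders, at 3%/3mm, 2%/2mm, 2%/1mm and 1%/1mm
   (global normalization, 10 % low-dose threshold).

## The statistic

For a reference point $r$ with dose $D_r(r)$, the gamma index against the
evaluated distribution $D_e$ is

$$\gamma(r) \;=\; \min_{r'} \sqrt{\;\frac{\lVert r-r'\rVert^2}{\mathrm{DTA}^2}
 \;+\; \frac{\bigl(D_e(r') - D_r(r)\bigr)^2}{(\mathrm{DD\%}\cdot D_{\max,\mathrm{ref}})^2}\;}$$

A point passes when $\gamma \le 1$.  Reported per comparison: the **gamma
pass rate** (GPR, % of assessed points passing) and the **gamma mean value**
(GMV).  An error is *detected* when its GPR falls strictly below the
no-error measurement-to-measurement standard for the same detector and
criteria — which is 100 % under the default noise model.

The DTA search is candidate-limited to the DTA radius around each reference
point (nearest evaluated node always included), with optional bilinear
subdivision of the evaluated grid.  On the diode array's native 5 mm export
this reproduces a structural fact of sparse detectors: 2%/2mm and 2%/1mm
produce *identical* gamma maps, so the array's sensitivity is governed by the
dose-difference tolerance alone, while the panel responds to the DTA choice.

## Worked example

Inject a +5 mm MLC bank shift and ask both virtual detectors whether they see
it:

```python
import qasense as q

plan = q.generate_patient_plan(seed=1, target_diameter=35.0, n_control_points=24)
variant = q.apply_error(plan, q.ErrorSpec(q.ErrorType.MLCSHIFT, +5.0))

extent = (664.0, 212.0)  # covers the unwrapped diode cylinder
baseline = q.render_composite_dose(plan, extent=extent)
errored = q.render_composite_dose(variant, extent=extent)

for name, spec, opts in [
    ("ArcCHECK", q.build_arccheck_lattice(), q.SearchOptions(interpolate=False)),
    ("EPID", q.build_epid_panel(), q.SearchOptions(interpolate=True, interp_step=0.1)),
]:
    ref = q.measure(baseline, spec, q.NoiseModel(seed=1))
    ne = q.measure(baseline, spec, q.NoiseModel(seed=2))
    ev = q.measure(errored, spec, q.NoiseModel(seed=3))
    for criteria in q.STUDY_CRITERIA:
        std = q.gamma_index(ref, ne, criteria, opts)
        res = q.gamma_index(ref, ev, criteria, opts)
        detected = res.gpr < std.gpr
        print(f"{name:8s} {criteria.label:7s}  NE standard {std.gpr:6.1f} %"
              f"  +5mm shift GPR {res.gpr:6.2f} %  GMV {res.gmv:6.3f}"
              f"  detected={detected}")
```

prints

```
ArcCHECK 3%/3mm   NE standard  100.0 %  +5mm shift GPR  16.39 %  GMV  5.557  detected=True
ArcCHECK 2%/2mm   NE standard  100.0 %  +5mm shift GPR  16.39 %  GMV  8.335  detected=True
ArcCHECK 2%/1mm   NE standard  100.0 %  +5mm shift GPR  16.39 %  GMV  8.335  detected=True
ArcCHECK 1%/1mm   NE standard  100.0 %  +5mm shift GPR  13.11 %  GMV 16.670  detected=True
EPID     3%/3mm   NE standard  100.0 %  +5mm shift GPR  57.09 %  GMV  1.914  detected=True
EPID     2%/2mm   NE standard  100.0 %  +5mm shift GPR  43.25 %  GMV  4.894  detected=True
EPID     2%/1mm   NE standard  100.0 %  +5mm shift GPR  32.54 %  GMV  7.372  detected=True
EPID     1%/1mm   NE standard  100.0 %  +5mm shift GPR  29.73 %  GMV 14.591  detected=True
```

Both devices detect a 5 mm shift at every criterion (GPR < 100).  The array's
2%/2mm and 2%/1mm rows are *identical* — its 5 mm sampling makes the DTA
tolerance inert — while the panel's pass rate drops steadily as DTA tightens.

Full studies (cohort × error grid × detectors × criteria × native/1 mm
resolutions, with CSV tables and a JSON manifest) run from the shell:

```bash
qasense config show-defaults          # every tunable, as YAML
qasense study run --config study.yaml --out results/
```

plus `generate`, `perturb`, `render`, `measure`, `gamma`, `resample` and
`fixtures` subcommands for the individual pipeline stages; dose matrices
travel as a documented plain-text format (`qasense-dose 1` header).

## Acceptance script

`scripts/acceptance.py` recomputes the headline quantity from scratch: it
generates a fresh patient plan from the given seed, measures its baseline
delivery twice with independent noise on both detector models, runs global
gamma at all four criteria, and reports the minimum pass rate over every
detector × criteria cell (the no-error measurement-to-measurement standard):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| Module | Contents |
| --- | --- |
| `qasense.plans` | plan/error types, plan generator, error injection, dose rendering |
| `qasense.detectors` | diode-array and panel models, noise, virtual measurement |
| `qasense.gamma` | gamma engine, criteria, summaries, brute-force oracle |
| `qasense.resample` | dose-matrix resolution changes |
| `qasense.study` | study orchestration, detection calls, aggregation |
| `qasense.io` / `qasense.cli` / `qasense.fixtures` | formats, CLI, fixture pack |

See `docs/methods.md` for the model assumptions, parameter defaults and known
limitations.
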