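# cupcov — acetabular cup coverage simulation for Crowe type-IV hips

In Crowe type-IV developmental dysplasia of the hip (DDH), the femoral head
is completely dislocated and the *true* acetabulum is a small, shallow,
roughly conic socket (usually under 40 mm across).  Total hip arthroplasty
in these hips typically uses a 44-mm cup — the smallest shell that accepts
a 28-mm head — so part of the cup is inevitably left uncovered by host
bone, and ≥ 70 % host-bone coverage is the usual stability guideline.

`cupcov` re-implements the 3-D implantation-simulation measurement of that
uncoverage as a tested, reproducible pipeline for surgeons and researchers
doing CT-based preoperative planning studies:

* **Pelvic frame** — coronal / sagittal / horizontal planes from the
  anterior pelvic plane landmarks (bilateral ASIS + pubic tubercles).
* **Cup placement** — a 44-mm hemispherical cup at 45° abduction / 20°
  anteversion (radiographic convention), medialized until it abuts the
  medial wall, with the front edge tangent to the anterior wall and the
  lower edge tangent to the transverse ligament.
* **Uncoverage ratios** — an eggshell (0.01-mm) copy of the cup is the
  measurement surface; a facet is covered iff its centroid lies in (or
  within ε = 0.1 mm of) host bone.  The total uncoverage ratio is

      TUCR = uncovered area / total outer surface area

  and the cup is split into anterior-superior, anterior-inferior,
  posterior-superior and posterior-inferior segments by two planes: the
  *quadrantal sagittal plane* through both ASIS and the cup centre, and the
  perpendicular *quadrantal horizontal plane* through the cup centre.
  Segmental ratios (A-SUCR, A-IUCR, P-SUCR, P-IUCR) share the total-area
  denominator, so they sum exactly to the TUCR.
* **Morphometrics** — acetabular height H (perpendicular distance of the
  most superior rim point from the horizontal plane through the lower
  edge, |a·p₁+b·p₂+c·p₃+d|/√(a²+b²+c²)), A-P diameter R at ½H, and the
  planning volume proxy V = H·R·R.
* **Cohort statistics** — Kolmogorov–Smirnov normality check, Pearson
  correlation + simple linear regression (R² = r²), and a Welch comparison
  of the TUCR ≤ 0.3 vs > 0.3 groups.

No patient CT data ship with the package.  Instead, `cupcov.synthetic`
generates watertight hemipelvis *phantoms* whose coverage is known by
construction: a pre-reamed cup-congruent socket with per-quadrant
deficiency "windows" of prescribed area fraction, plus landmark fiducials
encoding target height and A-P diameter.  The cohort generator emulates a
published reference cohort of 30 Crowe-IV hips (TUCR 0.2958 ± 0.1003,
H 31.99 ± 4.09 mm, R 25.23 ± 4.82 mm), which makes every stage of the
pipeline verifiable against analytic ground truth.

## Worked example

```python
import numpy as np
from cupcov import SyntheticHipParams, generate_hip, RunConfig, process_hip

params = SyntheticHipParams(
    acetabular_height_mm=32.0, ap_diameter_mm=25.0,
    f_as=0.30, f_ai=0.15, f_ps=0.45, f_pi=0.20, seed=42,
)
hip = generate_hip(params)                 # watertight phantom + landmarks
result = process_hip(hip.bone, RunConfig())  # frame -> seat -> measure

ucrs, m = result["ucrs"], result["metrics"]
print(f"TUCR   {ucrs.tucr:.4f}   (construction truth {hip.ground_truth.tucr:.4f})")
for name in ("asucr", "aiucr", "psucr", "piucr"):
    print(f"{name.upper():6s} {getattr(ucrs, name):.4f}   "
          f"(truth {getattr(hip.ground_truth, name):.4f})")
print(f"H = {m.height_mm:.2f} mm, R = {m.ap_diameter_mm:.2f} mm, "
      f"V = H*R*R = {m.volume_proxy_mm3:.0f} mm^3")
```

prints

```
TUCR   0.2922   (construction truth 0.2880)
ASUCR  0.0460   (truth 0.0444)
AIUCR  0.0282   (truth 0.0260)
PSUCR  0.1480   (truth 0.1472)
PIUCR  0.0700   (truth 0.0704)
H = 32.00 mm, R = 24.97 mm, V = H*R*R = 19954 mm^3
```

i.e. the pipeline recovers each requested segmental deficiency to a few
parts in a thousand and the morphometric targets to a few hundredths of a
millimetre — the 29 % total uncoverage is typical for a 44-mm cup in a
Crowe-IV socket (P-S segment contributing most).

The same pipeline runs from the shell on STL + landmark-JSON files:

```sh
cupcov simulate-cohort --n 30 --seed 1 --out-dir cohort/
cupcov run-all --manifest cohort/manifest.yaml --out-dir results/
cupcov stats results/per_hip.csv
```

`run-all` writes a per-hip CSV (ratios, pose, residuals, morphometrics), a
summary table mirroring the correlation matrix of a planning study, and a
plain-text report; every table carries the package version and config hash.

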