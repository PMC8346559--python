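# ocusim

Customized schematic-eye modeling for assessing the optical consequences of
myopic femto-LASIK surgery.

Laser refractive surgery flattens the central cornea to correct myopia, but
it also reshapes the cornea in ways that degrade night vision: as the pupil
dilates, the altered corneal periphery injects high-order aberrations.
`ocusim` quantifies this by building a complete optical model of each eye
from its measured biometry — before and after surgery — tracing
polychromatic ray bundles through it, and reporting the standard image
quality metrics at the retina across field angle (0–30°), pupil diameter
(2–6 mm) and initial myopia. It is aimed at vision scientists and
refractive-surgery researchers who want Zemax-style per-eye simulation as a
scriptable, reproducible Python library.

## The model

Each eye is a rotationally positioned surface stack on a common axis
(z = 0 at the anterior corneal vertex):

- **Corneas.** Anterior and posterior surfaces are conicoids plus
  sixth-order Zernike height maps fitted over a 6-mm zone (OSA double-index
  convention):

  z = r²/R / (1 + √(1 − (1+Q) r²/R²)) + Σᵢⱼ αᵢʲ Zᵢʲ(ρ, φ),

  with coefficients in µm over a 3-mm normalization radius.
- **Crystalline lens.** Equivalent power from Bennett's method,

  P_L = −1000 n_h (S + P_C) / [1000 n_h − (T_AC + c₁T_L)(S + P_C)]
        + 1000 n_h / (−c₂T_L + T_V),

  with n_h = 1.337, c₁ = 0.571, c₂ = −0.378; surface radii from Rozema's
  regressions R_La = 26.02 − 2.7 T_L − 0.2 P_L and
  R_Lp = −16.675 + 1.696 T_L + 0.126 P_L; fixed asphericities −3.13 / −1.00.
- **Retina.** Aspheric shell from Atchison's myopia regressions
  R_R = −12.815 − 0.045 S, Q_R = 0.26 + 0.022 S.
- **Media.** Homogeneous indices with two-term Cauchy dispersion fixed by
  each medium's d-line index and Abbe number (cornea 1.377/56.28, aqueous
  1.337/52.659, lens 1.42/51.226, vitreous 1.336/53.342).
- **Focusing.** Pre-operative eyes wear an ideal thin spectacle (12-mm
  vertex) whose power is optimized for best on-axis focus; post-operative
  eyes are focused by shifting the retina along the axis (|Δ| ≤ 2 mm).

A bespoke sequential ray tracer (closed-form conic intersection with Newton
refinement on the Zernike deviation, vector Snell refraction, iterative ray
aiming to the physical stop) produces spot diagrams, longitudinal and
transverse chromatic aberration, pupil OPD maps, FFT polychromatic PSF /
Strehl ratios, and tangential/sagittal-averaged MTF to 60 cyc/mm at the
three Fraunhofer lines (656.273 / 587.562 / 486.133 nm).

Because no per-eye dataset is published, `ocusim.cohort` generates a
synthetic paired pre/post cohort whose marginal statistics reproduce the
published 134-eye population (anterior radius 7.77 ± 0.25 → 8.56 ± 0.43 mm,
asphericity −0.28 ± 0.11 → 0.63 ± 0.44, high-order RMS 0.09 ± 0.02 →
0.15 ± 0.05 µm, …) and whose surgically induced anterior-corneal changes
correlate with initial myopia.

## Worked example

```python
import ocusim as oc
from ocusim.metrics import evaluate_eye

rec = oc.mean_biometry("post")          # published mean post-op biometry
eye = oc.build_eye(rec, stop_diameter=2.0)
print(f"retina shift: {eye.retina_shift:+.3f} mm")
report = evaluate_eye(eye, fields=(0.0, 30.0), pupils=(2.0, 6.0))
```

prints

```
retina shift: +0.656 mm
 field_deg  pupil_mm         metric   value
         0         2    rms_spot_um   5.596
         0         2         strehl   0.616
         0         2 mtf_mean_30cpm  0.7027
        30         2    rms_spot_um   28.76
        30         2         strehl 0.01848
        30         2 mtf_mean_30cpm  0.1598
         0         6    rms_spot_um   61.79
         0         6         strehl 0.01987
         0         6 mtf_mean_30cpm 0.03394
        30         6    rms_spot_um   99.85
        30         6         strehl 0.00106
        30         6 mtf_mean_30cpm 0.04328
```

The retina moves 0.66 mm back to reach best focus. At a 2-mm pupil the
on-axis polychromatic Strehl ratio is 0.62 (chromatic defocus is the
limiting factor; the green-only value is 0.99) and contrast at 30 cyc/mm is
0.70. Opening the pupil to 6 mm exposes the oblate post-operative cornea's
spherical aberration: the RMS spot grows from 5.6 µm to 62 µm and the
Strehl ratio collapses to 0.02. Performance also degrades from the central
to the peripheral retina (0° → 30°).

## Command line

```bash
ocusim simulate --n 134 --seed 42 --out run_out   # full synthetic cohort
ocusim build --input eye.json --pupil 2 --out model.json
ocusim evaluate --eye model.json --field 0 --pupil 2
ocusim validate biometry.json
ocusim summarize --report run_out/quality_report.csv \
                 --cohort run_out/cohort.jsonl --out summary.csv
```

`simulate` writes the cohort (JSONL), a tidy per-cell metric table (CSV), a
per-myopia-group summary (mean ± SD), and a machine-readable manifest that
reproduces the run byte for byte.

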