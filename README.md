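# cavipact

Simulation of **cavity-structure artifacts in photoacoustic tomography**
(PACT) and evaluation of two artifact-removal filters — anisotropic
diffusion (ADF) and non-local means (NLM) — as a function of light-source
uniformity.

Organs with cavities (lungs, airways) are hard to image photoacoustically:
the enormous acoustic impedance mismatch between tissue and air reflects
the pressure waves launched by absorbing blood vessels, and the reflections
reconstruct as semicircular artifacts. This package provides that whole
chain as a tested pipeline for researchers working on PA image quality:

```
phantom -> optics -> acoustics -> recon -> filters -> evaluate
```

* **phantom** — a 5 cm agarose cube with 1 mm tubes of blood, air and water
  in horizontal rows or 3x3 Latin squares (each medium once per row and
  column), rasterised to label maps.
* **optics** — initial pressure from the photoacoustic relation
  `P0 = Γ·η·μa·F` (uniform light, Γ = η = 1), or Monte-Carlo photon
  transport (Henyey–Greenstein scattering, Fresnel boundaries, Russian
  roulette) for Gaussian beams with waist radii of 1–20 mm from five
  sources spaced 39° apart.
* **acoustics** — k-space pseudospectral propagation of the first-order
  linear acoustics system through the heterogeneous map (air 340 m/s,
  1.2 kg/m³; everything else 1500 m/s, 1000 kg/m³) onto a 128-element
  half-ring array (radius 55 mm), 4096 samples at 12.5 ns. A 4th-order
  staggered-grid FDTD solver serves as an independent cross-check.
* **recon** — zero-phase 750 kHz low-pass, then delay-and-sum beamforming
  at the calibration speeds (water 1429 m/s, air 430 m/s).
* **filters** — Perona–Malik diffusion
  `I_s ← I_s + (Δt/|η_s|) Σ_p c(|I_p−I_s|)(I_p−I_s)` with
  `c(x) = exp(−(x/k)²)` or `1/(1+(x/k)²)`, and non-local means
  `I'(p) = Σ_q f(p,q) I(q) / Σ_q f(p,q)` with
  `f(p,q) = exp(−‖v_p−v_q‖²/h²)`.
* **evaluate** — PSNR/SSIM/MSE/NAE against the anticipated image `Ga`
  (ground-truth absorber disks), and the **lift ratio**
  `(X(Ga,Gf) − X(Ga,Go)) / X(Ga,Go)` for each metric X, plus artifact
  isolation, circle fitting, and the waist-radius sweep with ADF/NLM
  crossover detection.

## Worked example

```python
from cavipact import evaluate as ev, filters as flt

# uniform-light pipeline for the blood–air–water row
paired = ev.paired_artifact_case("s4")
print(paired["profile"])

case = paired["full"]
for name, fn, params in [("adf", flt.adf, ev.FROZEN_ADF_PARAMS),
                         ("nlm", flt.nlm, ev.FROZEN_NLM_PARAMS)]:
    rep = ev.build_report(case["ga"], case["go"], fn(case["go"], params), name)
    print(name, {m: round(100 * v, 2) for m, v in rep.lift_ratios.items()})
```

prints

```
ArtifactProfile(center_xy=(-0.290, -0.828), radius=8.998, arc_span=190.0,
                n_pixels=431, source_pair=None)
adf {'psnr': 0.9, 'ssim': -0.03, 'mse': -5.78, 'nae': -0.0}
nlm {'psnr': 0.94, 'ssim': -0.28, 'mse': -6.05, 'nae': -1.46}
```

The isolated artifact is a circular arc centred within 1 mm of the air
tube whose radius (9.0 mm) is within 10 % of the 10 mm blood–air distance —
the reflection signature of the air cavity. Under uniform light NLM's PSNR
lift exceeds ADF's, and both filters reduce the error metrics (negative MSE
and NAE lifts), matching the expected ordering for uniform illumination.

A full experiment (including YAML config, TIFF/HDF5 intermediates and a
hashed manifest) runs from the command line:

```sh
cavipact run --arrangement s4 --light uniform --out runs/s4
cavipact sweep --arrangement s4 --waists 5,10,14,17,20 --seed 1
```

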