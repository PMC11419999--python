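# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, in the order the method runs.

## Phantom (synthetic-data generator)

The phantom emulates a 5 cm agarose cube immersed in water, holding sealed
1 mm-diameter tubes (length 50 mm) of blood, air or water whose
cross-sections are disks in the imaging plane. Twelve layouts are
provided: single-tube controls (`s1`–`s3`), horizontal three-tube rows
(`s4` blood–air–water, `s5` air–blood–water, `s6` air–water–blood),
single-medium 3×3 matrices (`S1`–`S3`) and 3×3 Latin squares (`S4`–`S6`)
whose first row matches the lowercase layout and whose later rows are
cyclic shifts, so each medium appears once per row and column.

Centre-to-centre tube spacing has no single canonical value;
the default is **10 mm**, configurable and echoed in every output. Tube
radius defaults to 0.5 mm (the simulated 1 mm diameter); 0.45 mm matches
the physical PTFE tubes. Rasterisation labels each pixel by the medium
containing its centre (strict centre-in-disk, no area weighting — the
simplest reproducible rule); a tube narrower than one cell still marks its
centre cell. Coordinates: physical origin at the grid centre, x rightward,
y upward, row 0 on top, all geometry in mm.

What the generator does **not** emulate: tube walls (PTFE acoustics),
agarose fabrication variability, 3-D lung anatomy, and acoustic
attenuation. Passing tests therefore demonstrate the artifact mechanism
and filter behaviour under idealised geometry, not performance on real
lung images.

### Media properties

Uniform-light table (only blood absorbs): μa = 3 /cm for blood, 0 for
substrate/air/water. Monte-Carlo table at 800 nm: blood μa 2.38, μs 522,
g 0.9, n 1.4; water 0.06, 1, 0.99, 1.3; air 0.001, 347, 0.001, 1.0;
background 0.0001, 0.1, 1.0, 1.0. The optical table omits the agarose
substrate, so the package assigns it the spectrophotometer-measured
absorption at 800 nm (0.056 /cm) with the weak scattering of a plain 1 %
agarose gel (μs = 1 /cm, g = 0.8, i.e. μs′ = 0.2 /cm; n = 1.34). A
substrate that absorbs at this level is what lets focused beams imprint
visible light paths on the image — the phenomenon the waist sweep
measures; treating the substrate as optically inert makes the
reconstruction nearly waist-invariant.

Acoustic properties: air tubes 340 m/s and 1.2 kg/m³; substrate, blood,
water tubes and the surrounding bath 1500 m/s and 1000 kg/m³. The
tissue/air impedance mismatch is the studied mechanism, so the maps are
piecewise constant with no interface smoothing.

## Optics

Uniform light: `P0 = Γ·η·μa·F` pointwise, with Γ = η = 1 and unit
fluence, so P0 equals the absorption map numerically; it is normalised to
[0, 1] before the acoustic stage (the whole pipeline works on normalised
dimensionless fields).

Gaussian-beam Monte Carlo: photon packets with exponential free paths
against μs, **continuous absorption weighting** along every sub-path
(w ← w·e^(−μa·ℓ)), path-length fluence estimation (unbiased also where
μa = 0), Henyey–Greenstein scattering, Fresnel reflection/refraction at
voxel faces where the refractive index changes, and Russian roulette below
weight 1e-4 (survival 0.1). The weight ledger (absorbed + exited +
terminated + roulette-net = launched) balances to better than 1e-6
relative and is attached to every fluence map. In a scatter-free absorber
the ballistic transmission equals Beer–Lambert exactly, because continuous
weighting removes the sampling noise of discrete absorption events.

Beam geometry: five sources on an arc of radius 55 mm above the phantom,
spaced 39° and aimed at the grid centre. Each photon starts at its source
centre plus a Gaussian transverse offset with σ = w/2 per axis (the
positional spread of an intensity profile e^(−2r²/w²)); the 10 mm × 1 mm
emitter aperture is carried as provenance. The exact source placement
relative to the transducer ring is a free design choice, so it is exposed
as configuration with this default. Time gating is not modelled: fluence is
accumulated to steady state, since it only enters as a static weight in
the pressure relation.

Transport runs in full 3-D (extruded tubes, 120³ voxels at 1 mm, central
slice projected for the acoustic stage) or in a 2-D fast mode confined to
the imaging plane; 2-D scattering rotates in-plane by the HG polar angle
with a random sign. The sweep and tests use the 2-D mode (flagged in
metadata) with 10⁵ photons; the full-scale 10⁸-photon 3-D run is a
configuration change, not a code change.

## Acoustics

First-order linear acoustics (momentum + mass conservation + pressure
relation) on heterogeneous c(x), ρ(x), solved with the k-space
pseudospectral scheme: FFT derivatives on spatially staggered grids, a
k-space correction sinc(c_ref·k·Δt/2) with c_ref = max c, split acoustic
densities, and an exponential absorbing layer (10 pixels, quartic ramp,
α = 2) outside the 121×121 physical grid. The initial condition applies
p0 with a half-step velocity update; sources are smoothed with a
separable Blackman window in k-space (magnitude restored) to suppress
staircase ringing. With the PML disabled the domain is periodic and the
staggered-leapfrog energy invariant is conserved to machine precision.
No acoustic attenuation term is included. CFL checks reject unstable
time steps with the computed limit (≤ 1 for k-space, ≤ 1/√2 for FDTD);
the default settings give CFL ≈ 0.019.

A 4th-order staggered-grid FDTD solver with the same interface acts as an
independent oracle: on a 64² homogeneous fixture the two schemes agree to
trace correlation ≥ 0.999 with coincident peak arrival.

The 128-element half-ring (radius 55 mm, 180°, evenly spaced including
both endpoints) samples pressure by bilinear interpolation each step for
4096 samples at 12.5 ns. The arc sits above the phantom; orientation is
configurable. Both 121×121 (default) and 120×120 grids are expressible
via the spec; they differ only in whether the physical origin falls on a
grid node.

## Reconstruction

Traces are low-passed at 750 kHz (Butterworth order 4, forward–backward,
zero phase so arrival times are preserved) and beamformed by
delay-and-sum with straight-ray delays at 1429 m/s (water calibration
speed). An optional two-speed mode integrates each ray piecewise through
air pixels at 430 m/s (sampled at 64 points per ray). Delays beyond the
recorded window contribute zero and are counted; above 10 % a warning
reports the fraction. The signed DAS output is normalised by **clipping
negative lobes to zero and scaling the peak to 1**: the zero-pressure
background then maps to ~0, matching the normalised dark-background
convention of the evaluation stage (a min→0 mapping would park the
background at mid-gray and drown the error metrics in a constant offset).

The default reconstruction grid is desk-scale, 300×300 at 0.4 mm;
`ReconSpec.full_scale()` gives 1200×1200 at 0.1 mm (their downsampled images
correlate at ≥ 0.95 on the round-trip fixture). Because forward water
speed (1500) and calibration speed (1429) differ, reconstructed features
shift ~5 % radially toward the array; the artifact-geometry analysis
therefore reconstructs at the matched forward speed by default (mode
recorded), so fitted circle geometry is not biased by the calibration
offset. Both speeds remain independently configurable.

## Filters

ADF: explicit Euler iteration over the 4-neighbourhood with neighbour
differences I_p − I_s, reflective boundaries, and the neighbour count
|η_s| reduced at borders (4/3/2). Stability requires Δt ∈ (0, 0.25]; the
update is then a convex combination, giving the extremum principle. Mean
conservation holds exactly in the interior; the border |η_s| reduction
breaks exact flux antisymmetry at edge pixels, which is negligible
(< 1e-6 relative per iteration) for images whose borders are flat, as
reconstructions here are. The rational coefficient is implemented as
1/(1+(x/k)²), reading the printed "(x/2)" denominator as a typographical
slip for the edge scale k; the printed variant stays selectable for audit
(`coefficient="rational_printed"`).

NLM: weights exp(−‖v_p−v_q‖²/h²) on the *summed* (not averaged) squared
patch distance, candidates clipped to the image, patches reflectively
padded. The vectorised implementation is verified to match a brute-force
double-loop evaluation on ≤ 16×16 images to machine precision.

### Hyperparameter selection (frozen)

No canonical hyperparameters exist for this comparison. Defaults scale with
dynamic range (k = h = 0.1 × range, Δt = 0.2, 20 iterations, patch 2,
search 7). For reported comparisons, each filter's parameters were chosen
once by maximising the PSNR lift on the held-out `s5` arrangement and then
frozen: **ADF k = 0.1, Δt = 0.25, 40 iterations, exponential coefficient;
NLM h = 0.4, patch 2, search 7**. The search grids are bounded by each
filter's standard operating regime, fixed a priori: ADF's edge scale k
stays below the object edge-gradient magnitude (~0.2 per pixel on
normalised images — above it the coefficient no longer distinguishes
edges and the method degenerates to isotropic blurring by its own
definition), and NLM's h runs up to roughly ten times the background
fluctuation scale, the usual prescription relating h to the noise level.
Within those regimes both filters improve monotonically with smoothing
strength on these images, so bounding the grids is what makes the frozen
comparison meaningful.

## Evaluation

Metrics: MSE = mean((Ga−G)²); PSNR = 10·log₁₀(1/MSE) (identical images
report +inf); NAE = Σ|Ga−G| / Σ|Ga|; SSIM with K1 = 0.01, K2 = 0.03,
data range 1 and an 11-pixel Gaussian window (σ = 1.5). Lift ratios use a
1e-12 guard on the baseline; undefined ratios are flagged in the report,
never zeroed.

The anticipated image Ga is the ground-truth absorber-disk rendering at
reconstruction resolution, intensity proportional to μa, normalised — the
only observer-independent definition of an "anticipated" image. Media
with μa below 5 % of the strongest absorber (air, water, substrate)
render as zero. With this Ga most of the baseline error is irreducible
blob-shape mismatch plus smooth limited-view streaks, so lift magnitudes
are small (≈1 % PSNR) by construction; the *ordering* (NLM over ADF under
uniform light, negative error-metric lifts) is the meaningful output, and
that is what the tests assert.

Artifact isolation subtracts the blood-only twin simulation from the full
one — on raw traces for sensor data, on raw unnormalised DAS images
otherwise (mode recorded). The circle fit is unweighted algebraic least
squares (Kasa) on pixels above a threshold fraction (default 0.5) of the
peak |value|; the arc span is the fraction of occupied 5° bins. Fewer
than 10 super-threshold pixels is rejected.

### Waist sweep and crossover detection

For each waist the full Gaussian pipeline runs (2-D MC at 10⁵ photons by
default) and both frozen filters are scored. Waists below 8 mm are
flagged unstable: over-focused illumination makes the metrics track the
visible light paths rather than the blood tubes. Because the two
filters' lift magnitudes differ systematically with their smoothing
strength, raw lift quotients sit away from 1 at every waist; the
informative comparison is between the **normalised improvement-rate
trends** — each filter's per-metric lift curve, error-metric curves
flipped, min-max normalised over the sweep — which isolate how each
filter *responds* to light-source uniformity. Crossovers are sign changes
of the difference of the smoothed (3-point moving average, recorded)
normalised trends, located by linear interpolation. At the desk-scale
settings (waists {5, 10, 14, 17, 20} mm, seed 1) crossings fall at
≈ 11.9–15.3 mm for MSE/PSNR/SSIM, inside the 10–20 mm band where such a
flip is expected; raw quotient curves remain available
(`improvement_ratio_curves(rows, normalized=False)`).

## Problem sizes

All defaults are desk-scale, chosen so the full suite and the
reproduction script each run in minutes on one CPU: 121×121 acoustic grid
(4096 × 12.5 ns samples), 300×300 reconstruction at
0.4 mm, 10⁵ photons in the 2-D fast mode, 5-point waist sweep. The
full-scale values (1200×1200 at 0.1 mm, 10⁸ photons, 3-D transport,
20-point sweep) are reachable through configuration alone.

## Known limitations

* The Monte-Carlo 2-D fast mode is an approximation of in-plane
  transport, not a slice of the 3-D solution; its HG sampling uses the
  3-D polar angle in-plane.
* DAS with straight rays cannot model refraction around the air tube; the
  two-speed mode corrects travel time, not path.
* SSIM lifts are small and can be negative for both filters at these
  settings; they are reported but no ordering is asserted.
* Lift percentages depend strongly on the filter hyperparameters and on
  the operational definition of the anticipated image; comparisons here
  are directional by design, and magnitudes should not be compared across
  pipelines with different choices.
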