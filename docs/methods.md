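# Methods note

Assumptions, deliberate simplifications, and the validation evidence behind
each of them. Everything here is checked by the test suite
(`tests/test_acceptance.py` cites the same items).

## Coordinate conventions

Transducer frame: +x lateral (subject's right when worn on the forehead),
+y elevation (superior), +z axial into the head, origin at the center of
the array surface. Head volumes are handled in RAS millimetres and
converted with a rigid `TransducerPose` (orthonormal, right-handed —
asserted in tests).

## Acoustic solver

Monochromatic Rayleigh–Sommerfeld integral over 4.1 mm square elements with
3 × 3 sub-element quadrature:

p(r) = Σ_e A_e p0 e^{−iωτ_e} e^{−α d_e} Σ_s (k ΔS / 2π) e^{−ikd_s} / d_s

with k = 2πf/c, soft-tissue attenuation α = 0.3 dB/cm/MHz applied along the
element-center distance, and delays from time-of-flight to the focus.

**Validation.** Against an independent brute-force per-sub-element
summation the relative RMSE is < 1e−3 (machine precision in practice,
~1e−15). A 3 × 3 quadrature is sufficient because elements are ~1 λ across
at 400 kHz (λ = 3.85 mm).

**Heterogeneous overlay.** A straight-ray phase/attenuation screen:
per-element rays to each field point accumulate α(x) and k(x) by exact
midpoint quadrature over a labelled volume (soft tissue / skull / air);
rays crossing air are zeroed (total blockage). On a uniform soft-tissue map
this reduces *exactly* to the homogeneous solver (tested at rtol 1e−10). A
6 mm skull slab attenuates the central ray by the closed-form 1.44 dB
absolute / 1.37 dB relative to soft tissue (skull 2.7 dB/cm/MHz vs soft
tissue 0.3). Not modelled: refraction, reverberation, shear/mode
conversion, nonlinearity — acceptable for planning-grade field shapes at
transcranial LIFU pressures, but absolute transcranial pressures should be
taken as estimates.

## Solver substitution and its consequences (the known red result)

The reference steering volume (~1.8 × 2.5 × 2 cm centered at 5 cm depth)
derives from full-wave simulations, where scattering and diffraction
losses lower focal gain. The Rayleigh solver's gain is higher, so the source
pressure needed for 820 kPa focal PNP is lower, time-averaged power is
lower, and the cranial thermal index peaks at **2.83 < 3** everywhere on
the candidate grid (−12.5..12.5 × −20..10 × 40..60 mm). The TIC limit
therefore never trims the valid region: its lateral extent equals the full
candidate span (2.5 cm, +39% vs reference, outside the ±30% tolerance),
while elevation (3.0 cm, +20%) and axial (2.0 cm, exact) agree. We report
this honestly rather than tuning the grid, limits or solver to force
agreement; the acceptance test for this criterion encodes the reference
tolerance and fails.

## Grating-lobe metric: tube exclusion, not a ball

The grating ratio is peak amplitude outside the main lobe over focus
amplitude, limit 0.5 (−6 dB). The main lobe is a cigar (~4.8 mm lateral ×
~32 mm axial at −6 dB), so a 10 mm-radius *ball* around the focus leaves
the main lobe's own axial tails inside the search region and flags them as
grating lobes. We exclude a 10 mm-radius **tube around the beam axis
through the focus**, plus the first 10 mm of near field. This is a
deliberate, documented deviation that keeps the metric meaningful for
steered foci; true (laterally displaced) grating lobes remain in the search
region.

## Dose metrics

- I_SPPA = p²/(2ρc), ρ = 1050 kg/m³, c = 1540 m/s: 510/650/820 kPa →
  8.04/13.1/20.8 W/cm².
- MI = PNP[MPa]/√f[MHz]: 0.81/1.03/1.30 at 400 kHz.
- I_SPTA accumulates per-voxel intensity over the actual timeline (pulse
  duty × per-focus time fraction × train duty). Closed-form check: 510 kPa
  at 5% × 50% duty → 201 mW/cm²; simulated interleaved five-focus 650 kPa
  sequence → 167 mW/cm² spatial peak (no voxel sees every focus).
- TIC = W_acoustic / (5.31 cm × 40 mW/cm). Closed-form check: one element
  at 100 kPa, full duty → 51.98 mW.

## Thermal model

Explicit finite-difference Pennes bioheat equation (κ = 0.52 W/m/K,
ρC = 3.6 MJ/m³/K, optional perfusion), volumetric source Q = 2αI, stability
dt ≤ 0.8 h²/6κ. Validated against the adiabatic closed form (rel. error
1e−6 with conductivity disabled) and duty-cycle linearity. Multi-focus
heating by superposition of per-focus solutions matches the full simulation
within 0.7% (tested at 5%).

## Sinus ray tracing

Per element, intensities are sampled along the straight segment to the
target. Normalization maps the mean of the first 1 mm (air in front of the
standoff) to 0 and the 90th percentile of the last 2 mm (white matter) to
1; an element is blocked if any sample falls below 0.10, excluding the
first 1 mm and the leading contiguous sub-threshold run (the air/coupling
gap before skin entry — without this exclusion a standoff would flag every
element). Against the phantom's exact segment–sphere oracle, blocked counts
agree within ±2 elements and ≥98% of per-element labels agree at 1 mm
voxels for representative poses. Grazing poses (elevation ≈ 10°, rays
running nearly tangent to the sinus surface) are the worst case (~94%
agreement) — a discretization effect, documented rather than tuned away.

## Phantom

Ellipsoidal head (semi-axes 70 × 90 × 80 mm): 4 mm scalp (soft tissue)
outermost, 6 mm skull shell beneath it, soft-tissue brain inside, spherical
frontal sinuses tangent to the inner skull surface. Intensities are label
means plus seeded Gaussian noise (T1-like contrast: soft tissue bright,
skull intermediate, air dark), bit-identical for identical spec + seed. The
truth object provides the independent geometric blockage oracle
(segment–sphere intersection), so detector tests never grade the detector
against itself.

## Virtual fitting

Skin segmented by polar ray-casting (threshold 500) from the head center;
121 candidate positions (elevation 10–40°, azimuth −5–25°, 3° steps). Each
pose: SVD plane fit to a local skin patch, a 10° downward wedge (aims the
beam toward deep targets while the array sits flat on the forehead), and a
10 mm coupling-pad standoff. Selection is a three-stage filter: keep poses
whose target is steering-valid, keep the lowest decile of blocked-element
counts (inverted-CDF percentile), then minimize distance to target, ties
broken by (elevation, azimuth). The 10 mm standoff also guarantees a
leading air/pad gap so the ray normalization has a valid air reference.

## Steering-limits map

For each candidate focus: solve, scale to the plan PNP, compute grating
ratio on a shared 2 mm field grid and TIC from the required source
pressure. Valid ⇔ grating < 0.5 and TIC < 3. The full 11 × 13 × 9 map at
2.5 mm candidate spacing runs in ~30 s on one CPU (shared complex64
transfer matrix, chunked matrix products).

## Reproducibility

`python scripts/acceptance.py --seed <s> --out <path>` recomputes t9 (focus
width), t10 (five-focus I_SPTA peak) and t12 (lateral steering extent) from
scratch; all are deterministic. The full test suite runs in ~4 minutes on
one CPU.
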