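# lifuplan

Treatment-planning toolbox for a wearable, electronically steerable
transcranial low-intensity focused ultrasound (LIFU) system built around a
128-element, 400 kHz curved matrix array.

The package answers the questions that come up when planning a transcranial
LIFU exposure with such a device:

- **Where can the beam go?** Electronic steering trades focal gain for
  source pressure; grating lobes and cranial heating bound the usable
  steering volume (`steering_limits`).
- **Is the exposure within limits?** Derated free-field intensities
  (I_SPPA, I_SPTA), mechanical index, acoustic power, thermal index
  (`dose_metrics`), and a Pennes bioheat simulation of tissue temperature
  rise (`thermal_model`).
- **Where should the array sit on the head?** Virtual fitting over the
  forehead using a head scan, trading off sinus shadowing against distance
  to the target (`virtual_fitting`, `sinus_rays`).

## Physics and scope

The array is an 11 × 12 grid of 4.1 mm square elements at 4.1 mm pitch with
the four corner elements removed (128 active elements, 21.52 cm² active
area), laid on a cylindrical surface of 50 mm radius of curvature along the
lateral axis. Fields are computed with a monochromatic Rayleigh–Sommerfeld
integral (3 × 3 sub-element quadrature) in attenuating soft tissue, with an
optional heterogeneous straight-ray overlay that accumulates per-ray
attenuation and phase through a labelled head volume (soft tissue / skull /
air). This is a planning-grade solver: it captures focal size, steering
loss, grating lobes and bulk skull attenuation, but not refraction,
reverberation or mode conversion — see `docs/methods.md` for the validation
and the documented deviations.

Treatment sequences are pulse trains (e.g. 5 ms pulses at 100 ms PRI, 300
pulses per train, 20 trains at 30 s intervals — a 10-minute session) with
optional multi-focus interleaving across a 5-point cross of foci.

## Worked example

Plan the nominal single-focus exposure — 820 kPa focal peak negative
pressure (PNP) at 50 mm depth on the array axis:

```python
from lifuplan import build_array
from lifuplan.field_solver import (GridSpec, Medium, scale_to_pnp,
                                   simulate_field, uniform_solution)
from lifuplan.sequence import Plan, build_timeline
from lifuplan.dose_metrics import (acoustic_power, beam_widths,
                                   grating_lobe_ratio, ispta_map,
                                   mechanical_index, pnp_to_isppa,
                                   thermal_index_cranium)

geom = build_array()                      # 128 elements, 21.52 cm^2
plan = Plan()                             # 820 kPa, 5 ms / 100 ms, 10 min
timeline = build_timeline(plan)           # 600 s total

medium = Medium()                         # soft tissue: 1540 m/s, 1050 kg/m^3
focus = (0.0, 0.0, 50.0)
grid = GridSpec.from_bounds((-15, -15, 30), (15, 15, 70), 1.0)
sol = uniform_solution(geom, focus)
field = simulate_field(geom, sol, medium, grid)
_, sol, field = scale_to_pnp(field, sol, focus, plan.pnp_kpa)
```

Printed results (these are the actual outputs):

```text
source pressure for 820 kPa focal PNP: 89.2 kPa
-6 dB widths: lateral 4.83 mm, axial 32.2 mm
I_SPPA 20.8 W/cm^2, MI 1.30
spatial-peak I_SPTA: 1101 mW/cm^2   (5% pulse duty, trains back-to-back)
acoustic power 264.6 mW, TIC 1.25
grating ratio 0.154
```

The focus is the expected cigar: ~4.8 mm across and ~32 mm long at −6 dB.
The 510 kPa low-duty protocol (5% pulse duty × 50% train duty) gives the
closed-form I_SPTA of 201 mW/cm², and the interleaved five-focus 650 kPa
protocol peaks at 167 mW/cm² because no single voxel sees every focus.

Virtual fitting on the built-in head phantom (ellipsoidal head, 6 mm skull,
4 mm scalp, two 10 mm frontal sinuses) against a ~5 cm-deep prefrontal
target:

```python
from lifuplan.phantom import frontal_sinus_spec, make_head_phantom
from lifuplan.steering_limits import SteeringMap
from lifuplan.virtual_fitting import (evaluate_candidates,
                                      optimize_placement, segment_skin)

spec = frontal_sinus_spec(voxel_size_mm=2.0, seed=0)
vol, truth = make_head_phantom(spec)
surface = segment_skin(vol, 500.0)
cands = evaluate_candidates(vol, surface, (0.0, 40.0, 10.0), geom,
                            SteeringMap.from_box())
best, ranked = optimize_placement(cands)
```

```text
candidates: 121, steering-valid: 86
winner: elevation 31 deg, azimuth -2 deg, blocked 0/128,
        distance to target 58.0 mm
blockage bin: None
```

The optimizer climbs above the frontal sinuses (higher elevation) until the
ray bundle clears them, then picks the placement closest to the target. The
winner's blocked-element count matches the phantom's geometric ground truth
exactly here and within ±2 elements across candidates.

## Command line

Every step is also a `lifuplan` subcommand; all outputs are JSON/CSV/NIfTI:

```bash
lifuplan phantom --out head.nii.gz --truth-out truth.json --seed 0
lifuplan plan --plan plan.yaml --out-dir run/           # dose report, exit 3 on limit violation
lifuplan steering-map --plan plan.yaml --out-dir smap/  # valid steering volume
lifuplan fit --volume head.nii.gz --target 0,40,10 --out-dir fit/
lifuplan sinus --volume head.nii.gz --pose fit/fit_winner_pose.json --target 0,40,10 --out sinus.json
lifuplan thermal --plan plan.yaml --out thermal.json
lifuplan report --in-dir run/
```

## Package layout

| module | contents |
| ------ | -------- |
| `array_model` | array geometry, poses, element positions/normals |
| `sequence` | pulse/train plans, timelines, duty cycles, validation |
| `field_solver` | Rayleigh–Sommerfeld solver, heterogeneous overlay |
| `dose_metrics` | I_SPPA/I_SPTA/MI/TIC, beam widths, grating ratio |
| `steering_limits` | steering-volume mapping and validity checks |
| `thermal_model` | Pennes bioheat FD simulation, exposure limits |
| `head_volume` | NIfTI I/O, RAS handling, resampling, ray sampling |
| `sinus_rays` | ray-bundle tracing and sinus blockage detection |
| `virtual_fitting` | skin segmentation, candidate poses, optimizer |
| `phantom` | synthetic head phantoms with geometric ground truth |
| `cli` | `lifuplan` command-line interface |
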