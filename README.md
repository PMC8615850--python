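# leadorient

Fully automated detection of the rotational orientation of a **directional
deep-brain-stimulation (DBS) lead** from a postoperative CT scan.

Directional DBS leads steer current perpendicular to the lead axis through
radially segmented contacts, so interpreting or planning stimulation requires
knowing how the lead is rotated about its own axis ("yaw", reported relative
to anterior). The lead's radiopaque stereotactic marker produces a
characteristic metal-artifact pattern in CT, but the dominant hypodense
streak pattern is symmetric under 180°, yielding **two inverse candidate
solutions**. `leadorient` implements the complete pipeline that resolves
this ambiguity without user interaction:

1. **Trajectory refinement** — the two user-supplied trajectory points are
   refined against the hyperdense metal shaft: slice-wise centers of mass of
   voxels above 2000 HU are fitted with least-squares lines x(z), y(z), then
   the axis is anchored through sub-voxel shaft-center measurements on 0.1 mm
   perpendicular slices.
2. **Polar-angle gate** — artifacts degrade as the angle between lead and
   scanner axis grows: ≤ 40° ok, 40–55° reduced confidence, > 55° refused.
3. **Candidate detection** — HU intensities are sampled on circles
   perpendicular to the axis around the marker; the streak axis is the phase
   of the second circular Fourier harmonic, θ = arg(−c₂)/2 with
   c₂ = Σₖ I(αₖ)·e^{2iαₖ}, giving the candidate pair (θ, θ+180°) with
   sub-degree resolution. The artifact slice is auto-selected by maximizing
   the second-harmonic amplitude along the axis.
4. **Ambiguity resolution** by four independent methods:
   * **COM** — center of mass of the marker's thresholded (> 2000 HU)
     hyperdense volume on 0.1 mm perpendicular slices; its deviation from
     the lead axis points toward the true facing direction.
   * **COMsagittal** — the same decision on an in-line slice through the
     axis spanning the marker ± 1.5 mm.
   * **ASM** — compares the heights of the two bright peaks of the angular
     intensity profile (asymmetric sampling of the marker).
   * **STARS** — compares the observed "dark star" streaks at the segmented
     contact levels with each solution's expected streak template.

   The final orientation follows COM (the most reliable method on patient
   data); disagreement of any non-degenerate cross-check raises a mismatch
   flag, and if COM is degenerate a fallback cascade
   (COMsagittal → STARS → ASM) applies with reduced confidence.

A **synthetic phantom generator** (`leadorient.phantom`) emulates the whole
artifact phenomenology — windowed hyperdense marker band, 180°-periodic
streaks with first-harmonic asymmetry, 120°-periodic one-sided dark stars,
Gaussian HU noise, arbitrary tilt — with exact ground truth, so the full
pipeline is testable without patient data.

## Worked example

Generate a noisy phantom with known orientation (yaw 30°, polar tilt 20°)
and detect it:

```bash
leadorient phantom --yaw 30 --polar 20 --noise 15 --seed 1 \
    --out ph.nii --truth truth.json
leadorient detect --ct ph.nii --tip 0,0,0 --head 3.4202,0,9.3969 \
    --out report.json
```

The report (abridged):

```json
{
  "final_orientation_deg": 31.09,
  "candidate_pair_deg": [31.09, 211.09],
  "methods": [
    {"method": "COM",         "chosen_theta_deg": 31.09, "margin": 2.33, "degenerate": false},
    {"method": "COMsagittal", "chosen_theta_deg": 31.09, "margin": 4.71, "degenerate": false},
    {"method": "ASM",         "chosen_theta_deg": 31.09, "margin": 1.74, "degenerate": false},
    {"method": "STARS",       "chosen_theta_deg": 31.09, "margin": 4.62, "degenerate": false}
  ],
  "polar_deg": 20.0,
  "gate": "ok",
  "mismatch": false,
  "confidence": "ok"
}
```

All four methods picked the same solution of the candidate pair
(31.09°, 211.09°), about one degree from the true 30° at 15 HU noise; the
angle convention is 0° = anterior, positive counterclockwise viewed from
superior, range (−180°, 180°]. Exit codes are stable: 0 success, 3 polar
gate refused, 4 unresolved ambiguity, 5 I/O error, 6 no usable artifact.

The same pipeline is available as a library:

```python
import leadorient as lo

ct, truth = lo.generate_phantom(lo.PhantomSpec(yaw_true_deg=30, polar_deg=20, seed=1))
report = lo.detect_orientation(ct, tip=(0, 0, 0), proximal=(3.42, 0, 9.40))
print(report.final_orientation_deg)
```

## Limitations

The default geometry profile models a Cartesia™-style directional lead (one
asymmetric marker, two three-segment contact levels); other leads can be
described in a YAML profile but are unvalidated. The pipeline expects
in-plane CT resolution below 1 mm and a lead-to-scanner-axis angle below
55° (recommended < 40°). MRI–CT coregistration and automatic lead detection
are out of scope: the trajectory points are inputs. See `docs/methods.md`
for the model details and the phantom's known simplifications.
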