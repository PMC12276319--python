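# spinefield

Forward models of the magnetic fields that spinal-cord currents produce
outside the torso, for **magnetospinography (MSG)** — the magnetic
counterpart of spinal evoked potentials, now practical with wearable
optically pumped magnetometers (OPMs) on the back.

MSG source analysis needs a *volume conductor model*: a description of how
the ohmic return currents flowing through torso, organs, cord and vertebral
bone shape the measurable field.  This package implements the full model
hierarchy used to answer "how much conductor realism does MSG need?":

* a deterministic **synthetic geometry generator** — torso with a flat-ish
  back, polynomial spinal curve 50 mm deep, cord (8 mm) and vertebral
  (16 mm) tube surfaces, heart/lung surrogates, 61 × 9 dipole source space,
  and ~250 triaxial magnetometer sites at 10 mm standoff;
* **analytic forward models** — infinite homogeneous medium, the Sarvas
  closed form for a spherically symmetric conductor, and a corrected-sphere
  (single-shell class) model fitted with spherical harmonics up to ℓ = 10;
* a **multi-compartment linear-collocation boundary element solver** for
  1–5 compartment conductors (torso / +heart+lungs / +cord / +bone), with
  an isolated-source variant for the high-contrast cord boundary, validated
  against closed-form sphere oracles;
* **lead-field metrics** — relative error, squared correlation, and the
  eigenfield SVD of cardinal-dipole triplets
  (`L = [l_x l_y l_z] = U S V`, rows of `V` = source orientations);
* a **study pipeline** reproducing the model-comparison matrices, the
  orientation-sensitivity scan, the left/right source-separation analysis,
  a bone-conductivity sweep and the SNR trial-count calculation.

The core physics: the field splits as `B = B_p + B_v`, the Biot–Savart term
of the dipole plus the Geselowitz surface integral
`B_v = −(μ0/4π) Σ_i (σ_i⁻ − σ_i⁺) ∫_{S_i} φ (r − r′)/|r − r′|³ × dS′`
over the conductivity interfaces, with the boundary potentials φ from a
deflated second-kind collocation system.  See `docs/methods.md` for the
discretisation, sign conventions and validation oracles.

## Worked example

```python
from spinefield import GeometryConfig, StudyConfig
from spinefield.study import Study

study = Study(StudyConfig(geometry=GeometryConfig(density=0.5),
                          models=("1c-lc", "5c-lc")))
scan = study.orientation_scan()
print(scan.summary())
```

which prints (half-density synthetic geometry):

```
   model  median_ratio12  median_angle_deg  median_tangent_error_deg
0  1c LC        1.051234         88.838136                 88.829559
1  5c LC        6.322221          4.510260                  0.044264
```

Reading: with a torso-only conductor (`1c LC`) the first two eigenfields
are nearly equally strong (s1/s2 ≈ 1.05) and the dominant source
orientation lies ~89° from the inferior–superior axis (i.e. left–right).
Adding the vertebral bone (`5c LC`) makes one eigenfield ~6.3× stronger
than the next and locks its source orientation onto the spinal curvature
(0.04° median residual): bone acts as a global attenuator of off-axis
current, so sensitivity concentrates along the cord.  At the mid-thoracic
(T9) source the same ratio is 1.06 without bone and 6.27 with it, and the
maximal field of a 1 nAm inferior–superior dipole (~10 fT) is ~5× that of a
left–right one.  The left/right paramedial sources (8 mm apart) become more
distinguishable with bone: their primary-axis field poles go from
near-symmetric (+9.0/−9.3 fT/nAm, 98%) to asymmetric (+6.7/−8.2 fT/nAm,
82%).

Narrative scripts in `examples/` cover each capability (geometry, single
dipole fields, model comparison, eigenfield scan, lateral separation, SNR
planning); a thin CLI mirrors the pipeline stages:

```bash
spinefield build-geometry --out geo/
spinefield leadfield --model 5c-lc --density 0.5 --out lf5c.h5
spinefield run --config study.yaml
spinefield snr --amplitude 50 --noise 20
```

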