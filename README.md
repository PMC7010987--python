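# pvohscan

Noncontact **PV[O]H** tissue imaging in Python: turn streams of
near-infrared CCD spectral frames into elastic/inelastic emission pairs,
invert them to apparent blood-phase volume fractions and hematocrit, and
assemble bleaching-aware line-scan profiles and 2-D raster images — with a
forward optical phantom of a curved, bleachable, injured spinal-cord
surface for end-to-end validation.

It is written for optical-spectroscopy and biomedical-imaging researchers
who probe turbid tissue with a scanned NIR laser (spinal cord, skin) and
want a tested, scriptable implementation of the emission-ratiometry
pipeline without animal data.

## The model

Each 20 ms CCD frame is reduced to two band integrals on the Raman-shift
axis: the **elastic emission** EE (−30 to +10 cm⁻¹ around the 830 nm laser
line) and the **inelastic emission** IE (≈500–1750 cm⁻¹, autofluorescence
plus Raman). The probed volume is a three-phase mixture of red blood cells,
plasma/fluid, and static tissue whose volume fractions close to unity:

    φr + φp + φs = 1

Normalized emissions are affine in the two mobile fractions,

    EE = ϑ₁ + ϑ₂·φp + ϑ₃·φr          IE = ϑ₄ + ϑ₅·φp + ϑ₆·φr

and, being linearly independent, invert to

    φr = a + b·(EE/EE₀) + c·(IE/IE₀)     φp = d + e·(EE/EE₀) + f·(IE/IE₀)

with EE₀, IE₀ the emissions at the start of probing. Apparent hematocrit is

    Hct = 100·φr / (φr + φp)   [%]

anchored at **28.65 %** when EE/EE₀ = IE/IE₀ = 1. On spinal cord the
quantity reads as *turbidity* of the probed fluid (protein, cells, debris in
the CSF), not literal blood hematocrit; absolute values are relative to an
arbitrary reference state, and it is their spatial/temporal variation that
forms images.

The package covers the full pipeline:

| module | role |
|---|---|
| `pvohscan.spectra` | frame I/O, Raman-shift axis, EE/IE band integration, block averaging, adjacent-average smoothing |
| `pvohscan.pvoh` | forward model, analytic and least-squares calibration, inversion, hematocrit |
| `pvohscan.scan` | line (hold–traverse–hold) and single-exposure raster schedules, profile/image assembly, image statistics |
| `pvohscan.bleach` | exponential decay fits, fluence maps, first-order bleach kinetics |
| `pvohscan.phantom` | synthetic cord: Fresnel topographic contrast, bleachable fluorophore field, vessel strip, injury plume, seeded noise |

## Worked example

Simulate one raster image of the default uninjured synthetic cord and look
at the topographic contrast:

```python
import numpy as np
from pvohscan import phantom, pvoh, scan

calib = phantom.cord_calibration()
vf = pvoh.invert(calib.ee0, calib.ie0, calib)
print(f"anchor: phi_r={vf.phi_r:.5f} phi_p={vf.phi_p:.5f} "
      f"Hct={pvoh.hematocrit(vf):.2f}%")

spec = phantom.cord_control(seed=0)
sched = scan.build_raster_schedule(scan.ScanProtocol())
stream, state = phantom.simulate_scan(spec, sched, rng=np.random.default_rng(0))
print(f"stream: {len(stream)} frames over {sched.duration_s:.0f} s")

img = scan.assemble_image(stream, sched, calib)
hct = img.hct
ring = np.concatenate([hct[0], hct[-1], hct[1:-1, 0], hct[1:-1, -1]])
print(f"spatial-mean Hct: {hct.mean():.2f}%  "
      f"center 2x2: {hct[3:5, 3:5].mean():.2f}%  edge ring: {ring.mean():.2f}%")
```

prints

```
anchor: phi_r=0.01146 phi_p=0.02854 Hct=28.65%
stream: 115200 frames over 2304 s
spatial-mean Hct: 26.87%  center 2x2: 28.71%  edge ring: 24.98%
```

The anchor inverts exactly to the 28.65 % reference. The 8×8 image (64
pixels, 1800 frames each) shows the curvature-driven fall-off: at the cord
edges the steeper incidence reflects more light into EE and transmits less
into IE, so the apparent Hct of the rim (24.98 %) sits well below the
near-flat center (28.71 %). A slight overall offset from 28.65 % remains
because even the "flat" center pixels sit at a small tilt and bleach a
little during their 36 s dwell.

The same pipeline is scriptable from the shell:

```bash
pvohscan simulate --scan-type raster --seed 0 --out stream.csv
pvohscan image --stream stream.csv --calib calib.json --out img.tsv
pvohscan stats img1.tsv img2.tsv --out-mean mean.tsv --out-std std.tsv
pvohscan bleachfit --series hold_ie.csv --floor
```

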