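# Methods

## Model and assumptions

The pipeline treats a laser-probed tissue volume as a homogeneous
three-phase mixture — red-blood-cell-like scatterers (φr), plasma/fluid
(φp) and static tissue (φs) — filling the volume with no voids
(φr + φp + φs = 1). In the single-scattering/linear-propagation regime the
two measured channels, elastic emission EE (light remitted at the laser
wavelength) and inelastic emission IE (fluorescence plus Raman), are taken
to be affine in the two mobile fractions. Because the two affine forms are
linearly independent, each simultaneous (EE, IE) pair inverts through a
2×2 linear map to apparent (φr, φp), with φs closing the unity constraint.
Apparent hematocrit, Hct = 100·φr/(φr+φp), is reported in percent and
anchored at 28.65 % at the reference emissions EE₀, IE₀. All apparent
values are relative to that arbitrary reference: on cord tissue they read
as turbidity of the probed fluid, and only their variation is meaningful.

Assumptions worth keeping in mind: phases are optically homogeneous within
the probed depth, the emission response is linear in the fractions over the
ranges probed, and the reference state is stable over a scan. Crossing a
superficial vessel (a localized, strongly scattering and absorbing
structure) violates the homogeneity assumption; the resulting sharp
apparent-Hct dip is reproduced by the phantom as a *signature*, not as a
validated vessel model.

## The shipped calibration preset

The inversion coefficients a–f of the instrument are not publicly
available, so absolute apparent-Hct values are not reproducible; the
package ships a preset chosen to reproduce the method's *behaviors*. Three
end-to-end behaviors constrain the signs of the calibration:

1. photobleaching (IE falls at fixed EE) must raise apparent Hct,
   so ∂Hct/∂(IE/IE₀) < 0;
2. topographic edge coupling (EE up by reflection, IE slightly down by
   transmission loss) must lower apparent Hct, so ∂Hct/∂(EE/EE₀) < 0 and
   dominant;
3. an injected scatterer excess (the injury plume) must raise apparent
   Hct — automatic when the calibration is the exact inverse of the
   phantom's tissue response.

A fourth reported tendency (larger Hct with *increased* IE) cannot coexist
with (1) in any single linear calibration; the preset satisfies (1)–(3)
and the EE half of that tendency, which we judge the physically coherent
set. The preset uses the simplest member of the feasible family — diagonal
coupling, b = dφr/d(EE/EE₀) = −0.038, f = dφp/d(IE/IE₀) = +0.0034,
c = e = 0 — i.e. scatterer content is read from the elastic channel
(more scatterers → less elastic return) and the fluorophore-bearing fluid
from the inelastic channel. Magnitudes were fixed once from two design
targets at the 28.65 % anchor with a 4 % mobile fraction: a fully bleached
hold should rise by a few tenths of an Hct point (so a five-image series
drifts well inside ±1 %), and a 40° edge should fall by several points
(visible far above noise). The baseline mobile fraction φr0 + φp0 defaults
to 0.04 (perfusion-like 3–5 % context); only the φr0:φp0 ratio affects
Hct.

`calib_from_theta` re-anchors the analytic intercepts so the
baseline-consistency identities (a+b+c = φr0, d+e+f = φp0) hold to
round-off; `fit_calibration` imposes them on empirical fits as exact
equality constraints via a KKT solve rather than post-hoc nudging, keeping
the anchor exact and the fit optimal subject to it.

## Acquisition schedules

The line protocol holds 5 min (15,000 frames at 50 Hz) at each of A, B, C
and traverses 5 min between them, averaging 150-frame (3 s) points along
the way — 25 min total. Defaults place B at the impact site and A/C 1 mm
rostral/caudal and 1 mm off the midline. The raster protocol visits 64
pixels (8×8, 0.25 mm pitch — the minimal-assumption square layout for 64
points at ≈250 μm resolution) for 1800 frames (36 s) each, every cell
exactly once per image in a configurable (default boustrophedon) order
that is reused for successive images, so cumulative fluence stays uniform
across pixels and bleaching cannot imprint the visit order on an image.
Pure dwell is 64 × 36 s = 2304 s; any stage overhead is outside the
schedule, and successive images in the simulated series run back-to-back
(start-to-start spacing = scan duration, ≈38 min).

Numerical conventions: band windows are closed intervals on channel-center
shifts; `average_blocks` drops a trailing partial block shorter than half
a block and averages it otherwise (logged); `smooth_adjacent` shrinks its
window symmetrically at the series edges (length-preserving, no invented
padding); traverse points are timestamped at block midpoints and positioned
by linear interpolation; out-of-range inverted fractions are flagged, never
clamped.

## Photobleaching

Bleaching is first-order in locally accumulated fluence: the unbleached
fluorophore fraction is F = exp(−κΦ), with κ = ln 20 / Φ(420 s) so that a
continuous 80 mW, 100 μm top-hat hold reaches 95 % bleach at 7 min — the
midpoint of the observed 5–10 min window for complete bleaching at these
power levels. Only a fraction ρ = 0.20 of IE is bleachable by default; the
rest is an unbleachable floor (Raman and stable fluorophores), which is
what lets repeated raster images stay nearly constant while a continuous
hold still shows a clear monotone rise. Bleached state persists
indefinitely without exposure. Decay fitting defaults to log-linear
regression (matching the semilog evidence); an optional floor mode fits
B + A0·exp(−kt) by nonlinear least squares seeded from the log fit.

Fluence maps discretize the field at 12.5 μm; disk deposits are
renormalized over covered cells so total deposited energy is exactly
power × dwell (per-cell intensity then matches P·t/(πr²) to a few percent
of discretization error).

## The synthetic cord

The phantom emulates, per frame:

* **surface**: a circular-arc cylinder along the cord axis, radius 1.4 mm,
  giving ≈39° incidence at the outermost raster row (within the 35–45°
  design window) and a clamp at 75° where the flank merges into the field;
* **optics**: unpolarized Fresnel reflectance R(θ) for air→tissue
  (n = 1.333); collected EE contains a specular term S·R(θ) plus the
  transmitted tissue response scaled by T², and IE is transmitted only.
  S is tuned in closed form so a 40° tilt raises EE 10 % over baseline.
  (A steeper target such as +10 % at 20° is unattainable: unpolarized R
  grows only ≈3 % between 0° and 20°, and the specular term inflates the
  baseline it is measured against.)
* **fluorophore field**: relative density D(x,y) (default 1) with the
  bleach kinetics above, tracked on a shared fluence grid across scans;
* **vessel**: a 0.2 mm axis-parallel strip at y = 0.5 mm that multiplies
  the transmitted elastic return by 1.10 (whole-blood backscatter) and the
  inelastic by 0.85 (absorption of the excitation), producing the sharp
  localized dip-then-recovery when a traverse crosses it;
* **plume**: an isotropic Gaussian increment on the effective φr, peak
  amplitude 0.5·φr0 decaying e-fold over 3 h, radius relaxing from 0.05 mm
  toward 1.0 mm on a 3 h timescale, active after injury onset (default:
  after the first raster image completes);
* **noise**: mean-preserving multiplicative log-normal noise of σ = 0.5 %
  per frame on each channel, chosen so that at 1800-frame pixel averaging
  the control-series stability criterion (±1 %) holds with margin;
  deterministic under a seed.

On a flat surface at baseline fractions with unbleached fluorophore the
model returns exactly (EE₀, IE₀) — the anchor — and the paired calibration
is the exact inverse of the flat-surface response, so plume perturbations
are recovered exactly there.

During traverses the fluence grid is updated block-by-block (3 s, ≈14 μm
of motion per block at default speed), so a point being probed has already
received the deposits of the approaching spot; within stationary dwells
the local fluence grows analytically. This is accurate to well under a
block of exposure and keeps five full raster simulations to ~1 s of CPU.

### What the phantom does not emulate

Depth-resolved light transport (it is a surface-response model; probed
depth of several hundred μm is implicit in the coefficients), pulsatile and
respiratory motion, drying of the tissue surface, registration error
between scans, cosmic-ray spikes, detector dark current, and any
oxygenation decomposition of hemoglobin states. Passing tests therefore
demonstrate the correctness and stability of the *pipeline* under the
modeled contrast mechanisms, not instrument-level fidelity to in-vivo data.

## Test design notes

Stochastic end-to-end checks use fixed seeds and problem sizes matching the
default protocols: five 8×8 raster images of 1800 frames per pixel per
series, and 15,000-frame holds for bleaching tests (a few seconds of CPU
each). The monotone-rise property of a held location is asserted on the
noise-free phantom, where it is structural; with default noise the test
asserts the aggregate first-hold rise and the strictly smaller re-hold
rise, since late-hold per-block increments (~0.01 Hct) fall below per-block
noise and per-sample monotonicity of a noisy series is not a property of
the method. The plume "dissipation" check compares the impact-pixel excess
at the end of the sequence against its within-sequence peak: an off-center
pixel's difference first grows while the spreading plume reaches it, then
decays with the amplitude.

## Known limitations

Absolute apparent-Hct values depend entirely on the chosen calibration
anchor and are not comparable across instruments. The linear inversion
extrapolates freely outside the calibrated range (flagged, not clamped).
The vessel and plume defaults are signature-level models intended for
pipeline validation, and the ϑ coefficients are phenomenological inputs —
deriving them from radiative-transfer theory with published optical
coefficients is out of scope.
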